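"""Plain-text I/O: subject / genotype / weights TSVs, YAML configs, and an
optional VCF dosage reader."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .genotypes import GenotypeMatrix, PRSWeights
from .simulate import SUBJECT_COLUMNS, SimConfig

__all__ = [
    "write_subjects",
    "read_subjects",
    "write_genotypes",
    "read_genotypes",
    "write_weights",
    "read_weights",
    "write_sim_config",
    "read_sim_config",
    "read_vcf_dosages",
    "ValidationReport",
    "validate_inputs",
]


def write_subjects(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"subject table {path} lacks columns {missing}")
    return df


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Wide TSV: subject_id + one dosage column per SNP, empty cell = missing."""
    df = genotypes.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


def read_genotypes(path, effect_allele: str = "A", other_allele: str = "G") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject_id":
        raise ValidationError(f"genotype table {path} must start with subject_id")
    snp_ids = np.array(df.columns[1:])
    return GenotypeMatrix(
        subject_ids=df["subject_id"].to_numpy(),
        snp_ids=snp_ids,
        effect_allele=np.repeat(effect_allele, len(snp_ids)),
        other_allele=np.repeat(other_allele, len(snp_ids)),
        dosages=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_weights(weights: PRSWeights, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weights(path) -> PRSWeights:
    return PRSWeights(pd.read_csv(path, sep="\t"))


def write_sim_config(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_sim_config(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValidationError(f"unknown simulation-config keys: {sorted(unknown)}")
    for k in ("study_names", "population_based", "cases_per_study", "controls_per_study",
              "age_range", "bmi_range"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    for k in ("maf", "weights"):
        if k in d and d[k] is not None:
            d[k] = np.asarray(d[k], dtype=float)
    return SimConfig(**d)


def read_vcf_dosages(path, weights: PRSWeights) -> GenotypeMatrix:
    """Extract effect-allele dosages for the weights' SNPs from a VCF.

    Biallelic SNPs only; dosage is the genotype-call count of the
    weights-file effect allele (missing call -> missing dosage).  Variants
    are matched by ID.  Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF dosages requires the optional cyvcf2 dependency") from exc

    wanted = {snp: i for i, snp in enumerate(weights.snp_ids)}
    vcf = VCF(str(path))
    subject_ids = np.array(vcf.samples)
    dosages = np.full((len(subject_ids), len(wanted)), np.nan)
    eff = np.array(weights.table["effect_allele"], dtype=object)
    oth = np.array(weights.table["other_allele"], dtype=object)
    seen = set()
    for var in vcf:
        if var.ID not in wanted or len(var.ALT) != 1:
            continue
        j = wanted[var.ID]
        ref, alt = var.REF, var.ALT[0]
        if {ref, alt} != {eff[j], oth[j]}:
            raise ValidationError(
                f"VCF alleles {ref}/{alt} for {var.ID} do not match weights "
                f"{eff[j]}/{oth[j]}"
            )
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (with gts012), 3 unknown
        alt_count = np.array(
            [sum(1 for a in g[:2] if a == 1) if min(g[:2]) >= 0 else np.nan
             for g in var.genotypes],
            dtype=float,
        )
        dosages[:, j] = alt_count if alt == eff[j] else 2.0 - alt_count
        seen.add(var.ID)
    absent = [s for s in wanted if s not in seen]
    if absent:
        raise ValidationError(f"weights SNPs absent from VCF: {absent}")
    return GenotypeMatrix(
        subject_ids=subject_ids,
        snp_ids=np.array(list(wanted)),
        effect_allele=eff.astype(str),
        other_allele=oth.astype(str),
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ValidationReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(subject_path, genotype_path, weights_path) -> ValidationReport:
    """Schema check of the three input TSVs.

    Hard errors: missing columns, non-binary status, dosages outside
    {0, 1, 2, missing}, weight SNPs absent from the genotype matrix,
    subject-id mismatches, duplicate ids.  Warnings: out-of-range but
    plausible values (percent density outside [0, 100] is an error; ages
    outside [18, 100] a warning).
    """
    errors: list[str] = []
    warnings: list[str] = []

    try:
        subjects = read_subjects(subject_path)
    except (ValidationError, OSError, pd.errors.ParserError) as exc:
        return ValidationReport([f"subjects: {exc}"], warnings)

    if subjects["subject_id"].duplicated().any():
        errors.append("subjects: duplicate subject_id values")
    status = subjects["status"]
    if not status.isin([0, 1]).all():
        bad = subjects.loc[~status.isin([0, 1])].index[0]
        errors.append(f"subjects: non-binary status at row {bad}")
    pdv = subjects["pd_percent"]
    if ((pdv < 0) | (pdv > 100)).any():
        errors.append("subjects: pd_percent outside [0, 100]")
    if (subjects["da_cm2"] < 0).any():
        errors.append("subjects: negative dense area")
    if (subjects["total_area_cm2"] <= 0).any():
        errors.append("subjects: non-positive total area")
    age = subjects["age_years"]
    if ((age < 18) | (age > 100)).any():
        warnings.append("subjects: ages outside [18, 100]")

    genotype_df = pd.read_csv(genotype_path, sep="\t")
    if genotype_df.columns[0] != "subject_id":
        errors.append("genotypes: first column must be subject_id")
    else:
        dos = genotype_df.iloc[:, 1:]
        for col in dos.columns:
            vals = dos[col].dropna()
            bad = vals[~vals.isin([0, 1, 2])]
            if len(bad):
                row = bad.index[0]
                errors.append(
                    f"genotypes: dosage {bad.iloc[0]!r} not in {{0,1,2}} "
                    f"at row {row}, column {col}"
                )
        sub_ids = set(subjects["subject_id"])
        gen_ids = set(genotype_df["subject_id"])
        if sub_ids != gen_ids:
            errors.append(
                f"id cross-reference: {len(sub_ids - gen_ids)} subjects without "
                f"genotypes, {len(gen_ids - sub_ids)} genotype rows without subjects"
            )

    try:
        weights = read_weights(weights_path)
    except (ValidationError, OSError, pd.errors.ParserError) as exc:
        errors.append(f"weights: {exc}")
        return ValidationReport(errors, warnings)
    snp_cols = set(genotype_df.columns[1:])
    absent = [s for s in weights.snp_ids if s not in snp_cols]
    if absent:
        errors.append(f"weights: SNPs absent from genotype matrix: {absent}")

    return ValidationReport(errors, warnings)
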