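"""End-to-end orchestration: simulate/load -> score -> adjust -> model ->
goodness of fit -> report bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .density import make_adjusted_phenotypes
from .exceptions import DensPrsError, ValidationError
from .genotypes import GenotypeMatrix, apply_hwe_filter, build_prs_vector, impute_missing_mcmc
from .gof import hosmer_lemeshow, multiplicativity_report, tail_based_gof
from .models import (
    BASELINE_TERMS,
    confounder_sensitivity,
    fit_joint_categorical,
    fit_joint_continuous,
    fit_logistic,
    heterogeneity_by_study,
    interaction_test,
    lrt,
    multiplicativity_product_check,
    or_table,
    prepare_frame,
)
from .simulate import SimConfig, generate_population

__all__ = ["RunConfig", "run_pipeline", "analysis_frame"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``sim`` (a :class:`SimConfig`) or the three input
    paths must be provided.  ``population_based_only`` restricts every
    analysis to the population-based studies; ``confounders`` names the
    optional covariates for the sensitivity analysis.
    """

    sim: SimConfig | None = None
    subject_path: str | None = None
    genotype_path: str | None = None
    weights_path: str | None = None
    population_based_studies: tuple[str, ...] | None = None  # needed for file input
    population_based_only: bool = False
    interaction: bool = True
    k_density: int = 4
    k_prs: int = 5
    hwe_threshold: float = 1e-3
    gof_deciles: int = 10
    tail_fractions: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20)
    gof_n_null: int = 1000
    confounders: tuple[str, ...] = ("parity", "menopause", "family_history")
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        have_files = all(
            p is not None
            for p in (self.subject_path, self.genotype_path, self.weights_path)
        )
        if (self.sim is None) == (not have_files):
            raise ValidationError(
                "exactly one of a simulation block or the three input files is required"
            )


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # where the bundle lands does not change its content
    for k, v in list(d.items()):
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    if isinstance(d.get("sim"), dict):
        for k, v in list(d["sim"].items()):
            if isinstance(v, np.ndarray):
                d["sim"][k] = v.tolist()
    canon = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def analysis_frame(subjects: pd.DataFrame, adjusted, prs_vector) -> pd.DataFrame:
    """Merge subjects, adjusted phenotypes and PRS into one modelling frame."""
    frame = subjects.merge(adjusted.frame.drop(columns=["status"]), on="subject_id")
    frame = frame.merge(prs_vector.to_frame(), on="subject_id")
    return prepare_frame(frame)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return (and optionally write) the bundle.

    Identical seed and configuration produce a byte-identical bundle.  A
    stage failure aborts with the stage name in the error message and no
    partial output files are left behind (everything is computed first,
    written last).
    """
    config.validate()
    bundle: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "log": [],
    }
    log = bundle["log"]
    stage = "input"
    try:
        if config.sim is not None:
            subjects, genotypes, weights, _truth = generate_population(config.sim)
            pop_based = dict(zip(config.sim.study_names, config.sim.population_based))
            log.append(f"simulated {len(subjects)} subjects, seed {config.sim.seed}")
        else:
            stage = "validate_inputs"
            report = dio.validate_inputs(
                config.subject_path, config.genotype_path, config.weights_path
            )
            if not report.ok:
                raise ValidationError("; ".join(report.errors))
            log.extend(f"warning: {w}" for w in report.warnings)
            subjects = dio.read_subjects(config.subject_path)
            genotypes = dio.read_genotypes(config.genotype_path)
            weights = dio.read_weights(config.weights_path)
            pb = config.population_based_studies or ()
            pop_based = {s: s in pb for s in subjects["study"].unique()}

        stage = "study_subset"
        if config.population_based_only:
            keep = subjects["study"].map(pop_based).fillna(False).astype(bool)
            row_keep = keep.to_numpy()
            subjects = subjects.loc[keep].reset_index(drop=True)
            genotypes = GenotypeMatrix(
                subject_ids=genotypes.subject_ids[row_keep],
                snp_ids=genotypes.snp_ids,
                effect_allele=genotypes.effect_allele,
                other_allele=genotypes.other_allele,
                dosages=genotypes.dosages[row_keep],
                imputed=genotypes.imputed[row_keep],
            )
            log.append(
                f"restricted to population-based studies: {len(subjects)} subjects"
            )

        stage = "hwe_filter"
        n_missing_before = int(genotypes.missing_mask.sum())
        genotypes, exclusions = apply_hwe_filter(
            genotypes,
            study=subjects["study"],
            status=subjects["status"],
            threshold=config.hwe_threshold,
        )
        n_missing_after = int(genotypes.missing_mask.sum())
        log.append(
            f"HWE filter: {len(exclusions)} SNP x study blocks excluded "
            f"at P < {config.hwe_threshold}"
        )
        bundle["hwe_exclusions"] = [dataclasses.asdict(e) for e in exclusions]
        total = genotypes.dosages.size
        bundle["imputation_rate"] = n_missing_after / total
        log.append(
            f"genotypes to impute: {n_missing_after} of {total} "
            f"({100 * n_missing_after / total:.2f}%; {n_missing_before} missing, "
            f"{n_missing_after - n_missing_before} HWE-excluded)"
        )

        stage = "imputation"
        genotypes = impute_missing_mcmc(
            genotypes,
            age=subjects["age_years"],
            bmi=subjects["bmi"],
            seed=config.seed + 1,
        )

        stage = "prs"
        prs = build_prs_vector(genotypes, weights, subjects["status"], k=config.k_prs)

        stage = "density_adjustment"
        adjusted = make_adjusted_phenotypes(subjects, k=config.k_density)
        log.append(
            f"density adjustment: {adjusted.exclusions['n_used']} subjects used, "
            f"{adjusted.exclusions['missing_age']} missing age, "
            f"{adjusted.exclusions['missing_bmi']} missing BMI"
        )

        stage = "analysis_frame"
        frame = analysis_frame(subjects, adjusted, prs)
        bundle["n_cases"] = int((frame["status"] == 1).sum())
        bundle["n_controls"] = int((frame["status"] == 0).sum())

        stage = "main_effects"
        baseline = fit_logistic(frame, list(BASELINE_TERMS))
        per_sd = {}
        for name, col in (("pd", "adj_pd"), ("da", "adj_da"), ("prs", "prs_z")):
            fit = fit_logistic(frame, list(BASELINE_TERMS) + [col])
            tab = or_table(fit, [col])
            test = lrt(fit, baseline)
            per_sd[name] = {
                "OR": float(tab.loc[col, "OR"]),
                "L95": float(tab.loc[col, "L95"]),
                "U95": float(tab.loc[col, "U95"]),
                "lrt_vs_baseline": {"chi2": test.statistic, "df": test.df, "p": test.p_value},
            }
        bundle["per_sd_or"] = per_sd

        stage = "joint_continuous"
        joint = {}
        for name, col in (("pd", "adj_pd"), ("da", "adj_da")):
            fit = fit_joint_continuous(frame, col)
            tab = or_table(fit, [col, "prs_z"])
            joint[name] = {
                "OR_density_adj_prs": float(tab.loc[col, "OR"]),
                "OR_prs_adj_density": float(tab.loc["prs_z", "OR"]),
            }
        bundle["joint_continuous"] = joint

        stage = "categorical_tables"
        cat_tables = {}
        marginal_cat_ors = {}
        for name, col, k in (
            ("pd", "pd_quartile", config.k_density),
            ("da", "da_quartile", config.k_density),
            ("prs", "prs_quintile", config.k_prs),
        ):
            ref = 3 if name == "prs" else 2
            work = frame.copy()
            terms = []
            for lev in range(1, k + 1):
                if lev == ref:
                    continue
                cname = f"{col}[{lev}]"
                work[cname] = (work[col] == lev).astype(float)
                terms.append(cname)
            fit = fit_logistic(work, list(BASELINE_TERMS) + terms)
            tab = or_table(fit, terms)
            rows = []
            ors = {}
            for lev in range(1, k + 1):
                n_case = int(((frame[col] == lev) & (frame["status"] == 1)).sum())
                n_ctrl = int(((frame[col] == lev) & (frame["status"] == 0)).sum())
                if lev == ref:
                    rows.append(
                        {"category": lev, "n_case": n_case, "n_control": n_ctrl,
                         "OR": 1.0, "L95": np.nan, "U95": np.nan, "reference": True}
                    )
                    ors[lev] = 1.0
                else:
                    r = tab.loc[f"{col}[{lev}]"]
                    rows.append(
                        {"category": lev, "n_case": n_case, "n_control": n_ctrl,
                         "OR": float(r["OR"]), "L95": float(r["L95"]),
                         "U95": float(r["U95"]), "reference": False}
                    )
                    ors[lev] = float(r["OR"])
            cat_tables[name] = pd.DataFrame(rows)
            marginal_cat_ors[name] = ors
        bundle["categorical_tables"] = cat_tables

        stage = "joint_categorical"
        _, grid = fit_joint_categorical(frame)
        bundle["joint_grid"] = grid
        check = multiplicativity_product_check(
            marginal_cat_ors["pd"], marginal_cat_ors["prs"], grid
        )
        bundle["product_check"] = check

        stage = "interaction"
        inter_res = None
        if config.interaction:
            inter_res = interaction_test(frame, "adj_pd")
            bundle["interaction"] = {
                "or": inter_res["or_interaction"],
                "ci": list(inter_res["ci_interaction"]),
                "chi2": inter_res["lrt"].statistic,
                "df": inter_res["lrt"].df,
                "p": inter_res["lrt"].p_value,
            }

        stage = "goodness_of_fit"
        fit_null = fit_joint_continuous(frame, "adj_pd")
        hl = hosmer_lemeshow(fit_null, g=config.gof_deciles)
        tail = tail_based_gof(
            fit_null,
            tail_fractions=config.tail_fractions,
            n_null=config.gof_n_null,
            seed=config.seed + 2,
        )
        bundle["gof"] = {"hosmer_lemeshow": hl, "tail_based": tail}

        stage = "heterogeneity"
        het = {}
        for name, col in (("pd", "adj_pd"), ("da", "adj_da"), ("prs", "prs_z")):
            res = heterogeneity_by_study(frame, col)
            het[name] = {"chi2": res.statistic, "df": res.df, "p_het": res.p_value}
        bundle["heterogeneity"] = het

        stage = "confounders"
        if config.confounders:
            bundle["confounder_sensitivity"] = confounder_sensitivity(
                frame, ["adj_pd", "adj_da", "prs_z"], list(config.confounders)
            )

        stage = "multiplicativity_report"
        bundle["multiplicativity"] = multiplicativity_report(
            inter_res["lrt"] if inter_res else None,
            hl,
            tail,
            interaction_or=inter_res["or_interaction"] if inter_res else None,
            interaction_ci=inter_res["ci_interaction"] if inter_res else None,
            product_check=check,
        )

        bundle["subjects"] = subjects
        bundle["genotypes"] = genotypes
        bundle["weights"] = weights
        bundle["adjusted"] = adjusted
        bundle["prs"] = prs
        bundle["frame"] = frame
    except DensPrsError as exc:
        raise DensPrsError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if config.outdir is not None:
        _write_bundle(bundle, config)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    try:
        _w(outdir / "subjects.tsv", lambda p: dio.write_subjects(bundle["subjects"], p))
        _w(outdir / "weights.tsv", lambda p: dio.write_weights(bundle["weights"], p))
        _w(
            outdir / "adjusted_phenotypes.tsv",
            lambda p: bundle["adjusted"].frame.to_csv(p, sep="\t", index=False, float_format="%.10g"),
        )
        _w(
            outdir / "adjustment_coefficients.json",
            lambda p: p.write_text(
                json.dumps(bundle["adjusted"].coefficients, indent=2, sort_keys=True)
            ),
        )
        _w(
            outdir / "prs.tsv",
            lambda p: bundle["prs"].to_frame().to_csv(p, sep="\t", index=False, float_format="%.10g"),
        )
        for name, tab in bundle["categorical_tables"].items():
            _w(
                outdir / f"or_table_{name}.tsv",
                lambda p, t=tab: t.to_csv(p, sep="\t", index=False, float_format="%.10g"),
            )
        _w(
            outdir / "joint_grid.tsv",
            lambda p: bundle["joint_grid"].to_csv(p, sep="\t", index=False, float_format="%.10g"),
        )
        for key in ("hosmer_lemeshow", "tail_based"):
            _w(
                outdir / f"gof_{key}.json",
                lambda p, k=key: p.write_text(
                    bundle["gof"][k].to_json(indent=2, sort_keys=True, default=_json_default)
                ),
            )
        summary = {
            k: bundle[k]
            for k in (
                "seed",
                "config_hash",
                "log",
                "n_cases",
                "n_controls",
                "hwe_exclusions",
                "imputation_rate",
                "per_sd_or",
                "joint_continuous",
                "heterogeneity",
                "multiplicativity",
            )
            if k in bundle
        }
        if "interaction" in bundle:
            summary["interaction"] = bundle["interaction"]
        if "confounder_sensitivity" in bundle:
            summary["confounder_sensitivity"] = bundle[
                "confounder_sensitivity"
            ].reset_index().to_dict(orient="records")
        _w(
            outdir / "report.json",
            lambda p: p.write_text(
                json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
            ),
        )
    except Exception:
        for p in written:  # never leave a partial bundle behind
            p.unlink(missing_ok=True)
        raise
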