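"""Genotype handling and polygenic-risk-score construction.

This module covers the score-construction stage of the analysis:
Hardy-Weinberg equilibrium (HWE) filtering of SNP x study blocks, a
simple MCMC imputation of missing or excluded dosages, the weighted-sum
polygenic risk score (PRS), control-based standardization, and
control-quantile category assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "GenotypeMatrix",
    "PRSWeights",
    "PrsVector",
    "HweResult",
    "HweExclusion",
    "hwe_test",
    "genotype_counts",
    "apply_hwe_filter",
    "impute_missing_mcmc",
    "compute_prs",
    "standardize_by_controls",
    "assign_quantile_categories",
    "format_cutpoints",
    "build_prs_vector",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix with missingness and imputation flags.

    Dosages count copies of the per-SNP effect allele and live in [0, 2];
    ``nan`` marks a missing entry.  Observed dosages are integers
    {0, 1, 2}; imputed entries may be fractional (posterior-mean dosages).
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    dosages: np.ndarray  # float (n_subjects, n_snps), nan = missing
    imputed: np.ndarray | None = None  # bool, same shape

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.effect_allele = np.asarray(self.effect_allele)
        self.other_allele = np.asarray(self.other_allele)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0, 2] at subject {self.subject_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}: {self.dosages[i, j]}"
            )
        if self.imputed is None:
            self.imputed = np.zeros(self.dosages.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            subject_ids=self.subject_ids.copy(),
            snp_ids=self.snp_ids.copy(),
            effect_allele=self.effect_allele.copy(),
            other_allele=self.other_allele.copy(),
            dosages=self.dosages.copy(),
            imputed=self.imputed.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: subject_id plus one dosage column per SNP."""
        df = pd.DataFrame(self.dosages, columns=list(self.snp_ids))
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class PRSWeights:
    """Per-SNP PRS weights: published per-allele log odds ratios."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, other_allele, weight_log_or

    REQUIRED = ("snp_id", "effect_allele", "other_allele", "weight_log_or")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"weights table lacks columns {missing}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValidationError(f"duplicate snp_id in weights: {dups}")
        w = self.table["weight_log_or"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite PRS weight")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight_log_or"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PrsVector:
    """Per-subject polygenic risk score in raw and control-SD units."""

    subject_ids: np.ndarray
    raw: np.ndarray
    standardized: np.ndarray
    quantile: np.ndarray  # 1..k labels
    cutpoints: np.ndarray  # control-quantile boundaries, length k-1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "prs_raw": self.raw,
                "prs_z": self.standardized,
                "prs_quintile": self.quantile,
            }
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


class HweResult(NamedTuple):
    statistic: float
    p_value: float
    monomorphic: bool


def hwe_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> HweResult:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg proportions.

    Compares observed genotype counts (effect-allele homozygote,
    heterozygote, other homozygote) with the p^2 / 2pq / q^2 expectation
    at the sample allele frequency.  A monomorphic SNP admits no test and
    is returned with ``p_value = 1`` and the ``monomorphic`` flag set.
    """
    counts = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("at least one genotype observation required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(0.0, 1.0, True)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return HweResult(stat, float(stats.chi2.sf(stat, df=1)), False)


def genotype_counts(dosages_1d: np.ndarray) -> tuple[int, int, int]:
    """Counts of (2, 1, 0) dosages among observed integer entries."""
    x = np.asarray(dosages_1d, dtype=float)
    x = x[~np.isnan(x)]
    # imputed fractional values carry no genotype information for HWE
    x = x[x == np.round(x)]
    return int((x == 2).sum()), int((x == 1).sum()), int((x == 0).sum())


@dataclass
class HweExclusion:
    snp_id: str
    study: str
    p_value: float
    n_masked: int


def apply_hwe_filter(
    genotypes: GenotypeMatrix,
    study: Sequence,
    status: Sequence | None = None,
    threshold: float = 1e-3,
    controls_only: bool = True,
    per_study: bool = True,
) -> tuple[GenotypeMatrix, list[HweExclusion]]:
    """Mask SNP x study blocks that fail the HWE test at ``threshold``.

    The test is computed among controls (``controls_only``) separately per
    study (``per_study``), the convention of array-QC pipelines; failing
    blocks are set to missing across *all* subjects of that study so the
    imputation step replaces them.  Returns the filtered matrix and a log
    of exclusions.  ``threshold = 0`` excludes nothing.
    """
    study = np.asarray(study)
    if len(study) != genotypes.n_subjects:
        raise ValidationError("study labels do not align with genotype rows")
    status_arr = None
    if status is not None:
        status_arr = np.asarray(status)
        if len(status_arr) != genotypes.n_subjects:
            raise ValidationError("status does not align with genotype rows")
    out = genotypes.copy()
    exclusions: list[HweExclusion] = []
    blocks = (
        [(s, study == s) for s in pd.unique(study)]
        if per_study
        else [("all", np.ones(genotypes.n_subjects, dtype=bool))]
    )
    for label, block in blocks:
        test_rows = block
        if controls_only and status_arr is not None:
            test_rows = block & (status_arr == 0)
        for j, snp in enumerate(out.snp_ids):
            n2, n1, n0 = genotype_counts(out.dosages[test_rows, j])
            if n2 + n1 + n0 == 0:
                continue
            res = hwe_test(n2, n1, n0)
            if not res.monomorphic and res.p_value < threshold:
                n_masked = int(block.sum())
                out.dosages[block, j] = np.nan
                exclusions.append(
                    HweExclusion(str(snp), str(label), res.p_value, n_masked)
                )
    return out, exclusions


# ---------------------------------------------------------------------------
# MCMC imputation
# ---------------------------------------------------------------------------


def impute_missing_mcmc(
    genotypes: GenotypeMatrix,
    age: Sequence | None = None,
    bmi: Sequence | None = None,
    n_burn: int = 10,
    n_draws: int = 20,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simple MCMC imputation of missing dosages.

    Each SNP's missing entries are imputed from a linear predictor on the
    other SNPs' current dosages plus age and BMI (risk factors).  Case
    status is deliberately excluded from the predictors so that imputation
    cannot leak the outcome into the risk score.

    Scheme: per-SNP regression coefficients are estimated once by least
    squares on mean-initialised data; a Gibbs sampler then alternates
    draws of every missing entry for ``n_burn + n_draws`` sweeps, each
    draw Binomial(2, mu/2) where mu is the entry's current linear
    predictor (a linear-probability conditional, so draws are valid
    dosages and their mean is the predictor itself — under MCAR the mean
    imputed dosage is unbiased for 2*MAF).  The imputed value is the mean
    of the post-burn-in draws.  Observed entries are never modified.
    """
    miss = genotypes.missing_mask
    if not miss.any():
        return genotypes.copy()
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = list(genotypes.snp_ids[all_missing])
        raise ValidationError(f"SNPs with no observed dosage cannot be imputed: {bad}")

    n, s = genotypes.dosages.shape
    rng = np.random.default_rng(seed)

    covs = []
    if age is not None:
        covs.append(np.asarray(age, dtype=float))
    if bmi is not None:
        covs.append(np.asarray(bmi, dtype=float))
    for c in covs:
        if len(c) != n:
            raise ValidationError("covariate does not align with genotype rows")

    # design: intercept | dosages (mean-initialised) | covariates
    col_means = np.nanmean(genotypes.dosages, axis=0)
    D = np.where(miss, col_means, genotypes.dosages)
    Z = np.column_stack([np.ones(n), D] + covs)
    p = Z.shape[1]
    snp_cols = np.arange(1, 1 + s)

    # one Gram matrix serves all per-SNP regressions
    G = Z.T @ Z
    betas = np.zeros((s, p - 1))
    eye = np.eye(p - 1)
    for j in range(s):
        k = snp_cols[j]
        others = np.delete(np.arange(p), k)
        A = G[np.ix_(others, others)] + 1e-8 * eye
        betas[j] = np.linalg.solve(A, G[others, k])

    miss_rows = [np.flatnonzero(miss[:, j]) for j in range(s)]
    others_idx = [np.delete(np.arange(p), snp_cols[j]) for j in range(s)]
    sums = np.zeros(genotypes.dosages.shape)
    for sweep in range(n_burn + n_draws):
        for j in range(s):
            rows = miss_rows[j]
            if rows.size == 0:
                continue
            mu = Z[np.ix_(rows, others_idx[j])] @ betas[j]
            prob = np.clip(mu / 2.0, 0.0, 1.0)
            draw = rng.binomial(2, prob).astype(float)
            Z[rows, snp_cols[j]] = draw
            if sweep >= n_burn:
                sums[rows, j] += draw

    out = genotypes.copy()
    out.dosages[miss] = (sums / n_draws)[miss]
    out.imputed = miss | genotypes.imputed
    return out


# ---------------------------------------------------------------------------
# PRS
# ---------------------------------------------------------------------------


def compute_prs(genotypes: GenotypeMatrix, weights: PRSWeights) -> np.ndarray:
    """Weighted allele-dosage sum: PRS_i = sum_k beta_k x_ik.

    Dosages must be complete (impute first).  SNPs are matched by id in
    the weights order; a dosage column oriented to the non-effect allele
    is flipped to ``2 - x`` before summing.
    """
    if genotypes.missing_mask.any():
        n_miss = int(genotypes.missing_mask.sum())
        raise ValidationError(
            f"compute_prs requires a complete matrix; {n_miss} entries missing"
        )
    index = {snp: j for j, snp in enumerate(genotypes.snp_ids)}
    absent = [snp for snp in weights.snp_ids if snp not in index]
    if absent:
        raise ValidationError(f"weights SNPs absent from genotype matrix: {absent}")
    cols = np.array([index[snp] for snp in weights.snp_ids])
    D = genotypes.dosages[:, cols]
    ea = genotypes.effect_allele[cols]
    oa = genotypes.other_allele[cols]
    wea = weights.table["effect_allele"].to_numpy()
    woa = weights.table["other_allele"].to_numpy()
    same = (ea == wea) & (oa == woa)
    flipped = (ea == woa) & (oa == wea)
    mismatch = ~(same | flipped)
    if mismatch.any():
        bad = list(np.asarray(weights.snp_ids)[mismatch])
        raise ValidationError(f"allele labels irreconcilable for SNPs: {bad}")
    D = np.where(flipped, 2.0 - D, D)
    return D @ weights.weights


def standardize_by_controls(values: Sequence, status: Sequence) -> np.ndarray:
    """Scale values to control-group SD units: (x - mean_ctrl) / sd_ctrl."""
    x = np.asarray(values, dtype=float)
    st = np.asarray(status)
    ctrl = x[(st == 0) & np.isfinite(x)]
    if len(ctrl) < 2:
        raise ValidationError("need at least two controls with finite values")
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise ValidationError("control standard deviation is zero")
    return (x - ctrl.mean()) / sd


def assign_quantile_categories(
    values: Sequence, status: Sequence, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assign categories 1..k from control-group quantile cutpoints.

    Intervals are right-closed; values below the first cutpoint fall in
    bin 1 and above the last in bin k, so cases outside the control range
    are absorbed by the extreme bins.  Control counts per bin are equal
    within +/-1.  Returns (labels, cutpoints).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in quantile assignment")
    st = np.asarray(status)
    ctrl = x[st == 0]
    if len(ctrl) < k:
        raise ValidationError(f"need at least {k} controls for {k} categories")
    cut = np.quantile(ctrl, np.arange(1, k) / k)
    if ctrl.min() == ctrl.max() or np.any(np.diff(cut) <= 0):
        raise ValidationError("degenerate cutpoints: values too heavily tied")
    labels = 1 + np.searchsorted(cut, x, side="left")
    return labels.astype(int), cut


def format_cutpoints(cutpoints: np.ndarray, values: Sequence, name: str = "quantile") -> str:
    """Human-readable category boundaries, e.g. 'quintile 1, -1.411 to -0.014; ...'."""
    x = np.asarray(values, dtype=float)
    bounds = np.concatenate([[x.min()], np.asarray(cutpoints), [x.max()]])
    parts = [
        f"{name} {i + 1}, {bounds[i]:.3f} to {bounds[i + 1]:.3f}"
        for i in range(len(bounds) - 1)
    ]
    return "; ".join(parts)


def build_prs_vector(
    genotypes: GenotypeMatrix,
    weights: PRSWeights,
    status: Sequence,
    k: int = 5,
) -> PrsVector:
    """Full score stage: weighted sum, control-SD scaling, control quintiles."""
    raw = compute_prs(genotypes, weights)
    z = standardize_by_controls(raw, status)
    labels, cut = assign_quantile_categories(z, status, k)
    return PrsVector(
        subject_ids=genotypes.subject_ids.copy(),
        raw=raw,
        standardized=z,
        quantile=labels,
        cutpoints=cut,
    )
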