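"""Synthetic case-control generator.

Emulates the statistical structure of a multi-study breast-cancer
case-control analysis of mammographic density and a 77-SNP polygenic
risk score (PRS):

* eight studies (six population based) with fixed case/control counts;
* 77 independent biallelic SNPs drawn in Hardy-Weinberg equilibrium,
  Binomial(2, MAF) per SNP;
* a density phenotype generated on the square-root-area scale with
  age, 1/BMI and study structure plus a latent component correlated
  with the PRS (calibrated to a target control-group correlation);
* disease sampled from a multiplicative logistic model on the latent
  standardized adjusted density and the standardized PRS, with an
  optional interaction term, the intercept solved to hit a target
  population prevalence;
* case-control subsampling to the requested per-study counts.

The generator keeps a :class:`TruthRecord` of the latent variables it
used; analysis stages never read it — it exists only so tests can score
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from . import reference
from .exceptions import SimulationError, ValidationError
from .genotypes import GenotypeMatrix, PRSWeights

__all__ = [
    "SimConfig",
    "TruthRecord",
    "default_config",
    "scaled_config",
    "generate_population",
    "inject_missingness",
    "perturb_hwe",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "study",
    "status",
    "age_years",
    "bmi",
    "pd_percent",
    "da_cm2",
    "total_area_cm2",
    "parity",
    "menopause",
    "family_history",
    "ht_use",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic case-control generator.

    Defaults reproduce the study conditions the package emulates: eight
    studies totalling 3628 cases / 5126 controls (six population-based
    studies contributing 2439 / 3895), 77 SNPs, per-SD odds ratios 1.45
    (adjusted percent density), 1.34 (adjusted dense area) and 1.52
    (PRS), a control-group PRS-density correlation of 0.06, and 1.1%
    genotype missingness.
    """

    study_names: tuple[str, ...] = reference.DEFAULT_STUDY_NAMES
    population_based: tuple[bool, ...] = reference.DEFAULT_POPULATION_BASED
    cases_per_study: tuple[int, ...] = reference.DEFAULT_CASES_PER_STUDY
    controls_per_study: tuple[int, ...] = reference.DEFAULT_CONTROLS_PER_STUDY

    n_snps: int = 77
    maf: np.ndarray | None = None  # drawn U(0.05, 0.5) per seed when None
    weights: np.ndarray | None = None  # drawn +/-U(log 1.02, log 1.26) per seed

    beta_pd: float = field(default_factory=lambda: float(np.log(reference.OR_PER_SD_ADJUSTED_PD)))
    beta_da: float = field(default_factory=lambda: float(np.log(reference.OR_PER_SD_ADJUSTED_DA)))
    beta_prs: float = field(default_factory=lambda: float(np.log(reference.OR_PER_SD_PRS)))
    theta_int: float = 0.0
    interaction_region: str = "global"  # or "upper_tail": interaction only
    # beyond the 90th percentile of both factors

    # which density measure carries the latent sqrt-scale structure and
    # drives the disease model ("pd" or "da"); the other is derived from it
    density_phenotype: str = "pd"

    rho_prs_density: float = reference.CORR_PRS_ADJUSTED_PD

    age_mean: float = 62.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 85.0)
    bmi_logmean: float = field(default_factory=lambda: float(np.log(26.0)))
    bmi_logsd: float = 0.15
    bmi_range: tuple[float, float] = (17.0, 45.0)

    # sqrt-scale density model
    sqrt_pd_intercept: float = 5.0
    sqrt_da_intercept: float = 6.3
    age_slope: float = -0.03  # per year, sqrt scale
    inv_bmi_slope: float = 40.0  # per unit 1/BMI, sqrt scale
    study_effect_sd: float = 0.5
    residual_sd: float = 1.5
    total_area_mean: float = 175.0
    total_area_sd: float = 40.0

    missing_rate: float = 0.011
    prevalence: float = 0.10
    oversample: float = 1.4  # population head-room over the minimum size
    seed: int = 0

    def validate(self) -> None:
        k = len(self.study_names)
        if not (
            len(self.population_based)
            == len(self.cases_per_study)
            == len(self.controls_per_study)
            == k
        ):
            raise ValidationError("per-study fields must have equal length")
        if self.maf is not None:
            m = np.asarray(self.maf, dtype=float)
            if len(m) != self.n_snps or np.any(m <= 0) or np.any(m > 0.5):
                raise ValidationError("maf must have length n_snps with values in (0, 0.5]")
        if self.weights is not None and len(np.asarray(self.weights)) != self.n_snps:
            raise ValidationError("weights must have length n_snps")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not -1 < self.rho_prs_density < 1:
            raise ValidationError("rho_prs_density must be in (-1, 1)")
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")
        if self.density_phenotype not in ("pd", "da"):
            raise ValidationError("density_phenotype must be 'pd' or 'da'")
        if self.interaction_region not in ("global", "upper_tail"):
            raise ValidationError("interaction_region must be 'global' or 'upper_tail'")

    def resolved_snp_params(self) -> tuple[np.ndarray, np.ndarray]:
        """MAFs and weights, drawing seed-stable defaults when unset."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 77]))
        if self.maf is None:
            maf = rng.uniform(0.05, 0.5, self.n_snps)
        else:
            maf = np.asarray(self.maf, dtype=float)
            rng.uniform(0.05, 0.5, self.n_snps)  # keep stream aligned
        if self.weights is None:
            mag = rng.uniform(np.log(1.02), np.log(1.26), self.n_snps)
            sign = rng.choice([-1.0, 1.0], self.n_snps)
            weights = mag * sign
        else:
            weights = np.asarray(self.weights, dtype=float)
        return maf, weights


@dataclass
class TruthRecord:
    """Latent generative state; for test scoring only, never for analysis."""

    z_density: np.ndarray  # standardized latent adjusted density, sampled subjects
    prs_z: np.ndarray  # standardized true PRS, sampled subjects
    intercept: float
    gamma: float
    realized_prevalence: float
    config: SimConfig


def default_config(**overrides) -> SimConfig:
    return replace(SimConfig(), **overrides)


def scaled_config(n_cases: int, n_controls: int, **overrides) -> SimConfig:
    """Default study layout rescaled to the requested totals.

    Per-study counts are allocated proportionally to the default design
    (largest-remainder rounding), so the eight-study structure is kept.
    """
    base = SimConfig()

    def allocate(total: int, shares: Sequence[int]) -> tuple[int, ...]:
        shares = np.asarray(shares, dtype=float)
        exact = total * shares / shares.sum()
        out = np.floor(exact).astype(int)
        rem = total - out.sum()
        order = np.argsort(exact - np.floor(exact))[::-1]
        out[order[:rem]] += 1
        return tuple(int(v) for v in out)

    cfg = replace(
        base,
        cases_per_study=allocate(n_cases, base.cases_per_study),
        controls_per_study=allocate(n_controls, base.controls_per_study),
    )
    return replace(cfg, **overrides)


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_characteristics(rng, status, menopause_post):
    """Binary covariates with case-dependent margins matching the published
    characteristic table, including its missing-data fractions."""
    n = len(status)
    out = {}
    spec = {
        "parity": ("parous", {"parous": 1.0, "nulliparous": 0.0, "unknown": np.nan}),
        "family_history": ("yes", {"yes": 1.0, "no": 0.0, "unknown": np.nan}),
    }
    for name, (_, coding) in spec.items():
        vals = np.full(n, np.nan)
        for grp, grp_label in ((1, "case"), (0, "control")):
            rows = np.flatnonzero(status == grp)
            fr = reference.characteristic_fractions(name, grp_label)
            levels = list(fr)
            draw = rng.choice(len(levels), size=len(rows), p=[fr[l] for l in levels])
            vals[rows] = np.array([coding[l] for l in levels])[draw]
        out[name] = vals
    # HT use defined among postmenopausal women only
    ht = np.full(n, np.nan)
    for grp, grp_label in ((1, "case"), (0, "control")):
        rows = np.flatnonzero((status == grp) & (menopause_post == 1))
        fr = reference.characteristic_fractions("ht_use", grp_label)
        levels = list(fr)
        coding = {"ever": 1.0, "never": 0.0, "unknown": np.nan}
        draw = rng.choice(len(levels), size=len(rows), p=[fr[l] for l in levels])
        ht[rows] = np.array([coding[l] for l in levels])[draw]
    out["ht_use"] = ht
    return out


def _draw_menopause(rng, status):
    n = len(status)
    vals = np.full(n, np.nan)
    for grp, grp_label in ((1, "case"), (0, "control")):
        rows = np.flatnonzero(status == grp)
        fr = reference.characteristic_fractions("menopause", grp_label)
        levels = list(fr)
        coding = {"post": 1.0, "pre": 0.0, "unknown": np.nan}
        draw = rng.choice(len(levels), size=len(rows), p=[fr[l] for l in levels])
        vals[rows] = np.array([coding[l] for l in levels])[draw]
    return vals


def generate_population(
    config: SimConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, PRSWeights, TruthRecord]:
    """Generate one case-control dataset under ``config``.

    Returns ``(subjects, genotypes, weights, truth)``: the subject table
    (one row per sampled subject), the dosage matrix with missingness
    already injected at ``config.missing_rate``, the PRS weights table,
    and the latent truth record.

    Raises :class:`SimulationError` when a study cannot supply the
    requested number of cases or controls at the configured prevalence.
    """
    config.validate()
    maf, weights_vec = config.resolved_snp_params()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_pop, rng_outcome, rng_covar, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n_studies = len(config.study_names)
    study_effects = rng_struct.normal(0.0, config.study_effect_sd, n_studies)

    # population sizes per study, with head-room over the binomial minimum
    pops = []
    for c, k in zip(config.cases_per_study, config.controls_per_study):
        need = max(c / config.prevalence, k / (1.0 - config.prevalence))
        pops.append(int(np.ceil(config.oversample * need)) + 100)
    study_idx = np.repeat(np.arange(n_studies), pops)
    n = len(study_idx)

    age = _truncated_normal(rng_pop, config.age_mean, config.age_sd, *config.age_range, n)
    log_bmi = _truncated_normal(
        rng_pop,
        config.bmi_logmean,
        config.bmi_logsd,
        np.log(config.bmi_range[0]),
        np.log(config.bmi_range[1]),
        n,
    )
    bmi = np.exp(log_bmi)

    genotypes = rng_pop.binomial(2, maf, size=(n, config.n_snps)).astype(np.int8)
    prs_raw = genotypes @ weights_vec
    prs_mean = 2.0 * maf @ weights_vec
    prs_sd = np.sqrt(np.sum(weights_vec**2 * 2.0 * maf * (1.0 - maf)))
    prs_z = (prs_raw - prs_mean) / prs_sd

    # latent adjusted density on the sqrt scale: latent = gamma * PRS_z + eps.
    # rho_prs_density targets the CONTROL-group correlation (the published
    # quantity), which case-control selection pulls below the population
    # correlation gamma / sqrt(gamma^2 + sigma^2); gamma is therefore solved
    # against the control-weighted correlation (weights 1 - P(case)).
    eps = rng_pop.normal(0.0, config.residual_sd, n)
    beta_density = config.beta_pd if config.density_phenotype == "pd" else config.beta_da

    def control_corr_excess(gamma_try: float) -> float:
        lat = gamma_try * prs_z + eps
        zd = lat / np.sqrt(gamma_try**2 + config.residual_sd**2)
        if config.interaction_region == "global":
            it = zd * prs_z
        else:
            hot = (zd > np.quantile(zd, 0.9)) & (prs_z > np.quantile(prs_z, 0.9))
            it = np.where(hot, zd * prs_z, 0.0)
        e0 = beta_density * zd + config.beta_prs * prs_z + config.theta_int * it
        b = brentq(lambda b0_: float(np.mean(expit(b0_ + e0))) - config.prevalence, -25.0, 10.0)
        w = 1.0 - expit(b + e0)
        mz, mp = np.average(zd, weights=w), np.average(prs_z, weights=w)
        cov = np.average((zd - mz) * (prs_z - mp), weights=w)
        sd = np.sqrt(
            np.average((zd - mz) ** 2, weights=w)
            * np.average((prs_z - mp) ** 2, weights=w)
        )
        return cov / sd - config.rho_prs_density

    rho = config.rho_prs_density
    gamma0 = config.residual_sd * rho / np.sqrt(1.0 - rho**2)  # population solution
    if rho == 0.0:
        gamma = 0.0
    else:
        span = 0.5 * config.residual_sd
        lo = max(gamma0 - span, -0.99 * config.residual_sd * 5)
        gamma = brentq(control_corr_excess, lo, gamma0 + span)
    latent = gamma * prs_z + eps
    latent_sd = np.sqrt(gamma**2 + config.residual_sd**2)
    z_density = latent / latent_sd

    if config.density_phenotype == "pd":
        icept = config.sqrt_pd_intercept
    else:
        icept = config.sqrt_da_intercept
    sqrt_meas = (
        icept
        + config.age_slope * (age - 60.0)
        + config.inv_bmi_slope * (1.0 / bmi - 1.0 / 26.0)
        + study_effects[study_idx]
        + latent
    )

    if config.density_phenotype == "pd":
        sqrt_pd = np.clip(sqrt_meas, 0.0, 10.0)
        pd_percent = sqrt_pd**2
        total = _truncated_normal(
            rng_pop, config.total_area_mean, config.total_area_sd, 60.0, np.inf, n
        )
        da = pd_percent / 100.0 * total
    else:
        sqrt_da = np.clip(sqrt_meas, 0.0, None)
        da = sqrt_da**2
        nondense = _truncated_normal(
            rng_pop, config.total_area_mean - 40.0, config.total_area_sd, 10.0, np.inf, n
        )
        total = da + nondense
        pd_percent = 100.0 * da / total

    if config.interaction_region == "global":
        inter = z_density * prs_z
    else:
        hot = (z_density > np.quantile(z_density, 0.9)) & (
            prs_z > np.quantile(prs_z, 0.9)
        )
        inter = np.where(hot, z_density * prs_z, 0.0)
    eta0 = beta_density * z_density + config.beta_prs * prs_z + config.theta_int * inter

    def excess(b0: float) -> float:
        return float(np.mean(expit(b0 + eta0))) - config.prevalence

    b0 = brentq(excess, -25.0, 10.0)
    y = (rng_outcome.random(n) < expit(b0 + eta0)).astype(int)

    # per-study case-control subsampling
    keep = []
    for s in range(n_studies):
        in_study = study_idx == s
        for want, label, mask in (
            (config.cases_per_study[s], "cases", in_study & (y == 1)),
            (config.controls_per_study[s], "controls", in_study & (y == 0)),
        ):
            avail = np.flatnonzero(mask)
            if len(avail) < want:
                raise SimulationError(
                    f"study {config.study_names[s]}: requested {want} {label} "
                    f"but only {len(avail)} generated at prevalence "
                    f"{config.prevalence} (population {pops[s]}); "
                    f"short by {want - len(avail)}"
                )
            keep.append(rng_outcome.choice(avail, size=want, replace=False))
    sel = np.sort(np.concatenate(keep))

    status = y[sel]
    menopause = _draw_menopause(rng_covar, status)
    chars = _draw_characteristics(rng_covar, status, menopause)

    subjects = pd.DataFrame(
        {
            "subject_id": np.array([f"id{i:07d}" for i in sel]),
            "study": np.asarray(config.study_names)[study_idx[sel]],
            "status": status,
            "age_years": age[sel],
            "bmi": bmi[sel],
            "pd_percent": pd_percent[sel],
            "da_cm2": da[sel],
            "total_area_cm2": total[sel],
            "parity": chars["parity"],
            "menopause": menopause,
            "family_history": chars["family_history"],
            "ht_use": chars["ht_use"],
        }
    )

    snp_ids = np.array([f"snp{j + 1:03d}" for j in range(config.n_snps)])
    gm = GenotypeMatrix(
        subject_ids=subjects["subject_id"].to_numpy(),
        snp_ids=snp_ids,
        effect_allele=np.repeat("A", config.n_snps),
        other_allele=np.repeat("G", config.n_snps),
        dosages=genotypes[sel].astype(float),
    )
    if config.missing_rate > 0:
        gm = inject_missingness(gm, config.missing_rate, seed=int(rng_miss.integers(2**31)))

    weights_table = PRSWeights(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "effect_allele": "A",
                "other_allele": "G",
                "weight_log_or": weights_vec,
            }
        )
    )
    truth = TruthRecord(
        z_density=z_density[sel],
        prs_z=prs_z[sel],
        intercept=b0,
        gamma=gamma,
        realized_prevalence=float(y.mean()),
        config=config,
    )
    return subjects, gm, weights_table, truth


def inject_missingness(genotypes: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set dosages missing completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValidationError("rate must be in [0, 1)")
    out = genotypes.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.dosages.shape) < rate
    out.dosages[mask] = np.nan
    return out


def perturb_hwe(
    genotypes: GenotypeMatrix,
    snp_index: int,
    inbreeding_coefficient: float,
    seed: int = 0,
    subject_mask: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Redraw one SNP's genotypes under an inbreeding model.

    Genotype frequencies become p^2 + pqF / 2pq(1-F) / q^2 + pqF at the
    SNP's current sample allele frequency, so the SNP departs from
    Hardy-Weinberg proportions by the amount F.  ``subject_mask``
    restricts the perturbation to a subset (e.g. one study).  F = 0 is a
    no-op; F = 1 eliminates heterozygotes.
    """
    if not 0 <= inbreeding_coefficient <= 1:
        raise ValueError("inbreeding coefficient must be in [0, 1]")
    if not 0 <= snp_index < genotypes.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range")
    out = genotypes.copy()
    if inbreeding_coefficient == 0:
        return out
    rows = (
        np.arange(out.n_subjects)
        if subject_mask is None
        else np.flatnonzero(np.asarray(subject_mask, dtype=bool))
    )
    col = out.dosages[rows, snp_index]
    obs = col[~np.isnan(col)]
    p = float(obs.mean()) / 2.0
    q = 1.0 - p
    f = inbreeding_coefficient
    probs = np.array([q * q + p * q * f, 2 * p * q * (1 - f), p * p + p * q * f])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draw = rng.choice([0.0, 1.0, 2.0], size=len(rows), p=probs)
    draw[np.isnan(col)] = np.nan  # preserve the missingness pattern
    out.dosages[rows, snp_index] = draw
    return out
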