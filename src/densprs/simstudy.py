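"""Replicated simulation studies over the full pipeline.

Drivers for the package's own calibration experiments: parameter
recovery of the headline per-SD odds ratios, control-group correlation
calibration, multiplicative closure of the joint category grid, and
type-I error of the interaction and goodness-of-fit tests under the
multiplicative null.  Both the test suite and the reproduction script
run these; they exist in the package so the experiments are one function
call away for users too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density import make_adjusted_phenotypes
from .genotypes import apply_hwe_filter, build_prs_vector, impute_missing_mcmc
from .gof import hosmer_lemeshow, tail_based_gof
from .models import (
    BASELINE_TERMS,
    fit_joint_categorical,
    fit_joint_continuous,
    fit_logistic,
    interaction_test,
    multiplicativity_product_check,
)
from .pipeline import analysis_frame
from .simulate import generate_population, scaled_config

__all__ = [
    "replicate_seeds",
    "prepare_analysis_frame",
    "marginal_categorical_ors",
    "recovery_replicate",
    "recovery_study",
    "control_correlation",
    "null_calibration_replicate",
]


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def prepare_analysis_frame(config) -> pd.DataFrame:
    """Generate one dataset and run the full pre-model pipeline on it."""
    subjects, genotypes, weights, _ = generate_population(config)
    genotypes, _ = apply_hwe_filter(genotypes, subjects["study"], subjects["status"])
    genotypes = impute_missing_mcmc(
        genotypes, subjects["age_years"], subjects["bmi"], seed=config.seed + 1
    )
    prs = build_prs_vector(genotypes, weights, subjects["status"])
    adjusted = make_adjusted_phenotypes(subjects)
    return analysis_frame(subjects, adjusted, prs)


def marginal_categorical_ors(frame: pd.DataFrame, col: str, k: int, ref: int) -> dict[int, float]:
    work = frame.copy()
    terms = []
    for lev in range(1, k + 1):
        if lev == ref:
            continue
        name = f"{col}[{lev}]"
        work[name] = (work[col] == lev).astype(float)
        terms.append(name)
    fit = fit_logistic(work, list(BASELINE_TERMS) + terms)
    return {
        lev: (1.0 if lev == ref else fit.odds_ratio(f"{col}[{lev}]"))
        for lev in range(1, k + 1)
    }


def control_correlation(frame: pd.DataFrame, density_col: str = "adj_pd") -> float:
    ctrl = frame[frame["status"] == 0]
    return float(np.corrcoef(ctrl[density_col], ctrl["prs_z"])[0, 1])


def recovery_replicate(
    seed: int,
    phenotype: str = "pd",
    n_cases: int = 20_000,
    n_controls: int = 20_000,
    grid: bool = False,
) -> dict:
    """One parameter-recovery replicate at the study's generative effects.

    Generates a case-control dataset whose disease model uses the chosen
    density phenotype, runs the whole pipeline, and fits the joint
    continuous main-effects model.  Returns the per-SD ORs for the
    density measure and the PRS, the control-group correlation, and
    (optionally) the corner ratios joint-OR / product-of-marginals of the
    4 x 5 category grid.
    """
    config = scaled_config(n_cases, n_controls, seed=seed, density_phenotype=phenotype)
    frame = prepare_analysis_frame(config)
    density_col = "adj_pd" if phenotype == "pd" else "adj_da"
    fit = fit_joint_continuous(frame, density_col)
    out = {
        "seed": seed,
        "or_density": fit.odds_ratio(density_col),
        "or_prs": fit.odds_ratio("prs_z"),
        "control_corr": control_correlation(frame),
    }
    if grid:
        d_ors = marginal_categorical_ors(frame, "pd_quartile", 4, 2)
        p_ors = marginal_categorical_ors(frame, "prs_quintile", 5, 3)
        _, grid_tab = fit_joint_categorical(frame)
        check = multiplicativity_product_check(d_ors, p_ors, grid_tab)
        out["grid_ratios"] = {
            (int(r["density_cat"]), int(r["prs_cat"])): float(
                r["ratio_joint_over_product"]
            )
            for _, r in check.iterrows()
        }
    return out


def recovery_study(
    master_seed: int,
    n_reps: int = 25,
    phenotype: str = "pd",
    n_cases: int = 20_000,
    n_controls: int = 20_000,
    grid_reps: int = 0,
) -> pd.DataFrame:
    """``n_reps`` recovery replicates with seeds spawned from ``master_seed``."""
    rows = []
    for i, seed in enumerate(replicate_seeds(master_seed, n_reps)):
        rows.append(
            recovery_replicate(
                seed, phenotype=phenotype, n_cases=n_cases,
                n_controls=n_controls, grid=i < grid_reps,
            )
        )
    return pd.DataFrame(rows)


def null_calibration_replicate(
    seed: int,
    n_cases: int = 2000,
    n_controls: int = 2000,
    n_null: int = 250,
) -> dict:
    """One multiplicative-null replicate: interaction-LRT, Hosmer-Lemeshow
    and tail-based p-values of the (correctly specified) joint model."""
    config = scaled_config(n_cases, n_controls, seed=seed, theta_int=0.0)
    frame = prepare_analysis_frame(config)
    res = interaction_test(frame, "adj_pd")
    fit_null = res["fit_reduced"]
    hl = hosmer_lemeshow(fit_null)
    tail = tail_based_gof(fit_null, n_null=n_null, seed=seed + 2)
    return {
        "seed": seed,
        "p_lrt": res["lrt"].p_value,
        "p_hl": hl.p_value,
        "p_tail": tail.p_value,
    }
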