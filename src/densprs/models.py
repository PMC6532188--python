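"""Logistic association models for case-control data.

Fits maximum-likelihood logistic regressions (via statsmodels GLM/IRLS)
for the main-effect, joint continuous, joint categorical, interaction,
study-heterogeneity and confounder-sensitivity analyses, and provides
likelihood-ratio tests and odds-ratio tables with Wald 95% intervals.

The baseline covariate set for every disease model is age, 1/BMI and
study indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "ModelFit",
    "LrtResult",
    "BASELINE_TERMS",
    "prepare_frame",
    "fit_logistic",
    "or_table",
    "lrt",
    "fit_joint_continuous",
    "interaction_test",
    "fit_joint_categorical",
    "multiplicativity_product_check",
    "heterogeneity_by_study",
    "confounder_sensitivity",
]

BASELINE_TERMS = ("age_years", "inv_bmi", "study")

_Z95 = 1.96  # Wald multiplier


class LrtResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    """A fitted logistic model with everything downstream stages need."""

    params: pd.Series
    bse: pd.Series
    llf: float
    nobs: int
    converged: bool
    subject_index: np.ndarray
    fitted: np.ndarray
    X: np.ndarray
    y: np.ndarray
    column_names: list[str]

    def wald_ci(self, term: str) -> tuple[float, float]:
        b, se = self.params[term], self.bse[term]
        return float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.params[term]))


def prepare_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Copy of the analysis frame with 1/BMI materialised."""
    out = data.copy()
    if "inv_bmi" not in out.columns and "bmi" in out.columns:
        out["inv_bmi"] = 1.0 / out["bmi"].to_numpy(dtype=float)
    return out


def _study_indicators(study: pd.Series) -> pd.DataFrame:
    levels = list(pd.unique(study))
    return pd.DataFrame(
        {f"study[{lev}]": (study == lev).astype(float) for lev in levels[1:]},
        index=study.index,
    )


def build_design(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Design matrix with intercept; 'study' expands to drop-first indicators."""
    cols = [pd.Series(1.0, index=data.index, name="intercept")]
    for term in terms:
        if term == "study":
            ind = _study_indicators(data["study"])
            cols.extend(ind[c] for c in ind.columns)
        else:
            if term not in data.columns:
                raise ValidationError(f"term {term!r} not in analysis frame")
            cols.append(data[term].astype(float))
    X = pd.concat(cols, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValidationError(
            f"missing values in design columns {bad}; restrict to complete cases first"
        )
    return X


def fit_logistic(
    data: pd.DataFrame,
    terms: Sequence[str],
    outcome: str = "status",
) -> ModelFit:
    """Maximum-likelihood logistic regression of ``outcome`` on ``terms``.

    ``terms`` are column names of ``data`` ('study' expands to indicator
    contrasts); an intercept is always included.  Rows with missing
    outcome are rejected — handle complete-case selection upstream so the
    subject set is explicit.  Raises :class:`ConvergenceError` on
    non-convergence or apparent complete separation (|coef| > 15).
    """
    y = data[outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("outcome contains missing values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    X = build_design(data, terms)
    Xa = X.to_numpy()
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, Xa, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
    except Exception as exc:  # statsmodels flags perfect separation itself
        if "separation" in str(exc).lower() or "singular" in str(exc).lower():
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        raise
    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    if not res.converged:
        raise ConvergenceError("IRLS failed to converge in 100 iterations")
    # divergence check on the per-SD scale so it is invariant to covariate units
    col_sd = pd.Series(Xa.std(axis=0), index=names)
    scaled = (params * col_sd).abs()
    scaled = scaled[col_sd > 0]
    if len(scaled) and scaled.max() > 15:
        worst = scaled.idxmax()
        raise ConvergenceError(
            f"coefficient for {worst!r} diverged ({scaled.max():.1f} per SD > 15); "
            "likely complete separation"
        )
    index = (
        data["subject_id"].to_numpy()
        if "subject_id" in data.columns
        else data.index.to_numpy()
    )
    return ModelFit(
        params=params,
        bse=pd.Series(res.bse, index=names),
        llf=float(res.llf),
        nobs=int(len(y)),
        converged=bool(res.converged),
        subject_index=index,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        X=X.to_numpy(),
        y=y,
        column_names=names,
    )


def or_table(fit: ModelFit, terms: Sequence[str] | None = None) -> pd.DataFrame:
    """OR / L95 / U95 table (2-decimal presentation left to the writer)."""
    terms = [t for t in (terms or fit.column_names) if t != "intercept"]
    rows = []
    for t in terms:
        lo, hi = fit.wald_ci(t)
        rows.append({"term": t, "OR": fit.odds_ratio(t), "L95": lo, "U95": hi})
    return pd.DataFrame(rows).set_index("term")


def lrt(full: ModelFit, reduced: ModelFit) -> LrtResult:
    """Likelihood-ratio test of nested logistic models on identical subjects."""
    if len(full.subject_index) != len(reduced.subject_index) or not np.array_equal(
        full.subject_index, reduced.subject_index
    ):
        raise ValidationError(
            "LRT requires the same subjects in both models "
            f"(full n={full.nobs}, reduced n={reduced.nobs})"
        )
    df = len(full.params) - len(reduced.params)
    if df < 0:
        raise ValidationError("reduced model has more parameters than full model")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LrtResult(float(stat), int(df), p)


# ---------------------------------------------------------------------------
# joint models
# ---------------------------------------------------------------------------


def fit_joint_continuous(
    data: pd.DataFrame,
    density_col: str,
    prs_col: str = "prs_z",
    interaction: bool = False,
) -> ModelFit:
    """Baseline + standardized density + standardized PRS (+ product term)."""
    frame = prepare_frame(data)
    terms = list(BASELINE_TERMS) + [density_col, prs_col]
    if interaction:
        inter = f"{density_col}_x_{prs_col}"
        frame[inter] = frame[density_col].to_numpy() * frame[prs_col].to_numpy()
        terms.append(inter)
    return fit_logistic(frame, terms)


def interaction_test(
    data: pd.DataFrame, density_col: str, prs_col: str = "prs_z"
) -> dict:
    """1-df LRT of the density x PRS product term plus its Wald OR and CI."""
    full = fit_joint_continuous(data, density_col, prs_col, interaction=True)
    reduced = fit_joint_continuous(data, density_col, prs_col, interaction=False)
    res = lrt(full, reduced)
    inter = f"{density_col}_x_{prs_col}"
    lo, hi = full.wald_ci(inter)
    return {
        "lrt": res,
        "or_interaction": full.odds_ratio(inter),
        "ci_interaction": (lo, hi),
        "fit_full": full,
        "fit_reduced": reduced,
    }


def fit_joint_categorical(
    data: pd.DataFrame,
    density_cat_col: str = "pd_quartile",
    prs_cat_col: str = "prs_quintile",
    reference: tuple[int, int] = (2, 3),
) -> tuple[ModelFit, pd.DataFrame]:
    """Joint category grid: one indicator per (density, PRS) cell.

    Every cell except the reference (density quartile 2, PRS quintile 3
    by default) gets an indicator, with baseline covariates included.
    Returns the fit and a grid table with one row per cell: counts, OR
    and Wald CI; the reference row has OR 1 and an empty cell (no
    subjects) is reported with OR = NaN rather than dropped silently.
    """
    frame = prepare_frame(data)
    d = frame[density_cat_col].to_numpy()
    p = frame[prs_cat_col].to_numpy()
    d_levels = np.sort(np.unique(d))
    p_levels = np.sort(np.unique(p))
    ref_d, ref_p = reference

    terms = list(BASELINE_TERMS)
    cells = [(int(i), int(j)) for i in d_levels for j in p_levels]
    for i, j in cells:
        if (i, j) == (ref_d, ref_p):
            continue
        name = f"d{i}_p{j}"
        frame[name] = ((d == i) & (p == j)).astype(float)
        if frame[name].sum() > 0:
            terms.append(name)
    fit = fit_logistic(frame, terms)

    status = frame["status"].to_numpy()
    rows = []
    for i, j in cells:
        in_cell = (d == i) & (p == j)
        row = {
            "density_cat": i,
            "prs_cat": j,
            "n_case": int((in_cell & (status == 1)).sum()),
            "n_control": int((in_cell & (status == 0)).sum()),
        }
        if (i, j) == (ref_d, ref_p):
            row.update(OR=1.0, L95=np.nan, U95=np.nan, reference=True)
        elif f"d{i}_p{j}" in fit.params.index:
            lo, hi = fit.wald_ci(f"d{i}_p{j}")
            row.update(OR=fit.odds_ratio(f"d{i}_p{j}"), L95=lo, U95=hi, reference=False)
        else:  # empty cell: estimable by nobody, reported as undefined
            row.update(OR=np.nan, L95=np.nan, U95=np.nan, reference=False)
        rows.append(row)
    return fit, pd.DataFrame(rows)


def multiplicativity_product_check(
    density_ors: Mapping[int, float],
    prs_ors: Mapping[int, float],
    joint_grid: pd.DataFrame,
) -> pd.DataFrame:
    """Compare corner-cell joint ORs with products of the marginal ORs.

    For each corner of the category grid the report gives the product of
    the two marginal ORs, the fitted joint OR and their ratio, with a
    2-decimal presentation of product and joint OR.  Under a
    multiplicative model the ratio converges to 1.
    """
    d_cats = sorted(density_ors)
    p_cats = sorted(prs_ors)
    corners = [(d_cats[0], p_cats[0]), (d_cats[0], p_cats[-1]),
               (d_cats[-1], p_cats[0]), (d_cats[-1], p_cats[-1])]
    grid = joint_grid.set_index(["density_cat", "prs_cat"])
    rows = []
    for i, j in corners:
        product = density_ors[i] * prs_ors[j]
        joint = float(grid.loc[(i, j), "OR"])
        rows.append(
            {
                "density_cat": i,
                "prs_cat": j,
                "or_product": product,
                "or_joint": joint,
                "ratio_joint_over_product": joint / product,
                "or_product_2dp": round(product, 2),
                "or_joint_2dp": round(joint, 2),
            }
        )
    return pd.DataFrame(rows)


def heterogeneity_by_study(
    data: pd.DataFrame, factor_col: str, exclude_studies: Sequence[str] = ()
) -> LrtResult:
    """LRT of factor x study interaction, df = n_studies - 1.

    ``exclude_studies`` supports leave-one-study-out re-testing.
    """
    frame = prepare_frame(data)
    if exclude_studies:
        frame = frame.loc[~frame["study"].isin(list(exclude_studies))].copy()
    levels = list(pd.unique(frame["study"]))
    if len(levels) < 2:
        raise ValidationError("heterogeneity undefined with a single study")
    base_terms = list(BASELINE_TERMS) + [factor_col]
    inter_terms = []
    f = frame[factor_col].to_numpy(dtype=float)
    for lev in levels[1:]:
        name = f"{factor_col}_x_study[{lev}]"
        frame[name] = f * (frame["study"] == lev).to_numpy(dtype=float)
        inter_terms.append(name)
    full = fit_logistic(frame, base_terms + inter_terms)
    reduced = fit_logistic(frame, base_terms)
    return lrt(full, reduced)


def confounder_sensitivity(
    data: pd.DataFrame,
    factor_cols: Sequence[str],
    extra_covariates: Sequence[str],
) -> pd.DataFrame:
    """Side-by-side ORs with and without candidate confounders.

    Both models are fitted on the complete-case subset of the extra
    covariates so the comparison is like for like; the report records
    the per-SD OR of each factor before and after adjustment, the
    absolute change, and the complete-case n.
    """
    frame = prepare_frame(data)
    complete = frame[list(extra_covariates)].notna().all(axis=1)
    used = frame.loc[complete].copy()
    n_dropped = int((~complete).sum())
    base = fit_logistic(used, list(BASELINE_TERMS) + list(factor_cols))
    adjusted = fit_logistic(
        used, list(BASELINE_TERMS) + list(factor_cols) + list(extra_covariates)
    )
    rows = []
    for t in factor_cols:
        rows.append(
            {
                "term": t,
                "OR_base": base.odds_ratio(t),
                "OR_adjusted": adjusted.odds_ratio(t),
                "abs_change": abs(adjusted.odds_ratio(t) - base.odds_ratio(t)),
                "n_used": int(len(used)),
                "n_dropped": n_dropped,
            }
        )
    return pd.DataFrame(rows).set_index("term")
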