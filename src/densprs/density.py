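"""Adjusted mammographic density phenotypes.

Percent density (PD) and absolute dense area (DA) are square-root
transformed, residualised on age, 1/BMI and study by ordinary least
squares fitted among controls, standardized to control-SD units, and
categorised into control-based quartiles.  The residual ("adjusted
density") is the phenotype the association models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .genotypes import assign_quantile_categories, standardize_by_controls

__all__ = [
    "AdjustedPhenotype",
    "sqrt_transform",
    "residualize",
    "make_adjusted_phenotypes",
]


@dataclass
class AdjustedPhenotype:
    """Adjusted density phenotypes plus the audit trail of their fit.

    ``frame`` holds one row per retained subject with columns
    ``adj_pd``, ``adj_da`` (control-SD units), ``pd_quartile``,
    ``da_quartile`` and ``nondense_cm2``.  ``coefficients`` stores the
    OLS adjustment coefficients per measure; ``exclusions`` counts
    subjects dropped for missing age or BMI.
    """

    frame: pd.DataFrame
    coefficients: dict[str, dict[str, float]]
    cutpoints: dict[str, np.ndarray]
    exclusions: dict[str, int] = field(default_factory=dict)
    dropped_terms: dict[str, list[str]] = field(default_factory=dict)


def sqrt_transform(measure: Sequence) -> np.ndarray:
    """Element-wise square root; density measures must be non-negative."""
    x = np.asarray(measure, dtype=float)
    if np.any(x < 0):
        raise ValidationError("negative values cannot be square-root transformed")
    return np.sqrt(x)


def _design(age, inv_bmi, study):
    """Intercept | age | 1/BMI | study indicator columns (first level dropped)."""
    levels = list(pd.unique(np.asarray(study)))
    cols = [np.ones(len(age)), np.asarray(age, float), np.asarray(inv_bmi, float)]
    names = ["intercept", "age", "inv_bmi"]
    for lev in levels[1:]:
        cols.append((np.asarray(study) == lev).astype(float))
        names.append(f"study[{lev}]")
    return np.column_stack(cols), names


def residualize(
    transformed: Sequence,
    age: Sequence,
    inv_bmi: Sequence,
    study: Sequence,
    fit_group_mask: Sequence | None = None,
) -> tuple[np.ndarray, dict[str, float], list[str]]:
    """Residuals of an OLS fit on age, 1/BMI and study indicators.

    The model is fitted within ``fit_group_mask`` (all subjects when
    None) and the residual observed - predicted is returned for every
    subject.  A rank-deficient design is repaired by dropping redundant
    columns, which are reported in the third return value.

    Returns ``(residuals, coefficients, dropped_columns)``.
    """
    y = np.asarray(transformed, dtype=float)
    X, names = _design(age, inv_bmi, study)
    mask = (
        np.ones(len(y), dtype=bool)
        if fit_group_mask is None
        else np.asarray(fit_group_mask, dtype=bool)
    )
    Xf, yf = X[mask], y[mask]
    if Xf.shape[0] <= Xf.shape[1]:
        raise ValidationError(
            f"fitting group has {Xf.shape[0]} subjects for {Xf.shape[1]} parameters"
        )
    dropped: list[str] = []
    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        # pivoted QR keeps a maximal independent column subset
        from scipy.linalg import qr

        _, _, piv = qr(Xf, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        X, Xf = X[:, keep], Xf[:, keep]
        names = [names[j] for j in keep]
    beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
    residuals = y - X @ beta
    coefs = {nm: float(b) for nm, b in zip(names, beta)}
    return residuals, coefs, dropped


def make_adjusted_phenotypes(subjects: pd.DataFrame, k: int = 4) -> AdjustedPhenotype:
    """Run the full adjustment pipeline for percent density and dense area.

    Subjects with missing age or BMI are excluded (complete case) and
    counted in the exclusion report.  The adjustment model is fitted on
    controls and applied to everyone; standardization and quartile
    cutpoints also come from controls.
    """
    required = ["status", "age_years", "bmi", "pd_percent", "da_cm2", "study"]
    missing_cols = [c for c in required if c not in subjects.columns]
    if missing_cols:
        raise ValidationError(f"subject table lacks columns {missing_cols}")

    ok = subjects["age_years"].notna() & subjects["bmi"].notna()
    excl = {
        "missing_age": int(subjects["age_years"].isna().sum()),
        "missing_bmi": int((subjects["bmi"].isna() & subjects["age_years"].notna()).sum()),
        "n_used": int(ok.sum()),
    }
    sub = subjects.loc[ok].reset_index(drop=True)
    status = sub["status"].to_numpy()
    controls = status == 0
    inv_bmi = 1.0 / sub["bmi"].to_numpy(dtype=float)

    out = pd.DataFrame({"subject_id": sub["subject_id"], "status": status})
    if "total_area_cm2" in sub.columns:
        out["nondense_cm2"] = sub["total_area_cm2"].to_numpy() - sub["da_cm2"].to_numpy()
    coefficients: dict[str, dict[str, float]] = {}
    cutpoints: dict[str, np.ndarray] = {}
    dropped_terms: dict[str, list[str]] = {}
    for measure, col, qcol in (
        ("pd", "pd_percent", "pd_quartile"),
        ("da", "da_cm2", "da_quartile"),
    ):
        t = sqrt_transform(sub[col].to_numpy(dtype=float))
        resid, coefs, dropped = residualize(
            t, sub["age_years"], inv_bmi, sub["study"], fit_group_mask=controls
        )
        z = standardize_by_controls(resid, status)
        labels, cut = assign_quantile_categories(z, status, k)
        out[f"adj_{measure}"] = z
        out[qcol] = labels
        coefficients[measure] = coefs
        cutpoints[measure] = cut
        dropped_terms[measure] = dropped
    return AdjustedPhenotype(
        frame=out,
        coefficients=coefficients,
        cutpoints=cutpoints,
        exclusions=excl,
        dropped_terms=dropped_terms,
    )
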