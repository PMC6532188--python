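"""Goodness-of-fit tests of the multiplicative joint risk model.

Two complementary calibration checks of a fitted logistic model:

* the global Hosmer-Lemeshow test on equal-count bins (deciles by
  default) of fitted risk;
* a tail-based test focused on the extremes of the predicted-risk
  distribution, where clinical decisions concentrate: for several tail
  fractions the standardized deviation of observed from expected case
  counts is computed in the lowest- and highest-risk subjects, the
  statistic is the maximum absolute deviation, and its null distribution
  comes from a parametric bootstrap that regenerates outcomes from the
  fitted model and refits it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import LrtResult, ModelFit

__all__ = [
    "GofResult",
    "hosmer_lemeshow",
    "hl_statistic",
    "tail_based_gof",
    "tail_statistic",
    "tail_null_replicate",
    "multiplicativity_report",
]


@dataclass
class GofResult:
    """Outcome of a goodness-of-fit test, serialisable to JSON."""

    name: str
    statistic: float
    p_value: float
    df: int | None
    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        meta = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.metadata.items()
        }
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "table": self.table.to_dict(orient="records"),
            "warnings": list(self.warnings),
            "metadata": meta,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow
# ---------------------------------------------------------------------------


def _equal_count_bins(p: np.ndarray, g: int) -> list[np.ndarray]:
    """Indices of g equal-count bins of p, never splitting tied values."""
    order = np.argsort(p, kind="mergesort")
    n = len(p)
    sorted_p = p[order]
    raw_edges = [round(i * n / g) for i in range(g + 1)]
    edges = [0]
    for e in raw_edges[1:-1]:
        # advance the edge to the end of a tie run
        while 0 < e < n and sorted_p[e] == sorted_p[e - 1]:
            e += 1
        if e > edges[-1] and e < n:
            edges.append(e)
    edges.append(n)
    return [order[a:b] for a, b in zip(edges[:-1], edges[1:])]


def hl_statistic(
    y: np.ndarray, p: np.ndarray, g: int = 10
) -> tuple[float, int, pd.DataFrame, list[str]]:
    """Hosmer-Lemeshow chi-square on ``g`` equal-count bins of fitted risk.

    Statistic = sum over bins of (O - E)^2 / (E (1 - E / n_bin)) with the
    chi-square reference on (number of realised bins) - 2 degrees of
    freedom.  Tied fitted probabilities stay in one bin, so realised bin
    sizes (logged in the table) can deviate from n/g.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if g < 3:
        raise ValueError("need at least 3 bins")
    bins = _equal_count_bins(p, g)
    rows, warnings = [], []
    stat = 0.0
    for b, idx in enumerate(bins, start=1):
        nb = len(idx)
        O = float(y[idx].sum())
        E = float(p[idx].sum())
        rows.append(
            {
                "bin": b,
                "n": nb,
                "p_low": float(p[idx].min()),
                "p_high": float(p[idx].max()),
                "observed": O,
                "expected": E,
            }
        )
        if E < 1:
            warnings.append(f"bin {b}: expected count {E:.3f} < 1")
        denom = E * (1.0 - E / nb)
        if denom > 0:
            stat += (O - E) ** 2 / denom
    df = len(bins) - 2
    return stat, df, pd.DataFrame(rows), warnings


def hosmer_lemeshow(fit: ModelFit, g: int = 10) -> GofResult:
    """Global Hosmer-Lemeshow calibration test of a fitted logistic model."""
    stat, df, table, warnings = hl_statistic(fit.y, fit.fitted, g)
    p_value = float(stats.chi2.sf(stat, df))
    return GofResult(
        name="hosmer_lemeshow",
        statistic=float(stat),
        p_value=p_value,
        df=df,
        table=table,
        warnings=warnings,
        metadata={"g_requested": g, "bins_realised": len(table)},
    )


# ---------------------------------------------------------------------------
# tail-based test
# ---------------------------------------------------------------------------


def _tail_regions(
    p: np.ndarray, fractions: Sequence[float], min_subjects: int = 20
) -> tuple[list[tuple[str, float, np.ndarray]], list[str]]:
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    regions, warnings = [], []
    for f in fractions:
        if not 0 < f < 0.5:
            raise ValueError("tail fractions must lie in (0, 0.5)")
        m = int(np.floor(f * n))
        for tail, idx in (("lower", order[:m]), ("upper", order[n - m:])):
            if m < min_subjects:
                warnings.append(
                    f"{tail} tail at fraction {f}: only {m} subjects, region dropped"
                )
                continue
            regions.append((tail, f, idx))
    return regions, warnings


def tail_statistic(
    y: np.ndarray,
    p: np.ndarray,
    fractions: Sequence[float],
    score: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame, list[str]]:
    """Max |(O - E) / sqrt(Var E)| over lower/upper tail regions of fitted risk.

    Regions are defined by the ranks of ``score`` (the fitted probability
    when None), so the test is invariant to any monotone transformation of
    the risk score; expected counts always come from ``p``.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    regions, warnings = _tail_regions(p if score is None else np.asarray(score, float), fractions)
    if not regions:
        raise ValueError("no tail region satisfies the minimum-size rule")
    rows = []
    for tail, f, idx in regions:
        O = float(y[idx].sum())
        E = float(p[idx].sum())
        V = float((p[idx] * (1 - p[idx])).sum())
        z = (O - E) / np.sqrt(V) if V > 0 else 0.0
        rows.append(
            {
                "tail": tail,
                "fraction": f,
                "n": len(idx),
                "observed": O,
                "expected": E,
                "variance": V,
                "z": z,
            }
        )
    table = pd.DataFrame(rows)
    return float(table["z"].abs().max()), table, warnings


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> tuple[np.ndarray, bool]:
    """Fast Newton-Raphson logistic MLE for the bootstrap inner loop.

    Cross-checked against the statsmodels IRLS fit in the test suite.
    """
    beta = start.astype(float).copy()
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (y - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H += 1e-8 * np.eye(H.shape[0])
            step = np.linalg.solve(H, g)
        beta += step
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            return beta, True
        ll_old = ll
    return beta, False


def _tail_max_z(y: np.ndarray, p: np.ndarray, fractions: Sequence[float]) -> float:
    """max |z| over tail regions, without the reporting table (hot path)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    best = 0.0
    for f in fractions:
        m = int(np.floor(f * n))
        if m < 20:
            continue
        for idx in (order[:m], order[n - m:]):
            pi = p[idx]
            V = float((pi * (1 - pi)).sum())
            if V > 0:
                z = abs(float(y[idx].sum() - pi.sum())) / np.sqrt(V)
                best = max(best, z)
    return best


def tail_null_replicate(
    fit: ModelFit,
    fractions: Sequence[float],
    seed: np.random.SeedSequence | int,
) -> float:
    """One parametric-bootstrap replicate of the tail statistic.

    Outcomes are regenerated from the fitted null probabilities with the
    given seed (bit-reproducible), the null model is refitted, and the
    tail statistic of the refitted model is returned.
    """
    rng = np.random.default_rng(seed)
    y_star = (rng.random(len(fit.y)) < fit.fitted).astype(float)
    beta, _ = _newton_logistic(fit.X, y_star, fit.params.to_numpy())
    p_star = 1.0 / (1.0 + np.exp(-(fit.X @ beta)))
    return _tail_max_z(y_star, p_star, fractions)


def tail_based_gof(
    fit_null: ModelFit,
    tail_fractions: Sequence[float] = (0.01, 0.05, 0.10, 0.20),
    n_null: int = 1000,
    seed: int = 0,
) -> GofResult:
    """Tail-based goodness-of-fit test of a no-interaction logistic model.

    Subjects are ranked by fitted risk; for each tail fraction the
    standardized deviation z = (O - E)/sqrt(Var) of observed case counts
    is computed in the lower and upper tails, and the test statistic is
    max |z|.  Its p-value comes from a parametric bootstrap: ``n_null``
    datasets are regenerated from the fitted probabilities, the model is
    refitted to each, and the statistic recomputed.  The master seed
    spawns one child stream per replicate, so any single replicate can be
    reproduced bit-identically with :func:`tail_null_replicate`.
    """
    stat, table, warnings = tail_statistic(fit_null.y, fit_null.fitted, tail_fractions)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_null)
    null_stats = np.array(
        [tail_null_replicate(fit_null, tail_fractions, child) for child in children]
    )
    p_value = float((1 + np.sum(null_stats >= stat - 1e-12)) / (n_null + 1))
    return GofResult(
        name="tail_based",
        statistic=stat,
        p_value=p_value,
        df=None,
        table=table,
        warnings=warnings,
        metadata={
            "n_null": n_null,
            "seed": seed,
            "tail_fractions": list(tail_fractions),
            "null_statistics": null_stats,
        },
    )


def plot_tail_regions(result: GofResult, path) -> None:
    """Observed vs expected case counts in the tail regions (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=False)
    for ax, tail in zip(axes, ("lower", "upper")):
        sub = tab[tab["tail"] == tail]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["observed"], width=0.4, label="observed")
        ax.bar(x + 0.2, sub["expected"], width=0.4, label="expected")
        ax.set_xticks(x, [f"{f:g}" for f in sub["fraction"]])
        ax.set_xlabel("tail fraction")
        ax.set_title(f"{tail} tail")
    axes[0].set_ylabel("cases")
    axes[0].legend(frameon=False)
    fig.suptitle(f"{result.name}: statistic {result.statistic:.2f}, p = {result.p_value:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# combined verdict
# ---------------------------------------------------------------------------


def multiplicativity_report(
    lrt_result: LrtResult | None,
    global_gof: GofResult | None,
    tail_gof: GofResult | None,
    interaction_or: float | None = None,
    interaction_ci: tuple[float, float] | None = None,
    product_check: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """One-page summary of the multiplicativity evidence.

    Collects the interaction LRT, global and tail goodness-of-fit
    p-values, the interaction OR with CI and the corner-cell product
    check, and issues a verdict at level ``alpha``.  A component that was
    not computed is reported explicitly as ``"not computed"`` rather than
    omitted.
    """
    def p_or_missing(x):
        return float(x.p_value) if x is not None else "not computed"

    ps = [
        x.p_value
        for x in (lrt_result, global_gof, tail_gof)
        if x is not None
    ]
    verdict = (
        "consistent with multiplicative joint association"
        if ps and all(p > alpha for p in ps)
        else "evidence against multiplicativity"
        if ps
        else "not computed"
    )
    return {
        "alpha": alpha,
        "p_lrt_interaction": p_or_missing(lrt_result),
        "p_global_gof": p_or_missing(global_gof),
        "p_tail_gof": p_or_missing(tail_gof),
        "or_interaction": interaction_or if interaction_or is not None else "not computed",
        "ci_interaction": list(interaction_ci) if interaction_ci is not None else "not computed",
        "product_check": (
            product_check.to_dict(orient="records")
            if product_check is not None
            else "not computed"
        ),
        "verdict": verdict,
    }
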