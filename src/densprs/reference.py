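"""Published reference values from a large eight-study breast-cancer
case-control consortium analysis of mammographic density and a 77-SNP
polygenic risk score.

These numbers serve two purposes:

* generator calibration — the synthetic-data module defaults its sample
  sizes, covariate margins and effect sizes to these values so that the
  simulated data resemble the study population they emulate;
* worked-example arithmetic — the categorical odds-ratio tables support
  the multiplicativity product check on published marginal estimates.

Everything here is a published summary statistic, not individual-level
data.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Study design: eight studies, six of them cohort or population based.
# Totals: 3628 cases / 5126 controls, of which the population-based
# subset contributes 2439 / 3895.
# ---------------------------------------------------------------------------

N_CASES_TOTAL = 3628
N_CONTROLS_TOTAL = 5126
N_CASES_POPULATION_BASED = 2439
N_CONTROLS_POPULATION_BASED = 3895

DEFAULT_STUDY_NAMES = ("PB1", "PB2", "PB3", "PB4", "PB5", "PB6", "CL1", "CL2")
DEFAULT_POPULATION_BASED = (True, True, True, True, True, True, False, False)

# Per-study splits are not published; the totals are divided as evenly as
# possible within the population-based and clinic-based groups.
DEFAULT_CASES_PER_STUDY = (407, 407, 407, 406, 406, 406, 595, 594)
DEFAULT_CONTROLS_PER_STUDY = (650, 649, 649, 649, 649, 649, 616, 615)

assert sum(DEFAULT_CASES_PER_STUDY) == N_CASES_TOTAL
assert sum(DEFAULT_CONTROLS_PER_STUDY) == N_CONTROLS_TOTAL

# ---------------------------------------------------------------------------
# Headline per-SD odds ratios (full-sample estimates) used as generator
# defaults: adjusted percent density, adjusted dense area, 77-SNP PRS.
# ---------------------------------------------------------------------------

OR_PER_SD_ADJUSTED_PD = 1.45
OR_PER_SD_ADJUSTED_DA = 1.34
OR_PER_SD_PRS = 1.52

# Control-group Pearson correlation between adjusted percent density and
# the standardized PRS.
CORR_PRS_ADJUSTED_PD = 0.06

# ---------------------------------------------------------------------------
# Published categorical odds ratios (full sample).  Density categories are
# quartiles of the adjusted measure, PRS categories are quintiles; the
# reference categories are density quartile 2 and PRS quintile 3.
# ---------------------------------------------------------------------------

OR_PD_QUARTILES = {1: 0.60, 2: 1.00, 3: 1.25, 4: 1.64}
OR_DA_QUARTILES = {1: 0.56, 2: 1.00, 3: 1.15, 4: 1.41}
OR_PRS_QUINTILES = {1: 0.51, 2: 0.80, 3: 1.00, 4: 1.31, 5: 1.66}

# Published joint categorical estimates for the extreme cells relative to
# the (density quartile 2, PRS quintile 3) reference.
OR_JOINT_HIGHEST = 2.60
OR_JOINT_LOWEST = 0.34

# ---------------------------------------------------------------------------
# Subject characteristics (counts at time of mammogram, by case status).
# Keys: (characteristic, level) -> (n_cases, n_controls).  "Unknown" rows
# are genuine missing-data counts; the synthetic generator reproduces the
# full three-way margins including missingness.
# ---------------------------------------------------------------------------

CHARACTERISTIC_COUNTS = {
    ("parity", "nulliparous"): (431, 582),
    ("parity", "parous"): (3141, 4459),
    ("parity", "unknown"): (56, 85),
    ("menopause", "pre"): (540, 878),
    ("menopause", "post"): (3058, 4194),
    ("menopause", "unknown"): (30, 54),
    # HT use is tabulated among postmenopausal women only.
    ("ht_use", "ever"): (1737, 2116),
    ("ht_use", "never"): (1179, 1568),
    ("ht_use", "unknown"): (142, 510),
    ("family_history", "yes"): (637, 688),
    ("family_history", "no"): (2808, 3944),
    ("family_history", "unknown"): (183, 494),
}


def characteristic_fractions(characteristic: str, group: str) -> dict[str, float]:
    """Fractions of each level (including 'unknown') among cases or controls.

    ``group`` is ``"case"`` or ``"control"``.  For ``ht_use`` the
    denominator is the postmenopausal count of that group, matching how
    the summary table is laid out.
    """
    col = 0 if group == "case" else 1
    levels = {
        lvl: cnt[col]
        for (char, lvl), cnt in CHARACTERISTIC_COUNTS.items()
        if char == characteristic
    }
    total = sum(levels.values())
    return {lvl: n / total for lvl, n in levels.items()}


def postmenopausal_fraction(group: str = "case", include_unknown: bool = False) -> float:
    """Fraction postmenopausal among cases or controls with known status.

    With ``include_unknown=False`` (the usual presentation) the
    denominator is pre + post only, e.g. 3058 / (540 + 3058) for cases.
    Returned as a percentage.
    """
    col = 0 if group == "case" else 1
    pre = CHARACTERISTIC_COUNTS[("menopause", "pre")][col]
    post = CHARACTERISTIC_COUNTS[("menopause", "post")][col]
    unk = CHARACTERISTIC_COUNTS[("menopause", "unknown")][col]
    denom = pre + post + (unk if include_unknown else 0)
    return 100.0 * post / denom


def or_per_sd_defaults() -> dict[str, float]:
    """Generator-default per-SD log odds ratios on the natural-log scale."""
    return {
        "beta_pd": float(np.log(OR_PER_SD_ADJUSTED_PD)),
        "beta_da": float(np.log(OR_PER_SD_ADJUSTED_DA)),
        "beta_prs": float(np.log(OR_PER_SD_PRS)),
    }
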