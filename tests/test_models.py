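"""Logistic models, odds-ratio tables, LRTs, heterogeneity and confounding."""

import numpy as np
import pandas as pd
import pytest

import densprs as dp
from densprs.exceptions import ConvergenceError, ValidationError
from densprs.models import (
    BASELINE_TERMS,
    fit_joint_categorical,
    fit_logistic,
    heterogeneity_by_study,
    lrt,
    multiplicativity_product_check,
    or_table,
)


def frame_from_2x2(a, b, c, d):
    """Cases exposed / cases unexposed / controls exposed / controls unexposed."""
    status = [1] * (a + b) + [0] * (c + d)
    exposed = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"status": status, "exposed": [float(e) for e in exposed]})


def cross_product_ratio(a, b, c, d):
    """OR of (cases exposed, cases unexposed, controls exposed, controls
    unexposed): (a*d)/(b*c)."""
    return (a * d) / (b * c)


class TestFitLogistic:
    def test_balanced_2x2_gives_unit_or(self):
        fit = fit_logistic(frame_from_2x2(50, 50, 50, 50), ["exposed"])
        assert fit.odds_ratio("exposed") == pytest.approx(1.0, abs=1e-9)

    def test_family_history_2x2_matches_cross_product(self):
        """Published family-history counts: OR = (637*3944)/(2808*688) ~ 1.30."""
        fit = fit_logistic(frame_from_2x2(637, 2808, 688, 3944), ["exposed"])
        oracle = cross_product_ratio(637, 2808, 688, 3944)
        assert oracle == (637 * 3944) / (2808 * 688)
        assert fit.odds_ratio("exposed") == pytest.approx(oracle, rel=1e-6)
        assert round(fit.odds_ratio("exposed"), 2) == 1.30

    @pytest.mark.parametrize(
        "counts", [(13, 37, 22, 28), (5, 95, 40, 60), (70, 30, 55, 45)]
    )
    def test_2x2_mle_equals_cross_product_ratio(self, counts):
        fit = fit_logistic(frame_from_2x2(*counts), ["exposed"])
        assert fit.odds_ratio("exposed") == pytest.approx(
            cross_product_ratio(*counts), rel=1e-6
        )

    def test_wald_interval_brackets_or(self, small_dataset):
        fit = fit_logistic(
            small_dataset["frame"], list(BASELINE_TERMS) + ["adj_pd"]
        )
        tab = or_table(fit, ["adj_pd"])
        assert tab.loc["adj_pd", "L95"] <= tab.loc["adj_pd", "OR"] <= tab.loc["adj_pd", "U95"]

    def test_complete_separation_detected(self):
        df = pd.DataFrame(
            {"status": [0] * 30 + [1] * 30, "x": [0.0] * 30 + [1.0] * 30}
        )
        with pytest.raises(ConvergenceError):
            fit_logistic(df, ["x"])

    def test_missing_design_values_rejected(self):
        df = pd.DataFrame({"status": [0, 1, 0, 1], "x": [1.0, np.nan, 0.0, 1.0]})
        with pytest.raises(ValidationError, match="missing"):
            fit_logistic(df, ["x"])

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"status": [0, 1, 2], "x": [0.0, 1.0, 0.5]})
        with pytest.raises(ValidationError, match="binary"):
            fit_logistic(df, ["x"])


class TestLrt:
    def test_identical_models_give_zero(self, small_dataset):
        fit = fit_logistic(small_dataset["frame"], list(BASELINE_TERMS))
        res = lrt(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_matches_brute_force_log_likelihood(self, small_dataset):
        """2*(ll_full - ll_reduced) recomputed from an independent Bernoulli
        log-likelihood evaluator at the fitted parameters."""
        frame = small_dataset["frame"]
        full = fit_logistic(frame, list(BASELINE_TERMS) + ["adj_pd"])
        reduced = fit_logistic(frame, list(BASELINE_TERMS))

        def loglik(fit):
            eta = fit.X @ fit.params.to_numpy()
            return float(np.sum(fit.y * eta - np.logaddexp(0.0, eta)))

        oracle = 2.0 * (loglik(full) - loglik(reduced))
        assert lrt(full, reduced).statistic == pytest.approx(oracle, abs=1e-6)

    def test_subject_mismatch_rejected(self, small_dataset):
        frame = small_dataset["frame"]
        full = fit_logistic(frame, list(BASELINE_TERMS) + ["adj_pd"])
        reduced = fit_logistic(frame.iloc[:-2], list(BASELINE_TERMS))
        with pytest.raises(ValidationError, match="same subjects"):
            lrt(full, reduced)

    def test_invariant_to_affine_covariate_rescaling(self, small_dataset):
        frame = small_dataset["frame"].copy()
        full = fit_logistic(frame, list(BASELINE_TERMS) + ["adj_pd"])
        reduced = fit_logistic(frame, list(BASELINE_TERMS))
        stat = lrt(full, reduced).statistic
        frame["adj_pd"] = 1000.0 * frame["adj_pd"] + 7.0
        frame["age_years"] = frame["age_years"] / 50.0
        full2 = fit_logistic(frame, list(BASELINE_TERMS) + ["adj_pd"])
        reduced2 = fit_logistic(frame, list(BASELINE_TERMS))
        assert lrt(full2, reduced2).statistic == pytest.approx(stat, abs=1e-5)

    def test_density_association_strongly_significant(self, small_dataset):
        frame = small_dataset["frame"]
        full = fit_logistic(frame, list(BASELINE_TERMS) + ["adj_pd"])
        reduced = fit_logistic(frame, list(BASELINE_TERMS))
        res = lrt(full, reduced)
        assert res.df == 1
        assert res.statistic > 20 and res.p_value < 1e-4


class TestJointModels:
    def test_adding_prs_changes_density_or_little(self, small_dataset):
        frame = small_dataset["frame"]
        alone = fit_logistic(frame, list(BASELINE_TERMS) + ["adj_pd"])
        joint = dp.fit_joint_continuous(frame, "adj_pd")
        assert abs(joint.odds_ratio("adj_pd") - alone.odds_ratio("adj_pd")) < 0.05

    def test_interaction_test_structure(self, small_dataset):
        res = dp.interaction_test(small_dataset["frame"], "adj_pd")
        assert res["lrt"].df == 1
        assert res["ci_interaction"][0] <= res["or_interaction"] <= res["ci_interaction"][1]

    def test_reference_cell_is_one(self, small_dataset):
        _, grid = fit_joint_categorical(small_dataset["frame"])
        ref = grid[(grid["density_cat"] == 2) & (grid["prs_cat"] == 3)]
        assert ref["OR"].iloc[0] == 1.0 and bool(ref["reference"].iloc[0])

    def test_corner_ordering_under_positive_effects(self, small_dataset):
        _, grid = fit_joint_categorical(small_dataset["frame"])
        g = grid.set_index(["density_cat", "prs_cat"])["OR"]
        assert g[(1, 1)] < 1.0 < g[(4, 5)]
        assert g[(1, 1)] < g[(4, 1)] < g[(4, 5)]
        assert g[(1, 1)] < g[(1, 5)] < g[(4, 5)]

    def test_empty_cell_reported_not_dropped(self, small_dataset):
        frame = small_dataset["frame"]
        trimmed = frame[~((frame["pd_quartile"] == 1) & (frame["prs_quintile"] == 1))]
        _, grid = fit_joint_categorical(trimmed)
        cell = grid[(grid["density_cat"] == 1) & (grid["prs_cat"] == 1)]
        assert len(cell) == 1
        assert np.isnan(cell["OR"].iloc[0])
        assert cell["n_case"].iloc[0] == 0 and cell["n_control"].iloc[0] == 0

    def test_grid_counts_sum_to_sample(self, small_dataset):
        frame = small_dataset["frame"]
        _, grid = fit_joint_categorical(frame)
        assert grid["n_case"].sum() == (frame["status"] == 1).sum()
        assert grid["n_control"].sum() == (frame["status"] == 0).sum()


class TestProductCheck:
    def test_identity_margin(self):
        grid = pd.DataFrame(
            {
                "density_cat": np.repeat([1, 2, 3, 4], 5),
                "prs_cat": list(range(1, 6)) * 4,
                "OR": np.tile([0.5, 0.8, 1.0, 1.3, 1.7], 4),
            }
        )
        d_ors = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}
        p_ors = {1: 0.5, 2: 0.8, 3: 1.0, 4: 1.3, 5: 1.7}
        rep = multiplicativity_product_check(d_ors, p_ors, grid)
        assert np.allclose(rep["ratio_joint_over_product"], 1.0)

    def test_published_corner_products(self):
        """Product of the published lowest-quartile density OR and the
        lowest-quintile PRS OR reproduces the published 0.31 product."""
        from densprs import reference

        grid = pd.DataFrame(
            {
                "density_cat": [1, 1, 4, 4],
                "prs_cat": [1, 5, 1, 5],
                "OR": [
                    reference.OR_JOINT_LOWEST,
                    np.nan,
                    np.nan,
                    reference.OR_JOINT_HIGHEST,
                ],
            }
        )
        rep = multiplicativity_product_check(
            reference.OR_PD_QUARTILES, reference.OR_PRS_QUINTILES, grid
        ).set_index(["density_cat", "prs_cat"])
        assert rep.loc[(1, 1), "or_product_2dp"] == 0.31
        # the printed top-corner estimates multiply to 2.72 (1.64 x 1.66);
        # the published product 2.70 used unrounded marginal estimates
        assert rep.loc[(4, 5), "or_product_2dp"] == 2.72


class TestHeterogeneity:
    def test_single_study_undefined(self, small_dataset):
        frame = small_dataset["frame"]
        one = frame[frame["study"] == frame["study"].iloc[0]]
        with pytest.raises(ValidationError, match="single study"):
            heterogeneity_by_study(one, "adj_pd")

    def test_df_is_studies_minus_one(self, small_dataset):
        frame = small_dataset["frame"]
        res = heterogeneity_by_study(frame, "adj_pd")
        assert res.df == frame["study"].nunique() - 1
        assert 0.0 <= res.p_value <= 1.0

    def test_detects_study_with_doubled_effect(self, rng):
        """A study whose log-OR is twice the others' yields a small p_het."""
        n_per = 2500
        rows = []
        for s, beta in (("A", 0.3), ("B", 0.3), ("C", 0.6)):
            x = rng.normal(size=n_per)
            age = rng.normal(60, 8, n_per)
            bmi = rng.normal(26, 3, n_per)
            pr = 1 / (1 + np.exp(-(-0.5 + beta * x)))
            y = (rng.random(n_per) < pr).astype(int)
            rows.append(
                pd.DataFrame(
                    {"status": y, "x": x, "age_years": age, "bmi": bmi, "study": s}
                )
            )
        frame = pd.concat(rows, ignore_index=True)
        res = heterogeneity_by_study(frame, "x")
        assert res.p_value < 0.01

    def test_leave_one_study_out(self, small_dataset):
        frame = small_dataset["frame"]
        drop = frame["study"].iloc[0]
        res = heterogeneity_by_study(frame, "adj_pd", exclude_studies=[drop])
        assert res.df == frame["study"].nunique() - 2


class TestConfounderSensitivity:
    def test_independent_covariate_changes_nothing(self, rng):
        n = 4000
        x = rng.normal(size=n)
        z = rng.normal(size=n)  # unrelated to x and to the outcome
        pr = 1 / (1 + np.exp(-(-0.3 + 0.4 * x)))
        y = (rng.random(n) < pr).astype(int)
        frame = pd.DataFrame(
            {
                "status": y,
                "x": x,
                "z": z,
                "age_years": rng.normal(60, 8, n),
                "bmi": rng.normal(26, 3, n),
                "study": np.repeat(["A", "B"], n // 2),
            }
        )
        rep = dp.confounder_sensitivity(frame, ["x"], ["z"])
        assert rep.loc["x", "abs_change"] < 0.03

    def test_true_confounder_moves_or_toward_truth(self, rng):
        n = 6000
        z = rng.normal(size=n)
        x = 0.6 * z + rng.normal(size=n)  # exposure depends on confounder
        pr = 1 / (1 + np.exp(-(-0.5 + 0.5 * z)))  # outcome depends only on z
        y = (rng.random(n) < pr).astype(int)
        frame = pd.DataFrame(
            {
                "status": y,
                "x": x,
                "z": z,
                "age_years": rng.normal(60, 8, n),
                "bmi": rng.normal(26, 3, n),
                "study": np.repeat(["A", "B"], n // 2),
            }
        )
        rep = dp.confounder_sensitivity(frame, ["x"], ["z"])
        # truth: x has no direct effect (OR 1); adjustment removes the bias
        assert abs(rep.loc["x", "OR_adjusted"] - 1.0) < abs(rep.loc["x", "OR_base"] - 1.0)

    def test_missing_confounder_rows_counted(self, small_dataset):
        frame = small_dataset["frame"]
        rep = dp.confounder_sensitivity(
            frame, ["adj_pd", "prs_z"], ["parity", "menopause", "family_history"]
        )
        assert (rep["n_used"] + rep["n_dropped"] == len(frame)).all()
        assert rep.loc["adj_pd", "abs_change"] < 0.05
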