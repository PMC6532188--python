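"""Score-construction stage: HWE testing/filtering, imputation, PRS, scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import densprs as dp
from densprs.exceptions import ValidationError
from densprs.genotypes import (
    GenotypeMatrix,
    PRSWeights,
    assign_quantile_categories,
    compute_prs,
    format_cutpoints,
    genotype_counts,
    hwe_test,
    standardize_by_controls,
)


def make_matrix(dosages, effect="A", other="G"):
    dosages = np.asarray(dosages, dtype=float)
    n, s = dosages.shape
    return GenotypeMatrix(
        subject_ids=np.array([f"s{i}" for i in range(n)]),
        snp_ids=np.array([f"snp{j + 1:03d}" for j in range(s)]),
        effect_allele=np.repeat(effect, s),
        other_allele=np.repeat(other, s),
        dosages=dosages,
    )


def make_weights(values, snp_ids=None, effect="A", other="G"):
    values = np.asarray(values, dtype=float)
    if snp_ids is None:
        snp_ids = [f"snp{j + 1:03d}" for j in range(len(values))]
    return PRSWeights(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "effect_allele": effect,
                "other_allele": other,
                "weight_log_or": values,
            }
        )
    )


class TestHweTest:
    @pytest.mark.parametrize(
        "counts, stat, p",
        [
            ((25, 50, 25), 0.0, 1.0),  # exact HWE proportions
            ((30, 40, 30), 4.0, 0.04550026),  # hand computation at freq 0.5
        ],
    )
    def test_known_values(self, counts, stat, p):
        res = hwe_test(*counts)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-6)

    def test_no_heterozygotes_is_excludable(self):
        res = hwe_test(50, 0, 50)
        assert res.p_value < 1e-3

    def test_monomorphic_flagged_not_tested(self):
        res = hwe_test(0, 0, 40)
        assert res.p_value == 1.0 and res.monomorphic

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 5, 5)

    def test_matches_multinomial_oracle_on_all_small_triples(self):
        """Exhaustive agreement with an independent chi-square computation
        for every genotype-count triple with total <= 30."""
        for total in range(1, 31):
            for n2 in range(total + 1):
                for n1 in range(total - n2 + 1):
                    n0 = total - n2 - n1
                    p = (2 * n2 + n1) / (2 * total)
                    res = hwe_test(n2, n1, n0)
                    if p in (0.0, 1.0):
                        assert res.monomorphic
                        continue
                    expected = total * np.array(
                        [p * p, 2 * p * (1 - p), (1 - p) ** 2]
                    )
                    oracle = stats.chisquare([n2, n1, n0], expected, ddof=1)
                    assert res.statistic == pytest.approx(oracle.statistic, rel=1e-9)
                    assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-9)


class TestHweFilter:
    def test_clean_data_untouched(self, small_dataset):
        gm = small_dataset["genotypes"]
        subjects = small_dataset["subjects"]
        # threshold 0 can never exclude
        out, log = dp.apply_hwe_filter(
            gm, subjects["study"], subjects["status"], threshold=0.0
        )
        assert log == []
        assert np.array_equal(out.dosages, gm.dosages, equal_nan=True)

    def test_perturbed_block_and_only_that_block_masked(self):
        """A single SNP x study HWE violation masks exactly that block
        (relative to whatever the unperturbed data would have excluded)."""
        cfg = dp.scaled_config(1200, 2000, seed=19, missing_rate=0.0)
        subjects, gm, *_ = dp.generate_population(cfg)
        study = subjects["study"].to_numpy()
        target_study = cfg.study_names[2]
        pert = dp.perturb_hwe(
            gm, 10, 0.5, seed=55, subject_mask=study == target_study
        )
        _, log_base = dp.apply_hwe_filter(gm, study, subjects["status"])
        out, log_pert = dp.apply_hwe_filter(pert, study, subjects["status"])
        base_blocks = {(e.snp_id, e.study) for e in log_base}
        pert_blocks = {(e.snp_id, e.study) for e in log_pert}
        assert pert_blocks - base_blocks == {("snp011", target_study)}
        in_block = study == target_study
        assert np.isnan(out.dosages[in_block, 10]).all()
        assert not np.isnan(out.dosages[~in_block, 10]).any()

    def test_exclusion_log_carries_p_values(self):
        cfg = dp.scaled_config(500, 1500, seed=23, missing_rate=0.0)
        subjects, gm, *_ = dp.generate_population(cfg)
        pert = dp.perturb_hwe(gm, 0, 0.6, seed=5)
        _, log = dp.apply_hwe_filter(pert, subjects["study"], subjects["status"])
        assert all(e.p_value < 1e-3 for e in log)
        assert any(e.snp_id == "snp001" for e in log)


class TestImputation:
    def test_no_missing_is_identity(self):
        gm = make_matrix([[0, 1], [2, 1], [1, 0], [2, 2]])
        out = dp.impute_missing_mcmc(gm, seed=1)
        assert np.array_equal(out.dosages, gm.dosages)
        assert not out.imputed.any()

    def test_seed_determinism(self, small_dataset):
        gm = small_dataset["genotypes"]
        subjects = small_dataset["subjects"]
        a = dp.impute_missing_mcmc(gm, subjects["age_years"], subjects["bmi"], seed=3)
        b = dp.impute_missing_mcmc(gm, subjects["age_years"], subjects["bmi"], seed=3)
        assert np.array_equal(a.dosages, b.dosages)

    def test_observed_entries_never_overwritten(self, small_dataset):
        gm = small_dataset["genotypes"]
        subjects = small_dataset["subjects"]
        out = dp.impute_missing_mcmc(gm, subjects["age_years"], subjects["bmi"], seed=3)
        obs = ~gm.missing_mask
        assert np.array_equal(out.dosages[obs], gm.dosages[obs])
        assert not out.missing_mask.any()
        assert np.array_equal(out.imputed, gm.missing_mask)

    def test_mcar_imputed_means_match_allele_frequency(self):
        """Under MCAR the mean imputed dosage per SNP approaches 2*MAF."""
        cfg = dp.scaled_config(
            3000, 3000, seed=29, missing_rate=0.0,
            beta_pd=0.0, beta_da=0.0, beta_prs=0.0, rho_prs_density=0.0,
        )
        subjects, gm, *_ = dp.generate_population(cfg)
        gm = dp.inject_missingness(gm, 0.05, seed=31)
        out = dp.impute_missing_mcmc(gm, subjects["age_years"], subjects["bmi"], seed=7)
        maf, _ = cfg.resolved_snp_params()
        miss = gm.missing_mask
        devs = []
        for j in range(gm.n_snps):
            rows = miss[:, j]
            if rows.sum() < 30:
                continue
            imput_mean = out.dosages[rows, j].mean()
            se = np.sqrt(2 * maf[j] * (1 - maf[j]) / rows.sum())
            devs.append(abs(imput_mean - 2 * maf[j]) / se)
        # individually within ~4 SE and unbiased on average
        assert np.mean(devs) < 1.8
        assert np.quantile(devs, 0.95) < 4.0

    def test_all_missing_snp_rejected(self):
        gm = make_matrix([[0, np.nan], [1, np.nan], [2, np.nan]])
        with pytest.raises(ValidationError, match="no observed dosage"):
            dp.impute_missing_mcmc(gm, seed=1)


class TestComputePrs:
    def test_hand_computed_sum(self):
        gm = make_matrix([[1, 2]])
        w = make_weights([np.log(1.1), np.log(1.2)])
        assert compute_prs(gm, w)[0] == pytest.approx(0.45995, abs=5e-6)

    def test_zero_dosages_zero_score(self):
        gm = make_matrix(np.zeros((3, 4)))
        w = make_weights([0.1, 0.2, -0.1, 0.05])
        assert np.all(compute_prs(gm, w) == 0)

    def test_linearity_in_weights(self, rng):
        gm = make_matrix(rng.integers(0, 3, size=(20, 6)))
        w1 = make_weights(rng.normal(0, 0.1, 6))
        w2 = make_weights(2 * w1.weights)
        assert np.allclose(compute_prs(gm, w2), 2 * compute_prs(gm, w1))

    def test_invariant_to_snp_column_order(self, rng):
        d = rng.integers(0, 3, size=(15, 5)).astype(float)
        gm = make_matrix(d)
        w = make_weights(rng.normal(0, 0.1, 5))
        perm = rng.permutation(5)
        gm_perm = GenotypeMatrix(
            subject_ids=gm.subject_ids,
            snp_ids=gm.snp_ids[perm],
            effect_allele=gm.effect_allele[perm],
            other_allele=gm.other_allele[perm],
            dosages=d[:, perm],
        )
        assert np.allclose(compute_prs(gm, w), compute_prs(gm_perm, w))

    def test_opposite_orientation_flips_dosage(self):
        gm = make_matrix([[2, 0]], effect="G", other="A")  # counts the other allele
        w = make_weights([1.0, 1.0], effect="A", other="G")
        assert compute_prs(gm, w)[0] == pytest.approx((2 - 2) + (2 - 0))

    def test_missing_dosage_rejected(self):
        gm = make_matrix([[1, np.nan]])
        with pytest.raises(ValidationError, match="missing"):
            compute_prs(gm, make_weights([0.1, 0.2]))

    def test_absent_snp_listed(self):
        gm = make_matrix([[1, 0]])
        w = make_weights([0.1, 0.2, 0.3], snp_ids=["snp001", "snp002", "snpX"])
        with pytest.raises(ValidationError, match="snpX"):
            compute_prs(gm, w)

    def test_filter_impute_score_is_identity_on_clean_data(self, rng):
        """On complete HWE-clean data the staged path equals the direct sum."""
        maf = rng.uniform(0.2, 0.5, 8)
        d = rng.binomial(2, maf, size=(500, 8)).astype(float)
        gm = make_matrix(d)
        w = make_weights(rng.normal(0, 0.1, 8))
        study = np.repeat("S1", 500)
        status = rng.integers(0, 2, 500)
        filtered, _ = dp.apply_hwe_filter(gm, study, status, threshold=1e-12)
        imputed = dp.impute_missing_mcmc(filtered, seed=2)
        assert np.allclose(compute_prs(imputed, w), d @ w.weights)


class TestStandardizeAndCategories:
    def test_three_controls_hand_case(self):
        z = standardize_by_controls([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_idempotent_on_standard_controls(self, rng):
        x = rng.normal(size=200)
        status = np.zeros(200, dtype=int)
        z = standardize_by_controls(x, status)
        assert np.allclose(standardize_by_controls(z, status), z)

    def test_control_moments_exact(self, small_dataset):
        frame = small_dataset["frame"]
        ctrl = frame.loc[frame["status"] == 0, "prs_z"]
        assert ctrl.mean() == pytest.approx(0.0, abs=1e-12)
        assert ctrl.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            standardize_by_controls([1.0, 1.0, 5.0], [0, 0, 1])

    def test_cases_shift_up_under_positive_effect(self, small_dataset):
        frame = small_dataset["frame"]
        assert frame.loc[frame["status"] == 1, "prs_z"].mean() > 0.2

    def test_uniform_controls_get_equal_bins(self):
        values = np.arange(1.0, 101.0)
        labels, cut = assign_quantile_categories(values, np.zeros(100, int), k=4)
        assert np.array_equal(np.bincount(labels)[1:], [25, 25, 25, 25])

    def test_control_counts_equal_within_one(self, small_dataset):
        frame = small_dataset["frame"]
        ctrl = frame[frame["status"] == 0]
        counts = ctrl["prs_quintile"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            assign_quantile_categories(np.ones(50), np.zeros(50, int), k=5)

    def test_case_counts_increase_across_prs_quintiles(self, small_dataset):
        frame = small_dataset["frame"]
        cases = frame[frame["status"] == 1]
        counts = cases["prs_quintile"].value_counts().sort_index().to_numpy()
        assert np.all(np.diff(counts) > 0)

    def test_cutpoint_report_format(self):
        values = np.arange(1.0, 101.0)
        _, cut = assign_quantile_categories(values, np.zeros(100, int), k=5)
        text = format_cutpoints(cut, values, name="quintile")
        assert text.startswith("quintile 1, 1.000 to ")
        assert text.count(";") == 4
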