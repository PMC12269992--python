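"""Rank tests, mixed models, distributional tests, FDR, MAD, SVM separation."""

import numpy as np
import pandas as pd
import pytest

from brainarrow.errors import ParameterError
from brainarrow.group_stats import (
    bh_fdr,
    clinical_correlation,
    clinical_correlations,
    energy_test,
    lmm_contrast,
    mad_screen,
    mmd2_test,
    pattern_separation,
    rank_tests,
)


def lmm_table(rng, n_sub=20, n_val=50, effect=0.0, re_sd=0.1, noise_sd=0.1):
    rows = []
    for s in range(n_sub):
        cohort = "patient" if s < n_sub // 2 else "control"
        intercept = re_sd * rng.standard_normal() + (effect if cohort == "patient" else 0.0)
        age = rng.uniform(45, 80)
        sex = rng.choice(["F", "M"])
        for v in intercept + noise_sd * rng.standard_normal(n_val):
            rows.append(dict(subject=f"s{s:02d}", value=float(v),
                             cohort=cohort, age=age, sex=sex))
    return pd.DataFrame(rows)


class TestRankTests:
    def test_identical_samples_p_near_one(self):
        res = rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=0.11)

    def test_fully_separated_exact_p(self):
        # exhaustive null: 20 equally likely rank assignments, two-sided
        res = rank_tests([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.p_value == pytest.approx(0.1, rel=1e-9)
        assert res.direction == -1

    def test_all_tied_warns_p_one(self):
        res = rank_tests([5.0] * 4, [5.0] * 4)
        assert res.p_value == 1.0

    def test_brown_forsythe_detects_variance_difference(self, rng):
        a = rng.standard_normal(40)
        b = 5.0 * rng.standard_normal(40)
        res = rank_tests(a, b, kind="brownforsythe")
        assert res.p_value < 0.001
        assert res.direction == -1

    def test_too_small_samples_rejected(self):
        with pytest.raises(ParameterError):
            rank_tests([1.0, 2.0], [3.0, 4.0, 5.0])


class TestLmmContrast:
    def test_recovers_injected_cohort_effect(self):
        rng = np.random.default_rng(42)
        res = lmm_contrast(lmm_table(rng, effect=1.0))
        assert 0.9 <= res.extra["estimate"] <= 1.1
        assert res.p_value < 1e-6
        assert res.direction == 1

    def test_single_value_per_subject_collapses_to_ols(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        df = lmm_table(rng, n_sub=16, n_val=1, effect=0.5)
        res = lmm_contrast(df)
        ols_df = df.assign(
            cohort_num=(df.cohort == "patient").astype(float),
            sex_num=pd.factorize(df.sex)[0].astype(float),
        )
        ols = smf.ols("value ~ cohort_num + age + sex_num", data=ols_df).fit()
        assert res.extra["estimate"] == pytest.approx(
            ols.params["cohort_num"], abs=1e-8)

    def test_missing_columns_rejected(self):
        with pytest.raises(ParameterError):
            lmm_contrast(pd.DataFrame({"subject": [], "value": []}))


class TestDistributionalTests:
    def test_mmd_disjoint_split_near_zero(self, rng):
        pooled = rng.standard_normal((40, 6))
        res = mmd2_test(pooled[:20], pooled[20:], n_perm=500, seed=0)
        assert res.p_value > 0.05
        assert abs(res.statistic) < 0.05

    def test_mmd_shift_fully_separates(self, rng):
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 5)) + 3.0
        res = mmd2_test(X, Y, n_perm=1000, seed=1)
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.statistic > 0

    def test_energy_shift_detected(self, rng):
        X = rng.standard_normal((15, 4))
        Y = rng.standard_normal((15, 4)) + 1.5
        res = energy_test(X, Y, n_perm=1000, seed=2)
        assert res.p_value <= 0.01

    def test_energy_single_observation_rejected(self, rng):
        with pytest.raises(ParameterError):
            energy_test(rng.standard_normal((1, 4)),
                        rng.standard_normal((10, 4)))

    def test_permutation_p_reproducible_and_add_one(self, rng):
        X = rng.standard_normal((12, 3))
        Y = rng.standard_normal((12, 3)) + 0.3
        r1 = mmd2_test(X, Y, n_perm=200, seed=7)
        r2 = mmd2_test(X, Y, n_perm=200, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 201
        # add-one formula: p is a multiple of 1/(n_perm + 1)
        assert (r1.p_value * 201) == pytest.approx(round(r1.p_value * 201))

    def test_rigid_shift_invariance(self, rng):
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 4)) + 0.5
        a = mmd2_test(X, Y, n_perm=100, seed=3)
        b = mmd2_test(X + 7.0, Y + 7.0, n_perm=100, seed=3)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        c = energy_test(X, Y, n_perm=100, seed=3)
        d = energy_test(X + 7.0, Y + 7.0, n_perm=100, seed=3)
        assert c.statistic == pytest.approx(d.statistic, abs=1e-10)


class TestFdrAndScreening:
    def test_bh_fdr_hand_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_adjusted_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        adj = bh_fdr(p)
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= p - 1e-12)

    def test_mad_flags_planted_outlier(self):
        mask = mad_screen([1.0, 2.0, 3.0, 100.0])
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_mad_symmetric_data_no_flags(self, rng):
        mask = mad_screen(rng.standard_normal(50))
        assert mask.all()

    def test_mad_zero_no_flags(self):
        assert mad_screen([2.0, 2.0, 2.0, 2.0]).all()


class TestClinicalCorrelation:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert clinical_correlation(x, x**3).statistic == pytest.approx(1.0)
        assert clinical_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_constant_score_reported_missing(self):
        res = clinical_correlation(np.arange(6.0), np.ones(6))
        assert np.isnan(res.statistic)

    def test_family_fdr_applied(self, rng):
        measures = {f"m{i}": rng.standard_normal(20) for i in range(5)}
        out = clinical_correlations(measures, rng.standard_normal(20))
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()


class TestPatternSeparation:
    def test_separated_clouds_near_perfect(self, rng):
        Xa = rng.standard_normal((15, 8))
        Xb = rng.standard_normal((15, 8)) + 10.0
        res = pattern_separation(Xa, Xb, seed=0, n_iterations=200)
        assert res.mean_accuracy >= 0.99
        assert res.mean_accuracy == pytest.approx(res.fold_accuracies.mean())

    def test_shuffled_labels_at_chance(self, rng):
        X = rng.standard_normal((30, 8))
        labels = rng.permutation([0] * 15 + [1] * 15).astype(bool)
        res = pattern_separation(X[labels], X[~labels], seed=1,
                                 n_iterations=300)
        assert 0.35 <= res.mean_accuracy <= 0.65

    def test_no_leakage_with_many_features(self, rng):
        # n << d pure noise: any leak of test-fold statistics inflates accuracy
        Xa = rng.standard_normal((10, 500))
        Xb = rng.standard_normal((10, 500))
        res = pattern_separation(Xa, Xb, seed=2, n_iterations=300)
        assert 0.25 <= res.mean_accuracy <= 0.75
        loo = pattern_separation(Xa, Xb, protocol="loocv_permutation", seed=3,
                                 n_permutations=50)
        assert 0.2 <= loo.mean_accuracy <= 0.8

    def test_loocv_permutation_minimal_p_when_separated(self, rng):
        Xa = rng.standard_normal((8, 6))
        Xb = rng.standard_normal((8, 6)) + 8.0
        res = pattern_separation(Xa, Xb, protocol="loocv_permutation", seed=4,
                                 n_permutations=100)
        assert res.mean_accuracy == 1.0
        assert res.permutation_p == pytest.approx(1 / 101)

    def test_label_swap_degrades_accuracy(self, rng):
        Xa = rng.standard_normal((12, 6))
        Xb = rng.standard_normal((12, 6)) + 8.0
        clean = pattern_separation(Xa, Xb, seed=5, n_iterations=150)
        swapped = pattern_separation(Xa, Xb, seed=5, n_iterations=150,
                                     label_swap_fraction=0.25)
        assert swapped.mean_accuracy < clean.mean_accuracy - 0.05

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ParameterError):
            pattern_separation(rng.standard_normal((3, 4)),
                               rng.standard_normal((8, 4)))
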