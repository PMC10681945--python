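"""Design-based estimators: means, trends, LS means, ratios, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_design, srs_design
from milksub import (SurveyDesign, lsmeans_by_age_group, paired_t,
                     percent_change, population_ratio, trend_regression,
                     weighted_mean)


class TestSurveyDesign:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SurveyDesign(np.array([-1.0, 1.0]), [0, 0], [0, 1])

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurveyDesign(np.zeros(3), [0, 0, 0], [0, 1, 2])

    def test_psu_labels_are_nested_within_strata(self):
        # identical PSU labels in different strata are distinct clusters
        d = SurveyDesign(np.ones(4), [0, 0, 1, 1], ["P1", "P2", "P1", "P2"])
        assert d.n_psus == 4
        assert d.degrees_of_freedom == 2

    def test_cycle_pooling_divides_weights(self):
        d = SurveyDesign(np.full(4, 9.0), [0, 0, 0, 0], [0, 1, 2, 3], n_cycles=9)
        assert np.allclose(d.analysis_weight, 1.0)


class TestWeightedMean:
    def test_srs_limit_matches_classical_formula(self):
        res = weighted_mean([1.0, 2.0, 3.0], srs_design(3))
        assert res.estimate == pytest.approx(2.0)
        assert res.se == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_constant_outcome_has_zero_se(self):
        res = weighted_mean(np.full(6, 4.2), srs_design(6))
        assert res.se == 0.0

    def test_two_strata_fixture_matches_exact_expansion(self):
        """2 strata x 2 PSUs x 2 subjects with unequal weights: the variance
        equals the hand-expanded 8-term sum (computed in exact rationals:
        estimate 47/20, variance 313/8000)."""
        d = SurveyDesign(weight=np.array([1, 2, 3, 4, 5, 1, 2, 2], dtype=float),
                         stratum=["A", "A", "A", "A", "B", "B", "B", "B"],
                         psu=["1", "1", "2", "2", "1", "1", "2", "2"])
        res = weighted_mean(np.array([1, 2, 3, 1, 2, 5, 4, 3], dtype=float), d)
        assert res.estimate == pytest.approx(47 / 20, rel=1e-14)
        assert res.se**2 == pytest.approx(313 / 8000, rel=1e-12)

    def test_single_psu_stratum_raises_naming_it(self):
        d = SurveyDesign(np.ones(3), ["h1", "h1", "lonely"], [0, 1, 0])
        with pytest.raises(ValueError, match="lonely"):
            weighted_mean([1.0, 2.0, 3.0], d)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_equal_weight_independent_psus_reproduce_sd_over_sqrt_n(self, ys):
        y = np.asarray(ys)
        res = weighted_mean(y, srs_design(len(y)))
        assert res.estimate == pytest.approx(y.mean(), rel=1e-12, abs=1e-12)
        assert res.se == pytest.approx(y.std(ddof=1) / np.sqrt(len(y)),
                                       rel=1e-12, abs=1e-12)

    def test_zero_weight_subject_contributes_nothing(self):
        d = SurveyDesign(np.array([1.0, 1.0, 0.0]), [0, 0, 0], [0, 1, 2])
        res = weighted_mean(np.array([1.0, 3.0, 1e6]), d)
        assert res.estimate == pytest.approx(2.0)


class TestTrendRegression:
    def test_exact_linear_outcome_recovers_slope_with_zero_se(self):
        rng = np.random.default_rng(0)
        d = random_design(rng, 3, 2)
        age = rng.integers(6, 19, len(d)).astype(float)
        y = 5.0 - 1.25 * age
        fit = trend_regression(y, age, d)
        assert fit.beta == pytest.approx(-1.25, rel=1e-10)
        assert fit.se == pytest.approx(0.0, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        d = random_design(rng, 3, 2)
        n = len(d)
        age = rng.integers(6, 19, n).astype(float)
        y = 2.0 * age + rng.normal(0, 5, n)
        cov = pd.DataFrame({"sex": rng.choice(["male", "female"], n)})
        fit = trend_regression(y, age, d, cov)
        perm = rng.permutation(n)
        d2 = SurveyDesign(d.weight[perm], d.stratum[perm], d.psu[perm])
        fit2 = trend_regression(y[perm], age[perm], d2, cov.iloc[perm].reset_index(drop=True))
        assert fit2.beta == pytest.approx(fit.beta, rel=1e-10)
        assert fit2.se == pytest.approx(fit.se, rel=1e-8)

    def test_point_estimate_matches_statsmodels_wls(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        d = random_design(rng, 4, 3)
        n = len(d)
        age = rng.integers(6, 19, n).astype(float)
        y = 1.0 + 0.8 * age + rng.normal(0, 3, n)
        fit = trend_regression(y, age, d)
        X = sm.add_constant(age)
        ref = sm.WLS(y, X, weights=d.analysis_weight).fit()
        assert fit.beta == pytest.approx(ref.params[1], rel=1e-9)

    def test_collinear_covariate_dropped_not_fatal(self):
        rng = np.random.default_rng(3)
        d = random_design(rng, 3, 2)
        n = len(d)
        age = rng.integers(6, 19, n).astype(float)
        cov = pd.DataFrame({"a": np.where(age > 12, "old", "young"),
                            "b": np.where(age > 12, "o", "y")})  # duplicate info
        fit = trend_regression(age * 2.0, age, d, cov)
        assert len(fit.dropped_terms) >= 1
        assert np.isfinite(fit.beta)

    def test_too_few_psus_raises(self):
        d = SurveyDesign(np.ones(4), [0, 0, 1, 1], [0, 0, 0, 0])
        # 2 clusters, 2 strata -> zero degrees of freedom
        with pytest.raises(ValueError, match="degrees of freedom"):
            trend_regression(np.arange(4.0), np.arange(4.0), d)


class TestLsMeans:
    def test_constant_covariates_reduce_to_group_weighted_means(self):
        rng = np.random.default_rng(4)
        d = random_design(rng, 3, 2)
        n = len(d)
        age_group = rng.choice(["6-8", "9-13", "14-18"], n)
        y = rng.normal(50, 10, n)
        cov = pd.DataFrame({"sex": ["female"] * n})
        table = lsmeans_by_age_group(y, age_group, d, cov)
        for _, row in table.iterrows():
            mask = age_group == row["age_group"]
            direct = np.average(y[mask], weights=d.analysis_weight[mask])
            assert row["estimate"] == pytest.approx(direct, rel=1e-10)

    def test_single_age_group_equals_weighted_mean(self):
        rng = np.random.default_rng(5)
        d = random_design(rng, 2, 2)
        y = rng.normal(10, 2, len(d))
        table = lsmeans_by_age_group(y, ["6-18"] * len(d), d)
        assert len(table) == 1
        assert table["estimate"].iloc[0] == pytest.approx(
            weighted_mean(y, d).estimate, rel=1e-12)

    def test_recovers_known_group_means_with_balanced_covariates(self):
        rng = np.random.default_rng(6)
        truth = {"6-8": 30.0, "9-13": 20.0, "14-18": 10.0}
        n = 3000
        d = SurveyDesign(np.ones(n), np.arange(n) % 5, rng.integers(0, 4, n))
        groups = rng.choice(list(truth), n)
        sex = rng.choice(["male", "female"], n)
        y = (np.vectorize(truth.get)(groups) + np.where(sex == "male", 2.0, -2.0)
             + rng.normal(0, 5, n))
        table = lsmeans_by_age_group(y, groups, d, pd.DataFrame({"sex": sex}))
        for _, row in table.iterrows():
            assert abs(row["estimate"] - truth[row["age_group"]]) < 3 * row["se"]


class TestPopulationRatio:
    def test_source_equal_total_is_100(self):
        d = srs_design(4)
        res = population_ratio(np.full(4, 7.0), np.full(4, 7.0), d)
        assert res.percent == pytest.approx(100.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_simple_arithmetic(self):
        d = srs_design(2)
        res = population_ratio([10.0, 0.0], [50.0, 50.0], d)
        assert res.percent == pytest.approx(10.0)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            population_ratio([1.0, 1.0], [0.0, 0.0], srs_design(2))

    def test_partition_sums_to_100(self):
        rng = np.random.default_rng(7)
        d = random_design(rng, 3, 2)
        n = len(d)
        parts = rng.gamma(2, 10, (4, n))
        total = parts.sum(axis=0)
        s = sum(population_ratio(p, total, d).percent for p in parts)
        assert s == pytest.approx(100.0, abs=1e-9)


class TestPairedT:
    def test_no_change_gives_t_zero_p_one(self):
        d = srs_design(5)
        res = paired_t(np.ones(5), np.ones(5), d)
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_is_degenerate(self):
        d = srs_design(5)
        base = np.arange(5.0)
        res = paired_t(base, base + 5.0, d)
        assert res.mean_diff == pytest.approx(5.0)
        assert res.se == 0.0 and res.degenerate
        assert res.p < 1e-300

    def test_equals_weighted_mean_of_differences(self):
        rng = np.random.default_rng(8)
        d = random_design(rng, 3, 2)
        n = len(d)
        base = rng.gamma(5, 10, n)
        adj = base + rng.normal(1, 2, n)
        res = paired_t(base, adj, d)
        ref = weighted_mean(adj - base, d)
        assert res.mean_diff == pytest.approx(ref.estimate, rel=1e-12)
        assert res.se == pytest.approx(ref.se, rel=1e-12)

    def test_unweighted_variant_ignores_weights(self):
        rng = np.random.default_rng(9)
        d = random_design(rng, 3, 2)
        n = len(d)
        diff = rng.normal(1, 1, n)
        res = paired_t(np.zeros(n), diff, d, weighted=False)
        ref = weighted_mean(diff, SurveyDesign(np.ones(n), d.stratum, d.psu))
        assert res.mean_diff == pytest.approx(ref.estimate, rel=1e-12)


class TestPercentChange:
    @pytest.mark.parametrize("frm,to,mode,expected", [
        (91.7, 34.9, "decrease", 62.0),
        (396.0, 776.0, "increase", 96.0),
        (33.6, 145.0, "increase", 332.0),
        (123.0, 350.0, "increase", 185.0),
        (100.0, 100.0, "increase", 0.0),
        (100.0, 100.0, "decrease", 0.0),
        (210.0, 190.0, "decrease", 9.5),   # one decimal kept below 10
        (100.0, 187.5, "increase", 88.0),  # round half-up at .5
    ])
    def test_printed_convention(self, frm, to, mode, expected):
        assert percent_change(frm, to, mode) == expected

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_change(0.0, 5.0, "increase")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            percent_change(1.0, 2.0, "sideways")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.1, 1e4), st.floats(0.0, 1e4))
    def test_increase_and_decrease_are_mirrored(self, frm, to):
        assert percent_change(frm, to, "increase") == -percent_change(frm, to, "decrease")
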