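import numpy as np
import pytest
from scipy import stats as sps

import dfcstates as d


class TestOneWayAnova:
    def test_equal_means_give_zero_f(self):
        res = d.one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        res = d.one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2, abs=1e-10)

    def test_hand_computed_sums_of_squares(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [10.0, 11, 12]]
        # grand mean 16/3; SSB = 3[(2-16/3)^2+(3-16/3)^2+(11-16/3)^2] = 146
        # SSW = 2+2+2 = 6; F = (146/2)/(6/6) = 73
        res = d.one_way_anova(groups)
        assert res.statistic == pytest.approx(73.0, abs=1e-10)
        assert res.df == (2, 6)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, size=20) for m in (0.0, 0.3, 0.6)]
        res = d.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            d.one_way_anova([[1.0, 1.0], [1.0, 1.0]])


class TestSummaryAnova:
    def test_equal_means_zero_f(self):
        res = d.one_way_anova_from_summary([1.0, 1.0], [0.5, 0.5], [10, 10])
        assert res.statistic == pytest.approx(0.0)

    def test_agrees_with_raw_anova(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, size=n) for m, n in ((0, 12), (0.4, 9), (0.8, 15))]
        raw = d.one_way_anova(groups)
        summ = d.one_way_anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [g.size for g in groups],
        )
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-12)

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            d.one_way_anova_from_summary([1.0], [0.1], [10])
        with pytest.raises(ValueError):
            d.one_way_anova_from_summary([1.0, 2.0], [0.1, -0.1], [10, 10])


class TestPairwiseBonferroni:
    def test_adjustment_multiplies_by_pair_count(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, size=30) for m in (0, 0.5, 1.0)]
        results = d.pairwise_bonferroni(groups)
        assert len(results) == 3
        for res in results:
            assert res.adjusted_p == pytest.approx(min(1.0, 3 * res.p_value))

    def test_identical_groups_t_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = d.pairwise_bonferroni([g, g])[0]
        assert res.statistic == pytest.approx(0.0)
        assert res.adjusted_p == 1.0

    def test_comparison_labels(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=5) for _ in range(3)]
        labels = [r.comparison for r in d.pairwise_bonferroni(groups, ["NC", "SCD", "AD"])]
        assert labels == ["NC vs SCD", "NC vs AD", "SCD vs AD"]


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        res = d.chi_square_test([[10, 20], [10, 20]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # table (10,20 / 20,10): all expected counts 15,
        # chi2 = 4 * 25/15 = 20/3, df = 1
        res = d.chi_square_test([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-10)
        assert res.df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            d.chi_square_test([[0, 0], [5, 5]])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = d.partial_correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref_r, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)
        assert res.df == 38

    def test_degrees_of_freedom_with_three_covariates(self):
        rng = np.random.default_rng(6)
        res = d.partial_correlation(
            rng.normal(size=81), rng.normal(size=81), rng.normal(size=(81, 3))
        )
        assert res.df == 76

    def test_perfect_partial_association(self):
        rng = np.random.default_rng(7)
        cov = rng.normal(size=(50, 2))
        x = rng.normal(size=50)
        y = x + cov @ [2.0, -1.0]
        res = d.partial_correlation(x, y, cov)
        assert res.statistic == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_and_covariate_affine_invariant(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=60), rng.normal(size=60)
        cov = rng.normal(size=(60, 2))
        a = d.partial_correlation(x, y, cov)
        b = d.partial_correlation(y, x, cov)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        scaled = cov * [10.0, -0.5] + [3.0, 7.0]
        c = d.partial_correlation(x, y, scaled)
        assert a.statistic == pytest.approx(c.statistic, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=70),
                "y": rng.normal(size=70),
                "c1": rng.normal(size=70),
                "c2": rng.normal(size=70),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        res = d.partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(10)
        c = rng.normal(size=50)
        with pytest.raises(ValueError):
            d.partial_correlation(
                rng.normal(size=50), rng.normal(size=50), np.column_stack([c, 2 * c])
            )

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            d.partial_correlation([1.0, 2, 3], [1.0, 2, 3], np.ones((3, 2)))


def test_group_permutation_invariance():
    rng = np.random.default_rng(11)
    groups = [rng.normal(m, 1, size=15) for m in (0, 0.5, 1.0)]
    f1 = d.one_way_anova(groups).statistic
    f2 = d.one_way_anova(groups[::-1]).statistic
    assert f1 == pytest.approx(f2, abs=1e-10)
    p1 = {frozenset(r.comparison.split(" vs ")): r.p_value
          for r in d.pairwise_bonferroni(groups, ["a", "b", "c"])}
    p2 = {frozenset(r.comparison.split(" vs ")): r.p_value
          for r in d.pairwise_bonferroni(groups[::-1], ["c", "b", "a"])}
    for key in p1:
        assert p1[key] == pytest.approx(p2[key], abs=1e-12)
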