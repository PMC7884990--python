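"""Statistical toolkit: oracle and cross-library checks."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from sparenet.stats import (
    bh_fdr,
    bootstrap_ci_bca,
    cohen_d,
    paired_t,
    permutation_slope_test,
    ranksum_exact,
    robust_slope,
    spearman_rho,
)


def enumeration_ranksum_p(x, y, alternative):
    """Brute-force exact p: enumerate every assignment of pooled ranks."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n1 = len(x)
    obs = ranks[:n1].sum()
    hits = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        w = ranks[list(subset)].sum()
        total += 1
        if alternative == "greater":
            hits += w >= obs - 1e-12
        else:
            hits += w <= obs + 1e-12
    return hits / total


class TestRanksum:
    def test_minimal_example(self):
        res = ranksum_exact([1, 2], [3, 4], alternative="less")
        assert res.pvalue == pytest.approx(1 / 6)

    def test_single_pair(self):
        assert ranksum_exact([1], [2], "less").pvalue == pytest.approx(0.5)
        assert ranksum_exact([1], [2], "greater").pvalue == pytest.approx(1.0)

    def test_identical_samples_symmetric(self):
        x = [1.0, 2.0, 3.0]
        assert ranksum_exact(x, x, "greater").pvalue >= 0.5
        assert ranksum_exact(x, x, "less").pvalue >= 0.5

    @pytest.mark.parametrize("n1", [1, 2, 3, 4])
    def test_matches_enumeration_oracle(self, rng, n1):
        for _ in range(5):
            pool = rng.integers(0, 5, size=8).astype(float)  # ties likely
            x, y = pool[:n1], pool[n1:]
            for alt in ("greater", "less"):
                res = ranksum_exact(x, y, alt)
                assert res.pvalue == pytest.approx(
                    enumeration_ranksum_p(x, y, alt), abs=1e-12)
                assert res.method == "ranksum-exact"

    def test_matches_scipy_exact_untied(self, rng):
        x = rng.normal(0, 1, 7)
        y = rng.normal(1, 1, 6)
        res = ranksum_exact(x, y, "less")
        ref = sps.mannwhitneyu(x, y, alternative="less", method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_beyond_cap(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 20)
        res = ranksum_exact(x, y, "less")
        assert res.method == "ranksum-normal-approx"
        ref = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            ranksum_exact([], [1.0], "greater")


class TestCohenD:
    def test_unit_pooled_sd(self):
        assert cohen_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)
        assert cohen_d([3, 4, 5], [1, 2, 3]) == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        assert cohen_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_shift_invariance(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        assert cohen_d(x + 5, y + 5) == pytest.approx(cohen_d(x, y))

    def test_zero_pooled_sd_error(self):
        with pytest.raises(ValueError):
            cohen_d([1, 1], [1, 1])


class TestBCa:
    def test_constant_sample_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bootstrap_ci_bca([2.0] * 10, np.median, n_resamples=100, seed=0)
        assert lo == hi == 2.0

    def test_seeded_determinism(self, rng):
        x = rng.normal(0, 1, 25)
        a = bootstrap_ci_bca(x, np.median, n_resamples=500, seed=42)
        b = bootstrap_ci_bca(x, np.median, n_resamples=500, seed=42)
        assert a == b

    def test_against_scipy_bca(self, rng):
        x = rng.normal(0, 1, 40)
        lo, hi = bootstrap_ci_bca(x, np.mean, n_resamples=4000, seed=3)
        ref = sps.bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                            confidence_level=0.95, random_state=3)
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.08)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.08)

    def test_interval_contains_point_estimate(self, rng):
        x = rng.exponential(1.0, 30)
        lo, hi = bootstrap_ci_bca(x, np.median, n_resamples=2000, seed=1)
        assert lo <= np.median(x) <= hi


class TestBH:
    def test_worked_examples(self):
        reject, adj = bh_fdr([0.01, 0.02, 0.04], q=0.05)
        assert reject.all()
        reject, _ = bh_fdr([0.03, 0.5, 0.9], q=0.05)
        assert not reject.any()

    def test_empty(self):
        reject, adj = bh_fdr([])
        assert reject.size == 0 and adj.size == 0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50) ** 2
        reject, adj = bh_fdr(p, q=0.05)
        ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(reject, ref_rej)
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)

    def test_at_least_bonferroni(self, rng):
        p = rng.random(30) ** 3
        bh_rej, _ = bh_fdr(p, q=0.05)
        bonf_rej = p <= 0.05 / p.size
        assert (bh_rej | ~bonf_rej).all()


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_rho(x, [2, 4, 6, 9]).statistic == pytest.approx(1.0)
        assert spearman_rho(x, [9, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_tied_example_matches_scipy(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([3.0, 3.0, 1.0, 4.0, 4.0, 6.0, 6.0])
        res = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestRobustSlope:
    def test_matches_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0, 1, 40)
        y = 2.0 * x + rng.normal(0, 0.5, 40)
        y[:3] += 10  # outliers
        ours = robust_slope(x, y)
        ref = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight()).fit()
        assert ours == pytest.approx(ref.params[1], abs=0.05)

    def test_outlier_resistance(self, rng):
        x = np.arange(20.0)
        y = 3.0 * x + rng.normal(0, 0.1, 20)
        y[-1] += 500
        assert robust_slope(x, y) == pytest.approx(3.0, abs=0.05)


class TestPermutationSlope:
    def test_perfect_collinearity_extreme_p(self):
        # only (near-)monotone permutations can match the observed |slope|,
        # so the p-value sits at the bottom of its attainable range
        x = np.arange(10.0)
        res = permutation_slope_test(x, 2 * x, n_perm=999, seed=0)
        assert res.statistic == pytest.approx(2.0, abs=1e-8)
        assert res.pvalue <= 0.01

    def test_seeded_determinism(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        a = permutation_slope_test(x, y, n_perm=99, seed=7)
        b = permutation_slope_test(x, y, n_perm=99, seed=7)
        assert a.pvalue == b.pvalue and a.statistic == b.statistic

    def test_null_p_not_extreme(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        res = permutation_slope_test(x, y, n_perm=199, seed=5)
        assert res.pvalue > 0.005


class TestPairedT:
    def test_hand_arithmetic(self):
        res = paired_t([2, 4, 6], [1, 2, 3])  # diffs {1, 2, 3}
        assert res.statistic == pytest.approx(2 * np.sqrt(3))

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_matches_scipy(self, rng):
        pre = rng.normal(1, 1, 12)
        post = rng.normal(0, 1, 12)
        res = paired_t(pre, post)
        ref = sps.ttest_rel(pre, post)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-10)
        lo, hi = ref.confidence_interval(0.95)
        assert res.ci == (pytest.approx(lo, rel=1e-9), pytest.approx(hi, rel=1e-9))


class TestHypothesisProperties:
    """Invariants over arbitrary inputs (derandomized)."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bh_adjusted_p_bounds(self, pvals):
        reject, adj = bh_fdr(pvals, q=0.05)
        p = np.asarray(pvals)
        assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
        # rejected p-values are never larger than every accepted one
        if reject.any() and (~reject).any():
            assert p[reject].max() <= p[~reject].min() + 1e-12

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2,
                    max_size=15),
           st.lists(st.floats(min_value=-50, max_value=50), min_size=2,
                    max_size=15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cohen_d_antisymmetry(self, x, y):
        try:
            d = cohen_d(x, y)
        except ValueError:
            return  # zero pooled SD
        assert cohen_d(y, x) == pytest.approx(-d, rel=1e-9, abs=1e-12)
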