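"""Break-depth split, Wilcoxon rank-sum, permutation test and regressions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fjordsurvey import stats as fstats
from fjordsurvey.errors import BreakSplitError, CollinearityError, DataError


def bins_at(centres, values=None):
    centres = np.asarray(centres, dtype=float)
    return pd.DataFrame({
        "bin_lower_m": centres - 5.0,
        "bin_upper_m": centres + 5.0,
        "bin_centre_m": centres,
        "abundance": values if values is not None else np.arange(len(centres), dtype=float),
    })


class TestSplitByBreak:
    def test_bin_containing_break_goes_above(self):
        bins = bins_at([265, 275, 285], [1.0, 2.0, 3.0])
        above, below = fstats.split_by_break(bins, 275.0)
        assert sorted(above) == [1.0, 2.0]
        assert list(below) == [3.0]

    def test_break_at_zero_is_degenerate(self):
        with pytest.raises(BreakSplitError):
            fstats.split_by_break(bins_at([265, 275, 285]), 0.0)

    def test_all_bins_on_one_side(self):
        with pytest.raises(BreakSplitError):
            fstats.split_by_break(bins_at([15, 25, 35]), 275.0)


def enumeration_oracle(a, b):
    """Exhaustive two-sided rank-sum p by assigning the pooled values to group
    a in every possible way (independent of the rank-combination route)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = [ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), n_a)]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        W, p, method = fstats.wilcoxon_two_sample([1, 2, 3], [4, 5, 6])
        assert W == 6.0
        assert method == "exact"
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_multisets_give_p_one(self):
        _, p, _ = fstats.wilcoxon_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_constant_everything_degenerate(self):
        _, p, method = fstats.wilcoxon_two_sample([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0 and method == "degenerate"

    def test_strong_shift_large_n(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, 20)
        _, p, method = fstats.wilcoxon_two_sample(b + 1000.0, b)
        assert method == "normal"
        assert p < 0.001

    @pytest.mark.parametrize("n_a,n_b", [(n_a, n_b) for n_a in range(1, 7)
                                         for n_b in range(1, 7)])
    def test_exact_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(100 * n_a + n_b)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # distinct, no ties
            a, b = pooled[:n_a], pooled[n_a:]
            _, p, method = fstats.wilcoxon_two_sample(a, b)
            assert method == "exact"
            assert p == pytest.approx(enumeration_oracle(a, b), abs=1e-12)

    def test_exact_matches_scipy_exact(self):
        """Dual route: scipy's exact Mann-Whitney agrees with the enumeration."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            _, p, _ = fstats.wilcoxon_two_sample(a, b)
            sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(sp, abs=1e-9)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0.8, 1, 4)
        b = rng.normal(0.0, 1, 4)
        _, p_exact, _ = fstats.wilcoxon_two_sample(a, b)
        # force the approximation by duplicating scale-free: compare to scipy's
        # tie-corrected normal route on the same data
        p_norm = sps.ranksums(a, b).pvalue
        assert p_norm == pytest.approx(p_exact, abs=0.08)

    def test_normal_route_matches_scipy_ranksums(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.3, 1, 15)
        b = rng.normal(0.0, 1, 12)
        _, p, method = fstats.wilcoxon_two_sample(a, b)
        assert method == "normal"
        assert p == pytest.approx(sps.ranksums(a, b).pvalue, rel=1e-9)


class TestPermutation:
    def test_complete_separation_is_near_minimal(self):
        """Only relabellings that reproduce the observed grouping tie the
        statistic: p concentrates near (1 + B/20) / (B + 1)."""
        B = 10_000
        p = fstats.permutation_test([10.0, 10.0, 10.0], [0.0, 0.0, 0.0], B=B, seed=0)
        assert 1.0 / (B + 1) <= p < 0.12

    def test_identical_constant_groups(self):
        p = fstats.permutation_test([5.0, 5.0], [5.0, 5.0], B=999, seed=1)
        assert p == 1.0

    def test_converges_to_exact_tail(self):
        """3 vs 3 distinct values: Monte-Carlo p approaches the exact
        enumeration tail probability."""
        a, b = np.array([9.0, 7.0, 5.0]), np.array([4.0, 2.0, 1.0])
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        exact_tail = np.mean([
            np.mean(pooled[list(idx)]) - np.mean(np.delete(pooled, list(idx))) >= obs - 1e-12
            for idx in itertools.combinations(range(6), 3)
        ])
        B = 40_000
        p = fstats.permutation_test(a, b, B=B, seed=7)
        se = math.sqrt(exact_tail * (1 - exact_tail) / B)
        assert p == pytest.approx(exact_tail, abs=4 * se + 2 / B)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        p1 = fstats.permutation_test(a, b, B=500, seed=42)
        p2 = fstats.permutation_test(a, b, B=500, seed=42)
        assert p1 == p2

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            fstats.permutation_test([1.0, np.nan], [0.0], B=10, seed=0)

    def test_two_sided_at_least_one_sided(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 8)
        p1 = fstats.permutation_test(a, b, B=2000, seed=3, alternative="greater")
        p2 = fstats.permutation_test(a, b, B=2000, seed=3, alternative="two-sided")
        assert p2 >= p1 - 1e-12


class TestRegress:
    def test_perfect_linear_fit(self):
        bins = bins_at(np.arange(10) * 10 + 5)
        bins["pH"] = np.linspace(8.3, 7.7, 10)
        bins["abundance"] = 3.0 * bins["pH"] - 10.0
        r = fstats.regress(bins, "abundance", "pH")
        assert r.adjusted_r2 == pytest.approx(1.0)
        assert r.slopes["pH"] == pytest.approx(3.0)

    def test_adjusted_r2_closed_form(self):
        rng = np.random.default_rng(1)
        bins = bins_at(np.arange(50) * 10 + 5)
        bins["pH"] = rng.normal(8, 0.1, 50)
        bins["abundance"] = rng.normal(10, 2, 50)  # independent noise
        r = fstats.regress(bins, "abundance", "pH")
        n, p = r.n, 1
        assert r.adjusted_r2 == pytest.approx(1 - (1 - r.r2) * (n - 1) / (n - p - 1), abs=1e-12)
        assert abs(r.adjusted_r2) < 0.2  # near zero, negative allowed

    def test_missing_predictor_rows_dropped_pairwise(self):
        bins = bins_at(np.arange(20) * 10 + 5)
        bins["salinity"] = np.where(np.arange(20) < 5, np.nan, 32.0 + np.arange(20) * 0.01)
        r = fstats.regress(bins, "abundance", "salinity")
        assert r.n == 15

    def test_surface_exclusion_drops_shallow_bins(self):
        bins = bins_at([5.0, 15.0, 25.0, 35.0, 45.0], [1.0, 2.0, 3.0, 2.5, 3.5])
        bins["pH"] = [8.4, 8.0, 7.9, 7.95, 7.85]
        r = fstats.regress(bins, "abundance", "pH", exclude_surface=True)
        assert r.n == 4 and r.surface_excluded

    def test_collinear_predictors_named(self):
        bins = bins_at(np.arange(10) * 10 + 5)
        bins["pH"] = 8.0
        bins["pH2"] = 8.0
        with pytest.raises(CollinearityError, match="pH"):
            fstats.regress(bins, "abundance", ["pH", "pH2"])

    def test_multiple_fit_reports_all_slopes(self):
        rng = np.random.default_rng(4)
        bins = bins_at(np.arange(30) * 10 + 5)
        bins["pH"] = rng.normal(8, 0.1, 30)
        bins["oxygen_umol_l"] = rng.normal(160, 20, 30)
        bins["abundance"] = 2.0 * bins["pH"] + 0.05 * bins["oxygen_umol_l"] + rng.normal(0, 0.01, 30)
        r = fstats.regress(bins, "abundance", ["pH", "oxygen_umol_l"])
        assert set(r.slopes) == {"pH", "oxygen_umol_l"}
        assert r.slopes["pH"] == pytest.approx(2.0, rel=0.05)


def test_test_break_bundles_everything():
    rng = np.random.default_rng(6)
    centres = np.arange(10, 360, 10, dtype=float) + 5
    values = np.where(centres < 275, rng.normal(40, 5, centres.size),
                      rng.normal(8, 2, centres.size))
    bins = bins_at(centres, values)
    res = fstats.test_break(bins, 275.0, B=2000, seed=9)
    assert res.n_above + res.n_below == centres.size
    assert res.statistic > 0
    assert res.wilcoxon_p < 0.001  # the headline contrast is overwhelming
    assert res.perm_p <= 0.05
    assert 1.0 / (res.B + 1) <= res.perm_p <= 1.0
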