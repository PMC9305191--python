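import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleodemo import (delta_theta, geometric_mean, group_summary,
                       interpolate_to_grid, mann_whitney_u,
                       pairwise_correlations)
from paleodemo.trend import build_trend_table


class TestInterpolateToGrid:
    def test_exact_at_support_points(self):
        times = np.array([1000.0, 2000.0, 3000.0])
        vals = np.array([5.0, 5.0, 9.0])
        s = interpolate_to_grid(times, vals, 1000.0)
        assert s.loc[1000.0] == 5.0 and s.loc[2000.0] == 5.0 and s.loc[3000.0] == 9.0

    def test_linear_midpoint(self):
        s = interpolate_to_grid([1000.0, 3000.0], [1.0, 3.0], 1000.0)
        assert s.loc[2000.0] == pytest.approx(2.0)

    def test_no_extrapolation(self):
        s = interpolate_to_grid([1500.0, 3500.0], [1.0, 3.0], 1000.0,
                                t_min=0.0, t_max=5000.0)
        assert math.isnan(s.loc[1000.0])
        assert math.isnan(s.loc[4000.0])
        assert not math.isnan(s.loc[2000.0])

    def test_step_must_match_analysis_grids(self):
        with pytest.raises(ValueError, match="step_years"):
            interpolate_to_grid([0.0, 1.0], [0.0, 1.0], 300.0)


class TestPairwiseCorrelations:
    def test_self_correlation_is_one(self):
        t = np.arange(0, 10_000, 1000.0)
        x = np.sin(t / 2000)
        table = build_trend_table({"a": pd.Series(x, index=t),
                                   "b": pd.Series(x, index=t)})
        corr = pairwise_correlations(table)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)
        assert corr.r.loc["a", "a"] == 1.0

    def test_negation_gives_minus_one(self):
        t = np.arange(0, 8000, 1000.0)
        x = np.linspace(0, 1, len(t)) ** 2
        table = build_trend_table({"a": pd.Series(x, index=t),
                                   "b": pd.Series(-x, index=t)})
        corr = pairwise_correlations(table)
        assert corr.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_five_point_toy_matches_naive_covariance(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        t = np.arange(5) * 1000.0
        table = build_trend_table({"x": pd.Series(x, index=t),
                                   "y": pd.Series(y, index=t)})
        corr = pairwise_correlations(table)
        # naive covariance-formula oracle
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert corr.r.loc["x", "y"] == pytest.approx(r, abs=1e-12)

    def test_pairwise_complete_exclusion_and_undefined_cells(self):
        t = np.arange(0, 6000, 1000.0)
        a = pd.Series([1.0, 2, 3, 4, 5, 6], index=t)
        b = pd.Series([2.0, np.nan, 6, np.nan, 10, 12], index=t)
        c = pd.Series([np.nan] * 4 + [1.0, 2.0], index=t)
        corr = pairwise_correlations(build_trend_table({"a": a, "b": b, "c": c}))
        assert corr.n.loc["a", "b"] == 4
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)
        assert corr.n.loc["a", "c"] == 2
        assert math.isnan(corr.r.loc["a", "c"])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 20_000, 1000.0)
        x = pd.Series(rng.normal(size=t.size), index=t)
        y = pd.Series(rng.normal(size=t.size), index=t)
        base = pairwise_correlations(build_trend_table({"x": x, "y": y}))
        scaled = pairwise_correlations(
            build_trend_table({"x": 3.0 * x + 7.0, "y": -2.0 * y + 1.0}))
        assert scaled.r.loc["x", "y"] == pytest.approx(-base.r.loc["x", "y"])

    def test_synchrony_recovery_from_shared_forcing(self):
        # two taxa driven by the same sigmoid forcing correlate strongly;
        # independent random walks do not
        t = np.arange(1000.0, 30_001.0, 1000.0)
        forcing = 1 / (1 + np.exp((t - 10_000) / 1500))
        rng = np.random.default_rng(1)
        a = 0.01 * (1 + 5 * forcing) + rng.normal(0, 2e-4, t.size)
        b = 0.02 * (1 + 8 * forcing) + rng.normal(0, 4e-4, t.size)
        corr = pairwise_correlations(build_trend_table(
            {"a": pd.Series(a, index=t), "b": pd.Series(b, index=t)}))
        assert corr.r.loc["a", "b"] > 0.8

        pvals = []
        for rep in range(60):
            w1 = pd.Series(np.cumsum(rng.normal(size=t.size)), index=t)
            w2 = pd.Series(np.cumsum(rng.normal(size=t.size)), index=t)
            c = pairwise_correlations(build_trend_table({"x": w1, "y": w2}))
            pvals.append(c.p.loc["x", "y"])
        # random walks are not synchronized by construction; the p-value
        # spread must cover the unit interval rather than pile up near 0
        assert np.median(pvals) > 0.02

    def test_grid_robustness_on_smooth_trajectories(self):
        t_fine = np.arange(1000.0, 30_001.0, 500.0)
        f = 1 / (1 + np.exp((t_fine - 12_000) / 2000))
        a_vals = 1 + 4 * f
        b_vals = 2 + 3 * f ** 1.2
        rs = []
        for step in (1000.0, 2000.0, 5000.0):
            a = interpolate_to_grid(t_fine, a_vals, step)
            b = interpolate_to_grid(t_fine, b_vals, step)
            corr = pairwise_correlations(build_trend_table({"a": a, "b": b}))
            rs.append(corr.r.loc["a", "b"])
        assert max(rs) - min(rs) < 0.1


class TestDeltaTheta:
    def _series(self, vals, times=None):
        times = times if times is not None else np.arange(0, 31_000, 1000.0)
        return pd.Series(vals, index=times[:len(vals)])

    def test_fold_change_example(self):
        t = np.array([1000.0, 21_000.0])
        s = pd.Series([7.5, 1.0], index=t)
        assert delta_theta(s) == pytest.approx(7.5)

    def test_flat_series_is_one(self):
        s = self._series(np.ones(31))
        assert delta_theta(s) == pytest.approx(1.0)

    def test_halving(self):
        t = np.array([1000.0, 21_000.0])
        assert delta_theta(pd.Series([0.5, 1.0], index=t)) == pytest.approx(0.5)

    def test_zero_reference_undefined(self):
        t = np.array([1000.0, 21_000.0])
        assert math.isnan(delta_theta(pd.Series([1.0, 0.0], index=t)))

    def test_outside_support_undefined(self):
        t = np.array([5000.0, 15_000.0])
        assert math.isnan(delta_theta(pd.Series([1.0, 2.0], index=t)))


class TestGroupSummary:
    def test_range_endpoints(self):
        vals = {"a": 1.3, "b": 34.0, "c": 9.0}
        out = group_summary(vals, {"a": "g", "b": "g", "c": "g"})
        row = out.iloc[0]
        assert row["min"] == 1.3 and row["max"] == 34.0
        assert row["mean"] == pytest.approx(np.mean([1.3, 34.0, 9.0]))

    def test_single_species_group(self):
        out = group_summary({"a": 2.5}, {"a": "solo"})
        assert out.iloc[0]["mean"] == 2.5

    def test_geometric_mean(self):
        assert geometric_mean([2.0, 8.0]) == pytest.approx(4.0)
        with pytest.raises(ValueError, match="positive"):
            geometric_mean([2.0, -1.0])


def brute_force_mwu_p(a, b):
    """Exhaustive-labeling oracle written independently: U from direct
    pair counting, p from enumeration of all C(n, na) group assignments."""
    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
        return min(u, len(x) * len(y) - u)

    pooled = list(a) + list(b)
    na = len(a)
    obs = u_stat(a, b)
    hits = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(ga, gb) <= obs + 1e-12:
            hits += 1
    return obs, hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        # only the 2 most extreme labelings of C(6,3)=20 reach U = 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_maximal_u(self):
        U, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert U == pytest.approx(16 / 2)

    def test_matches_exhaustive_enumeration_with_crossing(self):
        a = [1.0, 2.0, 3.0, 4.0, 10.0]
        b = [5.0, 6.0, 7.0, 8.0, 9.0]
        U, p = mann_whitney_u(a, b)
        U_ref, p_ref = brute_force_mwu_p(a, b)
        assert U == pytest.approx(U_ref)
        assert p == pytest.approx(p_ref)

    def test_exhaustive_enumeration_with_ties(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 4.0, 6.0]
        U, p = mann_whitney_u(a, b)
        U_ref, p_ref = brute_force_mwu_p(a, b)
        assert U == pytest.approx(U_ref)
        assert p == pytest.approx(p_ref)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 30)
        U, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        assert p == pytest.approx(ref.pvalue)
        assert U == min(ref.statistic, 900 - ref.statistic)

    def test_u_of_three_at_five_vs_five(self):
        # U = 3 at group sizes 5 vs 5: the exact two-sided tail is
        # 14/252 (~0.056); the one-sided tail 7/252 clears 5%
        a = [1.3, 5.0, 7.0, 9.0, 34.0]
        b = [0.3, 0.9, 1.2, 2.0, 6.0]
        U, p = mann_whitney_u(a, b)
        assert U == 3.0
        assert p == pytest.approx(14 / 252)
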