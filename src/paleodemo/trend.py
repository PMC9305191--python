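"""Cross-taxon synchrony statistics: gridded trend tables, pairwise
Pearson correlations, fold changes in diversity (delta-theta), group
summaries and the Mann-Whitney rank test.

Correlations use pairwise-complete observations (intervals with missing
data are excluded per pair); p-values are raw, with no multiple-testing
correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ALLOWED_STEPS = (1000.0, 2000.0, 5000.0)


def trajectory_support(trajectory: pd.DataFrame,
                       value_column: str = "m_p") -> tuple[np.ndarray, np.ndarray]:
    """Support points (bin midpoints in years, values) of a calibrated table."""
    t = 0.5 * (trajectory["year_start"].to_numpy() + trajectory["year_stop"].to_numpy())
    v = trajectory[value_column].to_numpy(dtype=float)
    ok = ~np.isnan(v)
    return t[ok], v[ok]


def interpolate_to_grid(times, values, step_years: float = 1000.0,
                        t_min: float | None = None,
                        t_max: float | None = None) -> pd.Series:
    """Linear interpolation of a trajectory onto a fixed year grid.

    Grid points outside the trajectory's support are NaN (no
    extrapolation). Returns a Series indexed by age in years.
    """
    if step_years not in ALLOWED_STEPS:
        raise ValueError(f"step_years must be one of {ALLOWED_STEPS}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 support points")
    order = np.argsort(times)
    times, values = times[order], values[order]
    lo = times[0] if t_min is None else t_min
    hi = times[-1] if t_max is None else t_max
    grid = np.arange(math.ceil(lo / step_years) * step_years,
                     hi + 0.5 * step_years, step_years)
    out = np.interp(grid, times, values)
    out[(grid < times[0]) | (grid > times[-1])] = np.nan
    return pd.Series(out, index=grid, name="value")


def build_trend_table(series: dict[str, pd.Series]) -> pd.DataFrame:
    """Assemble gridded taxa (and temperature) series into one table.

    All series must share the same uniform grid step; the union of grid
    points becomes the index and absent points are missing.
    """
    df = pd.DataFrame(series)
    steps = np.unique(np.diff(df.index.to_numpy()))
    if steps.size > 1 and not np.allclose(steps, steps[0]):
        raise ValueError("trend table grid is not uniform")
    return df


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pairwise_correlations(table: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with t-distribution p-values.

    Cells with fewer than ``min_n`` jointly non-missing grid points are
    flagged undefined (NaN r and p, with the joint n still reported).
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 1.0)
    for i in range(k):
        nmat[i, i] = int(table[cols[i]].notna().sum())
    for i, j in combinations(range(k), 2):
        x = table[cols[i]].to_numpy(dtype=float)
        y = table[cols[j]].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        nmat[i, j] = nmat[j, i] = int(ok.sum())
        if ok.sum() < min_n:
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        res = stats.pearsonr(x[ok], y[ok])
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
    )


def delta_theta(series: pd.Series, t_ref: float = 21_000.0,
                t_recent: float = 1_000.0) -> float:
    """Fold change theta(t_recent) / theta(t_ref), linearly interpolated.

    NaN if either endpoint lies outside the series support or the
    reference value is zero.
    """
    times = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    times, vals = times[ok], vals[ok]
    if times.size < 2:
        return math.nan
    order = np.argsort(times)
    times, vals = times[order], vals[order]
    if not (times[0] <= t_recent <= times[-1] and times[0] <= t_ref <= times[-1]):
        return math.nan
    v_recent = float(np.interp(t_recent, times, vals))
    v_ref = float(np.interp(t_ref, times, vals))
    if v_ref == 0:
        return math.nan
    return v_recent / v_ref


def group_summary(values: dict[str, float], grouping: dict[str, str]) -> pd.DataFrame:
    """Arithmetic mean and min-max range of per-species values per group."""
    rows = []
    groups = sorted(set(grouping.values()))
    for g in groups:
        vals = [values[s] for s, gg in grouping.items() if gg == g and s in values]
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            raise ValueError(f"group {g!r} has no usable values")
        rows.append({"group": g, "n": len(vals), "mean": float(np.mean(vals)),
                     "min": float(np.min(vals)), "max": float(np.max(vals))})
    return pd.DataFrame(rows)


def geometric_mean(values) -> float:
    """Geometric mean of point estimates; requires strictly positive input."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if (x <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(stats.gmean(x))


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Returns (U, p) with U = min(U_a, U_b). The two-sided p-value is exact
    (enumeration over all labelings) when n_a + n_b <= 12, otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")

    def u_min(x_idx_mask: np.ndarray, ranks: np.ndarray, n1: int, n2: int) -> float:
        r1 = float(ranks[x_idx_mask].sum())
        u1 = r1 - n1 * (n1 + 1) / 2.0
        return min(u1, n1 * n2 - u1)

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mask = np.zeros(na + nb, dtype=bool)
    mask[:na] = True
    U = u_min(mask, ranks, na, nb)

    if na + nb <= 12:
        count = 0
        total = 0
        for combo in combinations(range(na + nb), na):
            m = np.zeros(na + nb, dtype=bool)
            m[list(combo)] = True
            total += 1
            if u_min(m, ranks, na, nb) <= U + 1e-12:
                count += 1
        p = count / total
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return float(U), float(min(p, 1.0))
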