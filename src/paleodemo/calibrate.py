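"""Pooling of replicate MCMC estimates and conversion of mutation-scaled
quantities to calendar years and effective population sizes.

Pooled per-bin point estimates weight each replicate's median by its
MCMC datapoint count:

    m_p  = sum_i n_i m_i / sum_i n_i
    SD_p = sqrt( sum_i (n_i - 1) SD_i^2 / (sum_i n_i - k) )
    CI   = m_p +/- 1.96 SD_p / sqrt(sum_i n_i)   (divisor configurable)

Effective size: Ne = theta / (4 mu) with mu per site per generation.
Calendar time: mutation-scaled ages divide by the per-year rate
(mitochondrial: per-generation rate / generation time).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

REPLICATE_COLUMNS = ("bin_start", "bin_stop", "median", "sd", "n")


@dataclass
class SpeciesCalibration:
    """Mutation rate and generation time for one species/marker."""

    marker_class: str
    generation_time_years: float
    mu_per_site_per_generation: float | None = None
    mu_per_site_per_year: float | None = None

    def __post_init__(self) -> None:
        if self.generation_time_years <= 0:
            raise ValueError("generation time must be positive")
        if self.marker_class == "nuclear":
            if self.mu_per_site_per_year is None or self.mu_per_site_per_year <= 0:
                raise ValueError("nuclear calibration needs a positive per-year rate")
            if self.mu_per_site_per_generation is None:
                self.mu_per_site_per_generation = (
                    self.mu_per_site_per_year * self.generation_time_years)
        else:
            if (self.mu_per_site_per_generation is None
                    or self.mu_per_site_per_generation <= 0):
                raise ValueError("mtDNA calibration needs a positive per-generation rate")
            if self.mu_per_site_per_year is None:
                self.mu_per_site_per_year = (
                    self.mu_per_site_per_generation / self.generation_time_years)


def _validate_replicate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"replicate table missing columns {missing}")
    if (df["n"] < 0).any() or (df["sd"].dropna() < 0).any():
        raise ValueError("counts and SDs must be >= 0")
    return df.reset_index(drop=True)


def pool_replicates(replicates: list[pd.DataFrame], ci_z: float = 1.96,
                    ci_denominator: str = "sqrt_total_n") -> pd.DataFrame:
    """Pool k replicate skyline estimates per time bin.

    Each replicate is a table with columns (bin_start, bin_stop, median,
    sd, n) on an identical bin grid. Bins with zero total datapoints are
    emitted with NaN estimates. ``ci_denominator`` selects the divisor of
    the CI half-width: ``sqrt_total_n`` (standard error of the weighted
    mean, the default) or ``total_n``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to pool")
    reps = [_validate_replicate(r) for r in replicates]
    base = reps[0][["bin_start", "bin_stop"]]
    for r in reps[1:]:
        if len(r) != len(base) or not np.allclose(
                r[["bin_start", "bin_stop"]].to_numpy(), base.to_numpy()):
            raise ValueError("replicate bin grids do not match")
    k = len(reps)
    n = np.stack([r["n"].to_numpy(dtype=float) for r in reps])
    m = np.stack([r["median"].to_numpy(dtype=float) for r in reps])
    sd = np.stack([r["sd"].to_numpy(dtype=float) for r in reps])
    n_total = n.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        mw = np.where(n > 0, m, 0.0)
        m_p = np.where(n_total > 0, (n * mw).sum(axis=0) / n_total, np.nan)
        sdw = np.where(n > 0, sd, 0.0)
        denom = n_total - k
        var_p = np.where(denom > 0,
                         ((n - 1).clip(min=0) * sdw**2).sum(axis=0) / denom,
                         np.nan)
        sd_p = np.sqrt(var_p)
        zero_dp = n_total == 0
        sd_p = np.where(zero_dp, np.nan, sd_p)
        if ci_denominator == "sqrt_total_n":
            half = ci_z * sd_p / np.sqrt(n_total)
        elif ci_denominator == "total_n":
            half = ci_z * sd_p / n_total
        else:
            raise ValueError("ci_denominator must be 'sqrt_total_n' or 'total_n'")
    out = base.copy()
    out["m_p"] = m_p
    out["sd_p"] = sd_p
    out["ci_lo"] = m_p - half
    out["ci_hi"] = m_p + half
    out["n_total"] = n_total.astype(int)
    return out


def theta_to_Ne(theta, calib: SpeciesCalibration):
    """Ne = theta / (4 mu), mu per site per generation."""
    theta = np.asarray(theta, dtype=float)
    if (theta <= 0).any():
        raise ValueError("theta must be > 0")
    out = theta / (4.0 * calib.mu_per_site_per_generation)
    return float(out) if out.ndim == 0 else out


def scale_time_to_years(t_mutational, calib: SpeciesCalibration):
    """Convert mutation-scaled ages (expected substitutions/site) to years.

    mtDNA: years = (t / mu_per_generation) * generation_time;
    nuclear: years = t / mu_per_year. Both reduce to t / mu_per_year.
    """
    t = np.asarray(t_mutational, dtype=float)
    if (t < 0).any():
        raise ValueError("ages must be >= 0")
    out = t / calib.mu_per_site_per_year
    return float(out) if out.ndim == 0 else out


def calibrate_trajectory(pooled: pd.DataFrame, calib: SpeciesCalibration) -> pd.DataFrame:
    """Attach calendar-year bin edges and Ne columns to a pooled table."""
    out = pooled.copy()
    out["year_start"] = scale_time_to_years(out["bin_start"].to_numpy(), calib)
    out["year_stop"] = scale_time_to_years(out["bin_stop"].to_numpy(), calib)
    with np.errstate(invalid="ignore"):
        out["Ne"] = out["m_p"] / (4.0 * calib.mu_per_site_per_generation)
    return out


def restrict_window(trajectory: pd.DataFrame, min_kya: float = 1.0,
                    max_kya: float = 30.0) -> pd.DataFrame:
    """Clip a calibrated trajectory to the analysis window (default 1-30 kya).

    Bins wholly outside the window are dropped; partially overlapping
    bins are clipped to the window edges.
    """
    lo, hi = min_kya * 1000.0, max_kya * 1000.0
    if "year_start" not in trajectory.columns:
        raise ValueError("trajectory must be calibrated (year_start/year_stop)")
    keep = (trajectory["year_stop"] > lo) & (trajectory["year_start"] < hi)
    out = trajectory[keep].copy()
    if out.empty:
        raise ValueError(f"no bins inside the {min_kya}-{max_kya} kya window")
    out["year_start"] = out["year_start"].clip(lower=lo)
    out["year_stop"] = out["year_stop"].clip(upper=hi)
    return out.reset_index(drop=True)
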