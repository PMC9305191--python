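"""Folded site-frequency-spectrum computation and piecewise-constant
demographic fitting (stairway-style composite likelihood).

The expected folded SFS under a piecewise-constant single-deme history
is computed analytically: expected time with k ancestral lineages in
each epoch comes from the lineage-count distribution of the coalescent
(a pure-death chain, evaluated through the rate-rescaled timescale),
and the probability that a branch with k ancestors subtends i of the n
sampled chromosomes is the classical combinatorial weight
C(n-i-1, k-2) / C(n-1, k-1). Folding adds complementary classes with
half weight at i = n/2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .scenario import DemographicScenario

_MAX_N = 200


@dataclass
class FoldedSFS:
    """Minor-allele-class counts eta_1..eta_{floor(n/2)} over L_total sites."""

    n_chrom: int
    eta: np.ndarray
    L_total: int

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.n_chrom < 4:
            raise ValueError("n_chrom must be >= 4")
        if self.eta.shape != (self.n_chrom // 2,):
            raise ValueError(f"eta must have floor(n/2) = {self.n_chrom // 2} entries")
        if (self.eta < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total_segregating(self) -> float:
        return float(self.eta.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "minor_allele_count": np.arange(1, self.eta.size + 1),
            "n_sites": self.eta,
        })

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_chrom={self.n_chrom}\n# L_total={self.L_total}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FoldedSFS":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = int(val)
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(n_chrom=meta["n_chrom"], eta=df["n_sites"].to_numpy(float),
                   L_total=meta["L_total"])


def folded_sfs_from_genotypes(genotypes: np.ndarray,
                              min_call_fraction: float = 0.80) -> FoldedSFS:
    """Tally the folded SFS from hard diploid genotype calls.

    ``genotypes`` is (n_sites, n_individuals) with codes {0, 1, 2} and a
    negative value (or NaN) for missing calls. Sites called in fewer
    than ``min_call_fraction`` of individuals are dropped entirely;
    monomorphic sites count toward L_total but not toward eta.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (sites x individuals)")
    n_ind = G.shape[1]
    n_chrom = 2 * n_ind
    if n_chrom < 4:
        raise ValueError("need at least 2 diploid individuals (n_chrom >= 4)")
    missing = np.isnan(G) | (G < 0)
    valid = np.isin(G[~missing], (0.0, 1.0, 2.0)).all()
    if not valid:
        raise ValueError("genotype codes must be 0, 1, 2 or missing")
    called = (~missing).sum(axis=1)
    keep = called / n_ind >= min_call_fraction
    Gk = np.where(missing, 0.0, G)[keep]
    calledk = called[keep]
    alt = Gk.sum(axis=1)
    minor = np.minimum(alt, 2 * calledk - alt).astype(int)
    eta = np.zeros(n_chrom // 2, dtype=float)
    poly = minor > 0
    np.add.at(eta, minor[poly] - 1, 1.0)
    return FoldedSFS(n_chrom=n_chrom, eta=eta, L_total=int(keep.sum()))


def genotypes_from_012(path) -> np.ndarray:
    """Read a sites x individuals 012 matrix TSV (-1 or blank = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# expected folded SFS under a piecewise-constant history
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _death_chain_coefficients(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed coefficients rho[j, k] of the ancestral lineage-count law.

    P(A(s) = k | A(0) = n) = sum_{j=k}^n rho[j, k] * exp(-j(j-1) s) on the
    rescaled timescale where the k -> k-1 rate is k(k-1).
    """
    rho = np.zeros((n + 1, n + 1))
    lg = math.lgamma
    for k in range(1, n + 1):
        for j in range(k, n + 1):
            logmag = (math.log(2 * j - 1)
                      + lg(k + j - 1) - lg(k)          # rising factorial k_(j-1)
                      + lg(n + 1) - lg(n - j + 1)      # falling factorial n_[j]
                      - lg(k + 1) - lg(j - k + 1)      # k! (j-k)!
                      - (lg(n + j) - lg(n)))           # rising factorial n_(j)
            rho[j, k] = (-1.0) ** (j - k) * math.exp(logmag)
    jj = np.arange(n + 1)
    rates = jj * (jj - 1)
    return rho, rates.astype(float)


def expected_time_with_k(scenario: DemographicScenario, n: int) -> np.ndarray:
    """E[time spent with k = 2..n ancestral lineages], mutation-scaled.

    Returns an array indexed k = 0..n (entries below 2 are zero). The
    per-epoch contribution integrates the lineage-count law over the
    epoch, mapped through the theta-rescaled clock.
    """
    if scenario.D != 1:
        raise ValueError("expected SFS is defined for single-deme scenarios")
    if n > _MAX_N:
        raise ValueError(
            f"n_chrom = {n} > {_MAX_N}: the alternating-series lineage-count law "
            "is numerically unstable; project the SFS down to fewer chromosomes")
    rho, rates = _death_chain_coefficients(n)
    grid = scenario.grid
    thetas = scenario.theta[0]
    E = grid.size
    # rescaled-time epoch boundaries
    lam = np.zeros(E + 1)
    for e in range(E):
        width = (grid[e + 1] - grid[e]) if e + 1 < E else np.inf
        lam[e + 1] = lam[e] + width / thetas[e]
    out = np.zeros(n + 1)
    for k in range(2, n + 1):
        total = 0.0
        for e in range(E):
            l0, l1 = lam[e], lam[e + 1]
            js = np.arange(k, n + 1)
            r = rates[js]
            upper = np.exp(-r * l1) if np.isfinite(l1) else 0.0
            integ = (np.exp(-r * l0) - upper) / r
            total += thetas[e] * float(np.dot(rho[js, k], integ))
        out[k] = max(total, 0.0)
    return out


@lru_cache(maxsize=None)
def _subtend_weights(n: int) -> np.ndarray:
    """W[k, i] = k * P(a branch among k ancestors subtends i of n tips)."""
    lg = math.lgamma

    def logC(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return lg(a + 1) - lg(b + 1) - lg(a - b + 1)

    W = np.zeros((n + 1, n))
    for k in range(2, n + 1):
        for i in range(1, n - k + 2):
            lp = logC(n - i - 1, k - 2) - logC(n - 1, k - 1)
            if lp > -math.inf:
                W[k, i] = k * math.exp(lp)
    return W


def expected_unfolded_sfs(scenario: DemographicScenario, n_chrom: int) -> np.ndarray:
    """Expected per-site counts xi_1..xi_{n-1} under the scenario."""
    Tk = expected_time_with_k(scenario, n_chrom)
    W = _subtend_weights(n_chrom)
    xi = np.zeros(n_chrom - 1)
    for i in range(1, n_chrom):
        xi[i - 1] = float(np.dot(W[2:, i], Tk[2:]))
    return xi


def fold_sfs(xi: np.ndarray) -> np.ndarray:
    """eta_i = xi_i + xi_{n-i}, with half weight (single term) at i = n/2."""
    n = xi.size + 1
    half = n // 2
    eta = np.empty(half)
    for i in range(1, half + 1):
        if i == n - i:
            eta[i - 1] = xi[i - 1]
        else:
            eta[i - 1] = xi[i - 1] + xi[n - i - 1]
    return eta


def expected_folded_sfs(scenario: DemographicScenario, n_chrom: int) -> np.ndarray:
    """Expected per-site folded SFS eta_1..eta_{floor(n/2)}."""
    return fold_sfs(expected_unfolded_sfs(scenario, n_chrom))


# ---------------------------------------------------------------------------
# stairway-style piecewise-constant fit
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseNeFit:
    boundaries: np.ndarray          # epoch start times, mutation-scaled
    theta: np.ndarray               # per-epoch theta (per site)
    log_likelihood: float
    converged: bool
    trajectory: pd.DataFrame | None = None   # year_start, theta, Ne

    def scenario(self) -> DemographicScenario:
        return DemographicScenario.piecewise(self.boundaries, self.theta[None, :])


def _watterson_from_sfs(sfs: FoldedSFS) -> float:
    n = sfs.n_chrom
    a1 = sum(1.0 / i for i in range(1, n))
    return sfs.total_segregating / (a1 * sfs.L_total)


def epoch_boundaries(theta0: float, n_epochs: int) -> np.ndarray:
    """Epoch starts at pairwise-coalescence quantiles of the constant model.

    Under constant theta0 a pair coalesces at rate 2/theta0; boundaries
    are placed at the e/n_epochs quantiles of that exponential so each
    epoch carries comparable coalescent signal.
    """
    qs = np.arange(1, n_epochs) / n_epochs
    return np.concatenate([[0.0], -0.5 * theta0 * np.log1p(-qs)])


def _poisson_composite_ll(log_theta: np.ndarray, boundaries: np.ndarray,
                          sfs: FoldedSFS) -> float:
    theta = np.exp(log_theta)
    scen = DemographicScenario.piecewise(boundaries, theta[None, :])
    lam = expected_folded_sfs(scen, sfs.n_chrom) * sfs.L_total
    lam = np.maximum(lam, 1e-300)
    return float(np.sum(sfs.eta * np.log(lam) - lam))


def fit_stairway(sfs: FoldedSFS, n_epochs: int = 3,
                 mu_per_site_year: float = 1.07e-9,
                 generation_years: float = 25.0,
                 seed: int | None = 0, n_starts: int = 4) -> PiecewiseNeFit:
    """Maximize the Poisson composite likelihood of the folded SFS.

    Epochs are fitted sequentially (1, 2, ..., n_epochs), warm-starting
    each richer model from the previous solution so the maximized
    likelihood is non-decreasing in the number of epochs. Additional
    seeded random restarts guard against local optima. The returned
    trajectory converts epoch boundaries to years via the annual
    mutation rate and theta to Ne via Ne = theta / (4 mu_generational).
    """
    if sfs.total_segregating < 10:
        raise ValueError("need at least 10 segregating sites to fit")
    rng = np.random.default_rng(seed)
    theta0 = _watterson_from_sfs(sfs)
    lo, hi = math.log(theta0) - 8.0, math.log(theta0) + 8.0

    prev = np.array([math.log(theta0)])
    best_x, best_ll, best_bounds, ok = prev, -np.inf, np.array([0.0]), False
    for k in range(1, n_epochs + 1):
        bounds_k = epoch_boundaries(theta0, k)
        starts = []
        if k == 1:
            starts.append(np.array([math.log(theta0)]))
        else:
            # warm start: previous optimum evaluated at the new epoch midpoints
            prev_scen_bounds = epoch_boundaries(theta0, k - 1)
            mids = np.append(bounds_k[1:], bounds_k[-1] * 2 + theta0)
            idx = np.searchsorted(prev_scen_bounds, mids, side="right") - 1
            starts.append(prev[idx])
        for _ in range(n_starts - 1):
            starts.append(starts[0] + rng.normal(0.0, 0.7, size=k))
        best_k, best_k_ll, k_ok = None, -np.inf, False
        for x0 in starts:
            res = minimize(
                lambda x: -_poisson_composite_ll(x, bounds_k, sfs),
                np.clip(x0, lo, hi), method="L-BFGS-B",
                bounds=[(lo, hi)] * k)
            if -res.fun > best_k_ll:
                best_k, best_k_ll, k_ok = res.x, -res.fun, bool(res.success)
        prev = best_k
        if k == n_epochs:
            best_x, best_ll, best_bounds, ok = best_k, best_k_ll, bounds_k, k_ok

    theta = np.exp(best_x)
    mu_gen = mu_per_site_year * generation_years
    years = best_bounds / mu_per_site_year
    traj = pd.DataFrame({
        "year_start": years,
        "theta": theta,
        "Ne": theta / (4.0 * mu_gen),
    })
    return PiecewiseNeFit(boundaries=best_bounds, theta=theta,
                          log_likelihood=best_ll, converged=ok, trajectory=traj)


class StairwayEstimator:
    """Piecewise-constant Ne estimator from a folded SFS (sklearn-style).

    Parameters mirror :func:`fit_stairway`; after :meth:`fit` the fitted
    attributes ``theta_``, ``boundaries_``, ``log_likelihood_``,
    ``converged_`` and ``trajectory_`` are available.
    """

    def __init__(self, n_epochs: int = 3, mu_per_site_per_year: float = 1.07e-9,
                 generation_time_years: float = 25.0, n_starts: int = 4,
                 random_state: int = 0):
        self.n_epochs = n_epochs
        self.mu_per_site_per_year = mu_per_site_per_year
        self.generation_time_years = generation_time_years
        self.n_starts = n_starts
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_epochs", "mu_per_site_per_year", "generation_time_years",
            "n_starts", "random_state")}

    def set_params(self, **params) -> "StairwayEstimator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: FoldedSFS, y=None) -> "StairwayEstimator":
        fit = fit_stairway(
            X, n_epochs=self.n_epochs,
            mu_per_site_year=self.mu_per_site_per_year,
            generation_years=self.generation_time_years,
            seed=self.random_state, n_starts=self.n_starts)
        self.fit_ = fit
        self.theta_ = fit.theta
        self.boundaries_ = fit.boundaries
        self.log_likelihood_ = fit.log_likelihood
        self.converged_ = fit.converged
        self.trajectory_ = fit.trajectory
        return self

    def predict(self, times) -> np.ndarray:
        """theta at the given mutation-scaled times under the fitted model."""
        if not hasattr(self, "theta_"):
            raise RuntimeError("estimator is not fitted")
        idx = np.searchsorted(self.boundaries_, np.asarray(times, float),
                              side="right") - 1
        return self.theta_[idx]
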