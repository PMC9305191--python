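"""Bayesian MCMC estimation of temporal diversity (theta per deme) and
immigration (M per direction) from a single-locus alignment.

Model: structured coalescent over 1 or 2 demes with piecewise-constant
theta and M (mutation-scaled time), uniform priors, HKY/JC sequence
likelihood via Felsenstein pruning, Metropolis-coupled MCMC with three
move families — parameter updates, node-time slides constrained by the
migration paths, and a lineage detach/re-attach move whose migration
path is re-simulated from the structured-coalescent conditional given
the current parameters (so its Hastings ratio reduces to the sequence
likelihood ratio).

The skyline output assigns, for each recorded state, each genealogy
inter-event interval's implied parameter draws to the time bins the
interval overlaps; per-bin medians, SDs and draw counts mirror the
replicate-pooling contract downstream.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .diversity import watterson_theta
from .genealogy import Genealogy
from .scenario import DemographicScenario
from .simulate import simulate_genealogy
from .substitution import HKYModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def coalescent_log_density(gen: Genealogy, scenario: DemographicScenario) -> float:
    """Structured-coalescent log density of a genealogy with migration paths.

    Sums -dt * sum_d [k_d (k_d - 1)/theta_d + k_d * (total emigration rate)]
    over inter-event intervals (split at epoch boundaries, parameters
    looked up at interval midpoints) plus the log rate of each realized
    coalescence (2/theta_d) and migration (M_{s<-d}) event. Returns -inf
    for deme-inconsistent genealogies.
    """
    D = scenario.D
    n = gen.n_tips
    events: list[tuple[float, int, tuple]] = []
    for v in range(n, gen.n_nodes):
        events.append((float(gen.time[v]), 0, (int(gen.node_deme[v]), v)))
    for (t, v, a, b) in gen.migration_events():
        events.append((float(t), 1, (a, b)))
    events.sort(key=lambda e: (e[0], e[1]))

    k = np.zeros(D, dtype=int)
    for d in gen.node_deme[:n]:
        k[d] += 1

    grid = scenario.grid
    logp = 0.0
    t_prev = 0.0
    for (t, kind, data) in events:
        # accumulate waiting-time exponent, splitting at epoch boundaries
        seg_start = t_prev
        while seg_start < t:
            e = int(np.searchsorted(grid, seg_start, side="right") - 1)
            seg_end = min(t, grid[e + 1] if e + 1 < grid.size else np.inf)
            mid_e = int(np.searchsorted(grid, (seg_start + seg_end) / 2.0,
                                        side="right") - 1)
            theta_e = scenario.theta[:, mid_e]
            out_rate = scenario.mig[:, :, mid_e].sum(axis=0)
            lam = float(np.sum(k * (k - 1) / theta_e) + np.sum(k * out_rate))
            logp -= lam * (seg_end - seg_start)
            seg_start = seg_end
        e = int(np.searchsorted(grid, t, side="right") - 1)
        if kind == 0:
            d, _v = data
            if k[d] < 2:
                return -math.inf
            logp += math.log(2.0 / scenario.theta[d, e])
            k[d] -= 1
        else:
            a, b = data
            if k[a] < 1:
                return -math.inf
            rate = scenario.mig[b, a, e]
            if rate <= 0:
                return -math.inf
            logp += math.log(rate)
            k[a] -= 1
            k[b] += 1
        t_prev = t
    return logp


class _PatternData:
    """Site-pattern-compressed alignment for pruning."""

    def __init__(self, aln: SequenceAlignment):
        if (aln.seqs >= 4).any():
            raise ValueError("likelihood requires a gap/missing-free alignment")
        patterns, counts = np.unique(aln.seqs.T, axis=0, return_counts=True)
        self.patterns = patterns.T        # (n, n_patterns)
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        n = aln.n
        self.tip_partials = np.zeros((n, self.n_patterns, 4))
        for i in range(n):
            self.tip_partials[i, np.arange(self.n_patterns), self.patterns[i]] = 1.0


def sequence_log_likelihood(aln: SequenceAlignment, gen: Genealogy,
                            subst_model: HKYModel | None = None,
                            _patterns: _PatternData | None = None) -> float:
    """Felsenstein pruning over compressed site patterns (log space).

    Alignment row i is tip i of the genealogy; branch lengths are in
    expected substitutions per site.
    """
    model = subst_model or HKYModel()
    pat = _patterns or _PatternData(aln)
    n = gen.n_tips
    if aln.n != n:
        raise ValueError("alignment size does not match genealogy tips")
    kids = gen.children_map()
    bl = np.array([gen.branch_length(v) for v in range(gen.n_nodes)])
    P = model.transition_matrices(bl)

    partials = np.empty((gen.n_nodes, pat.n_patterns, 4))
    partials[:n] = pat.tip_partials
    logscale = np.zeros(pat.n_patterns)

    # postorder
    order: list[int] = []
    stack = [gen.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(kids[v])
    for v in reversed(order):
        if v < n:
            continue
        a, b = kids[v]
        pa = partials[a] @ P[a].T
        pb = partials[b] @ P[b].T
        res = pa * pb
        m = res.max(axis=1)
        if (m <= 0).any():
            return -math.inf
        partials[v] = res / m[:, None]
        logscale += np.log(m)

    site_l = partials[gen.root] @ model.stationary
    return float(np.dot(pat.counts, np.log(site_l) + logscale))


# ---------------------------------------------------------------------------
# configuration and outputs
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """Desk-scale defaults; ``paper_scale_config`` holds the full-size preset."""

    steps: int = 200_000
    burn_in: int = 100_000
    thin: int = 50
    heat_temperatures: tuple = (1.0,)
    theta_bounds: tuple[float, float] = (1e-4, 1e-1)
    m_bounds: tuple[float, float] = (0.0, 200.0)
    epoch_boundaries: tuple = (0.0,)
    n_time_bins: int = 30
    time_horizon: float | None = None
    seed: int = 0
    ess_threshold: float = 200.0
    sample_prior_only: bool = False
    kappa: float = 2.0
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    swap_interval: int = 10

    def __post_init__(self) -> None:
        if not self.burn_in < self.steps:
            raise ValueError("burn_in must be < steps")
        temps = tuple(self.heat_temperatures)
        if temps[0] != 1.0 or any(b < a for a, b in zip(temps, temps[1:])):
            raise ValueError("heat temperatures must start at 1.0 and be non-decreasing")
        if self.theta_bounds[0] <= 0 or self.theta_bounds[1] <= self.theta_bounds[0]:
            raise ValueError("theta prior must have positive width and lower bound > 0")
        if self.m_bounds[1] <= self.m_bounds[0] or self.m_bounds[0] < 0:
            raise ValueError("M prior must have non-negative bounds of positive width")
        if tuple(self.epoch_boundaries)[0] != 0.0:
            raise ValueError("epoch boundaries must start at 0")


def paper_scale_config(**overrides) -> McmcConfig:
    """The full-scale MCMC preset (16M steps, half burn-in, thin 200,
    four statically heated chains, ESS floor 10,000)."""
    kw = dict(steps=16_000_000, burn_in=8_000_000, thin=200,
              heat_temperatures=(1.0, 1.5, 3.0, 1_000_000.0),
              ess_threshold=10_000.0)
    kw.update(overrides)
    return McmcConfig(**kw)


@dataclass
class SkylineTrajectory:
    """Per-time-bin summaries: median, SD, draw count per parameter."""

    table: pd.DataFrame              # bin_start, bin_stop, parameter, median, sd, n
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return sorted(self.table["parameter"].unique())

    def for_parameter(self, name: str) -> pd.DataFrame:
        return self.table[self.table["parameter"] == name].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class McmcResult:
    trace: pd.DataFrame
    skyline: SkylineTrajectory
    acceptance: dict[str, float]
    ess: dict[str, float]
    config: McmcConfig


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def effective_sample_size(trace) -> float:
    """Initial-positive-sequence autocorrelation ESS (Geyer 1992)."""
    x = np.asarray(trace, dtype=float)
    N = x.size
    if N < 10:
        raise ValueError("trace too short for an ESS estimate")
    v = x.var()
    if v == 0:
        warnings.warn("constant trace: ESS reported as trace length")
        return float(N)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * N)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:N].real / N
    rho = acov / acov[0]
    # sum of adjacent-pair autocorrelations while positive
    s = 0.0
    t = 1
    while t + 1 < N:
        g = rho[t] + rho[t + 1]
        if g <= 0:
            break
        s += g
        t += 2
    ess = N / (1.0 + 2.0 * s)
    return float(max(1.0, min(ess, N)))


def suggest_prior_bounds(aln: SequenceAlignment,
                         factor: float = 10.0) -> tuple[tuple[float, float], tuple[float, float]]:
    """Watterson/F_ST-based uniform prior bounds (0.1x .. 10x heuristics).

    Mirrors the practice of setting prior ranges from quick preliminary
    estimates: theta bounds bracket Watterson's estimate; M bounds
    bracket the equilibrium-island-model rate implied by Hudson's F_ST
    (single-deme alignments get a default M range).
    """
    theta_w = watterson_theta(aln)
    theta_w = max(theta_w, 1e-6)
    theta_bounds = (theta_w / factor, theta_w * factor)
    demes = np.unique(aln.demes)
    if demes.size < 2:
        return theta_bounds, (0.0, 100.0)
    from .diversity import mean_pairwise_differences
    within = []
    for d in demes:
        rows = np.flatnonzero(aln.demes == d)
        if rows.size >= 2:
            within.append(mean_pairwise_differences(aln.take(rows)))
    s1 = aln.seqs[aln.demes == demes[0]]
    s2 = aln.seqs[aln.demes == demes[1]]
    between = float((s1[:, None, :] != s2[None, :, :]).sum(axis=2).mean())
    pi_w, pi_b = float(np.mean(within)), between
    fst = max(1e-3, min(1.0 - pi_w / pi_b if pi_b > 0 else 0.5, 0.999))
    m_hat = max(0.5 * (1.0 / fst - 1.0), 0.1)
    return theta_bounds, (0.0, m_hat * factor)


def _relabel_tips_to_alignment(gen: Genealogy, demes0: np.ndarray) -> Genealogy:
    """Permute tip indices so tip i carries the deme of alignment row i."""
    n = gen.n_tips
    pools: dict[int, list[int]] = {}
    for tip in range(n):
        pools.setdefault(int(gen.node_deme[tip]), []).append(tip)
    perm = np.arange(gen.n_nodes)
    for i, d in enumerate(demes0):
        perm[pools[int(d)].pop()] = i
    # perm maps old node id -> new node id (identity on internals)
    parent = np.full(gen.n_nodes, -1, dtype=int)
    time = gen.time.copy()
    node_deme = gen.node_deme.copy()
    events: dict[int, list] = {v: [] for v in range(gen.n_nodes)}
    for v in range(gen.n_nodes):
        nv = int(perm[v])
        parent[nv] = int(perm[gen.parent[v]]) if gen.parent[v] >= 0 else -1
        time[nv] = gen.time[v]
        node_deme[nv] = gen.node_deme[v]
        events[nv] = list(gen.edge_events[v])
    return Genealogy(gen.n_tips, parent, time, node_deme, events)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Chain:
    def __init__(self, gen: Genealogy, scen: DemographicScenario, temp: float):
        self.gen = gen
        self.scen = scen
        self.temp = temp
        self.coal_ld = 0.0
        self.seq_ll = 0.0
        self.stats = None   # cached coalescent sufficient statistics


class _Mcmc:
    def __init__(self, aln: SequenceAlignment, config: McmcConfig):
        self.aln = aln
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        labels = np.unique(aln.demes)
        self.D = labels.size
        self.demes0 = np.searchsorted(labels, aln.demes)   # 0-based
        self.model = HKYModel(kappa=config.kappa, freqs=config.base_freqs)
        self.patterns = None if config.sample_prior_only else _PatternData(aln)
        self.bounds = np.asarray(config.epoch_boundaries, dtype=float)
        self.E = self.bounds.size
        self.accept: dict[str, list[int]] = {
            k: [0, 0] for k in ("param", "gibbs", "time", "regraft", "scale",
                                "swap")}

    # -- state initialisation ------------------------------------------
    def _initial_chain(self, temp: float) -> _Chain:
        cfg = self.cfg
        lo, hi = cfg.theta_bounds
        try:
            th0 = float(np.clip(watterson_theta(self.aln), lo, hi))
        except ValueError:
            th0 = math.sqrt(lo * hi)
        theta = np.full((self.D, self.E), th0)
        mig = np.zeros((self.D, self.D, self.E))
        if self.D > 1:
            m0 = max(min(10.0, cfg.m_bounds[1] * 0.5), cfg.m_bounds[0] + 1e-6)
            for e in range(self.E):
                mig[:, :, e] = m0 * (1 - np.eye(self.D))
        scen = DemographicScenario.piecewise(self.bounds, theta, mig)
        n_per = np.bincount(self.demes0, minlength=self.D)
        gen = simulate_genealogy(scen, n_per, self.rng)
        gen = _relabel_tips_to_alignment(gen, self.demes0)
        ch = _Chain(gen, scen, temp)
        ch.stats = self._sufficient_stats(gen)
        ch.coal_ld = self._coal_ld_from_stats(scen, ch.stats)
        ch.seq_ll = self._seq_ll(gen)
        return ch

    def _coal_ld_from_stats(self, scen: DemographicScenario, stats) -> float:
        """Structured-coalescent log density from sufficient statistics.

        Equals coalescent_log_density(gen, scen) whenever ``stats`` was
        computed from the same genealogy; O(D^2 E) instead of O(events).
        """
        C, W, n_coal, n_mig = stats
        theta = scen.theta
        mig = scen.mig
        ld = float(np.sum(n_coal * np.log(2.0 / theta)) - np.sum(C / theta))
        out_rate = mig.sum(axis=0)                       # (D, E)
        ld -= float(np.sum(W * out_rate))
        active = n_mig > 0
        if active.any():
            if (mig[active] <= 0).any():
                return -math.inf
            ld += float(np.sum(n_mig[active] * np.log(mig[active])))
        return ld

    def _seq_ll(self, gen: Genealogy) -> float:
        if self.cfg.sample_prior_only:
            return 0.0
        return sequence_log_likelihood(self.aln, gen, self.model, self.patterns)

    # -- parameter bookkeeping -------------------------------------------
    def _param_entries(self) -> list[tuple]:
        out = []
        for d in range(self.D):
            for e in range(self.E):
                out.append(("theta", d, e))
        for s in range(self.D):
            for d in range(self.D):
                if s != d:
                    for e in range(self.E):
                        out.append(("mig", s, d, e))
        return out

    @staticmethod
    def param_label(entry: tuple) -> str:
        if entry[0] == "theta":
            return f"theta_{entry[1] + 1}_e{entry[2]}"
        return f"M_{entry[1] + 1}->{entry[2] + 1}_e{entry[3]}"

    # -- moves -----------------------------------------------------------
    def _move_param(self, ch: _Chain) -> bool:
        cfg, rng = self.cfg, self.rng
        entries = self._param_entries()
        entry = entries[int(rng.integers(len(entries)))]
        scen = ch.scen
        if entry[0] == "theta":
            _, d, e = entry
            x = scen.theta[d, e]
            lo, hi = cfg.theta_bounds
        else:
            _, s, d, e = entry
            x = scen.mig[s, d, e]
            lo, hi = cfg.m_bounds
        u = rng.random()
        if u < 1.0 / 3.0:
            mult = math.exp(1.4 * (rng.random() - 0.5))
            x_new = x * mult
            log_hastings = math.log(mult)
        elif u < 2.0 / 3.0:
            w = 0.25 * (hi - lo)
            x_new = x + w * (rng.random() - 0.5)
            # reflect at bounds
            if x_new < lo:
                x_new = 2 * lo - x_new
            if x_new > hi:
                x_new = 2 * hi - x_new
            log_hastings = 0.0
        else:
            # independence draw from the uniform prior
            x_new = lo + rng.random() * (hi - lo)
            log_hastings = 0.0
        if entry[0] == "theta":
            if not (lo < x_new < hi):
                return False
        elif not (lo <= x_new < hi):
            return False
        theta = scen.theta.copy()
        mig = scen.mig.copy()
        if entry[0] == "theta":
            theta[entry[1], entry[2]] = x_new
        else:
            mig[entry[1], entry[2], entry[3]] = x_new
        new_scen = DemographicScenario.piecewise(self.bounds, theta, mig)
        new_ld = self._coal_ld_from_stats(new_scen, ch.stats)
        if math.isinf(new_ld) and new_ld < 0:
            return False
        log_alpha = (new_ld - ch.coal_ld) + log_hastings
        if math.log(rng.random() + 1e-300) < log_alpha:
            ch.scen = new_scen
            ch.coal_ld = new_ld
            return True
        return False

    def _time_window(self, gen: Genealogy, v: int) -> tuple[float, float]:
        kids = gen.children(v)
        lower = 0.0
        for c in kids:
            lo_c = gen.time[c]
            if gen.edge_events[c]:
                lo_c = max(lo_c, gen.edge_events[c][-1][0])
            lower = max(lower, float(lo_c))
        p = gen.parent[v]
        if p < 0:
            upper = math.inf
        else:
            upper = float(gen.time[p])
            if gen.edge_events[v]:
                upper = min(upper, gen.edge_events[v][0][0])
        return lower, upper

    def _move_time(self, ch: _Chain) -> bool:
        rng = self.rng
        gen = ch.gen
        n = gen.n_tips
        v = int(rng.integers(n, gen.n_nodes))
        lower, upper = self._time_window(gen, v)
        t_old = float(gen.time[v])
        log_hastings = 0.0
        if math.isinf(upper):
            d = int(gen.node_deme[v])
            # rate depends only on the (fixed) window edge so the
            # exponential proposal stays reversible across epochs
            rate = 2.0 / ch.scen.theta_at(d, lower)
            t_new = lower + rng.exponential(1.0 / rate)
            log_hastings = rate * (t_new - t_old)
        else:
            t_new = lower + rng.random() * (upper - lower)
        gen.time[v] = t_new
        new_stats = self._sufficient_stats(gen)
        new_ld = self._coal_ld_from_stats(ch.scen, new_stats)
        new_ll = self._seq_ll(gen)
        log_alpha = (new_ld - ch.coal_ld) + (new_ll - ch.seq_ll) / ch.temp + log_hastings
        if math.log(rng.random() + 1e-300) < log_alpha:
            ch.coal_ld = new_ld
            ch.seq_ll = new_ll
            ch.stats = new_stats
            return True
        gen.time[v] = t_old
        return False

    def _sufficient_stats(self, gen: Genealogy):
        """Per-deme, per-epoch coalescent sufficient statistics.

        Returns (C, W, n_coal, n_mig): C[d, e] = integral of k_d(k_d-1) dt,
        W[d, e] = integral of k_d dt, n_coal[d, e] = coalescences in deme d,
        n_mig[s, d, e] = migration events of a deme-d lineage to deme s.
        """
        D, E = self.D, self.E
        grid = self.bounds
        C = np.zeros((D, E))
        W = np.zeros((D, E))
        n_coal = np.zeros((D, E), dtype=int)
        n_mig = np.zeros((D, D, E), dtype=int)
        events: list[tuple[float, int, tuple]] = []
        n = gen.n_tips
        for v in range(n, gen.n_nodes):
            events.append((float(gen.time[v]), 0, (int(gen.node_deme[v]),)))
        for (t, _v, a, b) in gen.migration_events():
            events.append((float(t), 1, (a, b)))
        events.sort(key=lambda e: (e[0], e[1]))
        k = np.zeros(D, dtype=int)
        for d in gen.node_deme[:n]:
            k[d] += 1
        t_prev = 0.0
        for (t, kind, data) in events:
            seg = t_prev
            while seg < t:
                e = int(np.searchsorted(grid, seg, side="right") - 1)
                seg_end = min(t, grid[e + 1] if e + 1 < grid.size else math.inf)
                dt = seg_end - seg
                C[:, e] += k * (k - 1) * dt
                W[:, e] += k * dt
                seg = seg_end
            e = int(np.searchsorted(grid, t, side="right") - 1)
            if kind == 0:
                d = data[0]
                n_coal[d, e] += 1
                k[d] -= 1
            else:
                a, b = data
                n_mig[b, a, e] += 1
                k[a] -= 1
                k[b] += 1
            t_prev = t
        return C, W, n_coal, n_mig

    @staticmethod
    def _truncated_gamma(rng, shape: float, rate: float, lo: float,
                         hi: float) -> float | None:
        """One draw from Gamma(shape, rate) truncated to [lo, hi]."""
        from scipy.stats import gamma as gamma_dist
        if shape <= 0 or rate <= 0:
            return None
        dist = gamma_dist(shape, scale=1.0 / rate)
        c_lo, c_hi = dist.cdf(lo), dist.cdf(hi)
        if not (np.isfinite(c_lo) and np.isfinite(c_hi)) or c_hi - c_lo < 1e-12:
            return None
        x = float(dist.ppf(c_lo + rng.random() * (c_hi - c_lo)))
        if not (lo <= x <= hi) or not math.isfinite(x):
            return None
        return x

    def _move_gibbs(self, ch: _Chain) -> bool:
        """Exact conditional update of one theta or M entry.

        Given the genealogy, M_{s->d} | rest ~ Gamma(n_events + 1, W_d)
        and 1/theta_d | rest ~ Gamma(n_coal - 1, C_d/...) — both truncated
        to the uniform prior bounds. The sequence likelihood does not
        depend on the parameters, so these conditionals are exact in both
        prior-only and full runs.
        """
        rng = self.rng
        entries = self._param_entries()
        entry = entries[int(rng.integers(len(entries)))]
        C, W, n_coal, n_mig = ch.stats
        theta = ch.scen.theta.copy()
        mig = ch.scen.mig.copy()
        if entry[0] == "theta":
            _, d, e = entry
            nc = int(n_coal[d, e])
            if nc < 2 or C[d, e] <= 0:
                return self._move_param(ch)
            lo, hi = self.cfg.theta_bounds
            # y = 1/theta ~ Gamma(nc - 1, rate = C) on [1/hi, 1/lo]
            y = self._truncated_gamma(rng, nc - 1.0, C[d, e], 1.0 / hi, 1.0 / lo)
            if y is None:
                return False
            theta[d, e] = 1.0 / y
        else:
            _, s, d, e = entry
            lo, hi = self.cfg.m_bounds
            if W[d, e] <= 0:
                x = lo + rng.random() * (hi - lo)   # conditional is the prior
            else:
                x = self._truncated_gamma(rng, n_mig[s, d, e] + 1.0, W[d, e],
                                          max(lo, 1e-300), hi)
                if x is None:
                    return False
            mig[s, d, e] = x
        new_scen = DemographicScenario.piecewise(self.bounds, theta, mig)
        new_ld = self._coal_ld_from_stats(new_scen, ch.stats)
        if math.isinf(new_ld):
            return False
        ch.scen = new_scen
        ch.coal_ld = new_ld
        return True

    def _move_scale(self, ch: _Chain) -> bool:
        """Jointly rescale all theta and every node/migration time.

        Breaks the strong posterior coupling between theta and total tree
        length; the Hastings term is c^k for the k rescaled variables.
        """
        rng = self.rng
        c = math.exp(0.7 * (rng.random() - 0.5))
        lo, hi = self.cfg.theta_bounds
        theta_new = ch.scen.theta * c
        if (theta_new <= lo).any() or (theta_new >= hi).any():
            return False
        gen = ch.gen
        n = gen.n_tips
        old_times = gen.time.copy()
        old_events = {v: list(evs) for v, evs in gen.edge_events.items()}
        n_mig = sum(len(evs) for evs in old_events.values())
        gen.time[n:] = gen.time[n:] * c
        for v in gen.edge_events:
            gen.edge_events[v] = [(t * c, a, b) for (t, a, b) in gen.edge_events[v]]
        new_scen = DemographicScenario.piecewise(self.bounds, theta_new,
                                                 ch.scen.mig)
        new_stats = self._sufficient_stats(gen)
        new_ld = self._coal_ld_from_stats(new_scen, new_stats)
        new_ll = self._seq_ll(gen)
        k = (n - 1) + n_mig + theta_new.size
        log_alpha = ((new_ld - ch.coal_ld) + (new_ll - ch.seq_ll) / ch.temp
                     + k * math.log(c))
        if math.log(rng.random() + 1e-300) < log_alpha:
            ch.scen = new_scen
            ch.coal_ld = new_ld
            ch.seq_ll = new_ll
            ch.stats = new_stats
            return True
        gen.time[:] = old_times
        gen.edge_events = old_events
        return False

    # regraft: detach a lineage and re-simulate its migration/coalescence
    # path conditional on the rest under the current parameters.
    def _move_regraft(self, ch: _Chain) -> bool:
        rng = self.rng
        gen = ch.gen
        scen = ch.scen
        n = gen.n_tips
        root = gen.root
        c = int(rng.integers(gen.n_nodes - 1))
        if c >= root:
            c += 1
        p = int(gen.parent[c])
        kids_p = gen.children(p)
        sib = kids_p[0] if kids_p[1] == c else kids_p[1]
        gp = int(gen.parent[p])

        # subtree(c) exclusion set
        excl = {c, p}
        stack = [c]
        while stack:
            w = stack.pop()
            for ck in gen.children(w):
                excl.add(ck)
                stack.append(ck)

        # forest: parent of sib becomes gp, sib edge inherits p's edge events
        f_parent = {v: int(gen.parent[v]) for v in range(gen.n_nodes)}
        f_events = {v: list(gen.edge_events[v]) for v in range(gen.n_nodes)}
        f_parent[sib] = gp
        f_events[sib] = (list(gen.edge_events[sib]) + list(gen.edge_events[p])
                         if gp >= 0 else [])
        froot = sib if gp < 0 else root
        if froot == p:   # cannot happen: p removed
            raise AssertionError
        # The conditional-path factorization requires the detached lineage
        # to start at or below the forest root: above it, the forest-root
        # lineage's own continuation on [t_froot, t_c] would be part of the
        # conditional but is not re-simulated. That configuration (p is the
        # root and c is the higher child) is rejected symmetrically — the
        # forest, c and both times are shared by the reverse move.
        if float(gen.time[c]) > float(gen.time[froot]):
            return False
        # active forest edges: (node, t_low, t_high, event list); forest root
        # handled separately as the "continuation" lineage
        edges = []
        for v in range(gen.n_nodes):
            if v in excl or v == froot:
                continue
            q = f_parent[v]
            if q == p:
                raise AssertionError
            edges.append((v, float(gen.time[v]), float(gen.time[q]), f_events[v]))
        t_froot = float(gen.time[froot])

        def edge_deme(idx: int, t: float) -> int:
            v, t0, t1, evs = edges[idx]
            d = int(gen.node_deme[v])
            for (et, a, b) in evs:
                if et <= t:
                    d = b
                else:
                    break
            return d

        # breakpoints where forest composition or epochs change
        breaks = set()
        for (v, t0, t1, evs) in edges:
            breaks.add(t0)
            breaks.add(t1)
            for (et, _a, _b) in evs:
                breaks.add(et)
        breaks.add(t_froot)
        for b in scen.grid[1:]:
            breaks.add(float(b))
        t_c = float(gen.time[c])
        breaks = sorted(b for b in breaks if b > t_c)

        # re-simulate: detached lineage from (t_c, deme of c); the forest-root
        # lineage's continuation path above t_froot is co-simulated.
        d_det = int(gen.node_deme[c])
        d_cont = int(gen.node_deme[froot])
        cont_events: list[tuple[float, int, int]] = []
        new_events: list[tuple[float, int, int]] = []
        t = t_c
        coal_time = None
        coal_partner = None     # ("edge", idx) or ("cont",)
        bi = 0
        iterations = 0
        while coal_time is None:
            iterations += 1
            if iterations > 50_000:
                # pathological excursion (vanishing rates); reject proposal
                return False
            next_break = breaks[bi] if bi < len(breaks) else math.inf
            e = max(int(np.searchsorted(scen.grid, t, side="right") - 1), 0)
            epoch_end = scen.grid[e + 1] if e + 1 < scen.grid.size else math.inf
            seg_end = min(next_break, epoch_end)
            # active forest edges and their demes
            active = [i for i, (v, t0, t1, evs) in enumerate(edges) if t0 <= t < t1]
            cont_active = t >= t_froot
            mig_e = scen.mig[:, :, e]
            out_det = float(mig_e[:, d_det].sum())
            out_cont = float(mig_e[:, d_cont].sum()) if cont_active else 0.0
            colocated = [i for i in active if edge_deme(i, t) == d_det]
            n_coloc = len(colocated) + (1 if cont_active and d_cont == d_det else 0)
            coal_rate = 2.0 * n_coloc / scen.theta[d_det, e]
            total = out_det + out_cont + coal_rate
            if total <= 0:
                t = seg_end
                if math.isinf(t):
                    raise RuntimeError("absorbing state in regraft re-simulation")
            else:
                wait = rng.exponential(1.0 / total)
                if t + wait >= seg_end:
                    t = seg_end
                else:
                    t += wait
                    u = rng.random() * total
                    if u < coal_rate:
                        j = int(rng.integers(n_coloc))
                        if j < len(colocated):
                            coal_time, coal_partner = t, ("edge", colocated[j])
                        else:
                            coal_time, coal_partner = t, ("cont",)
                    elif u < coal_rate + out_det:
                        w = rng.random() * out_det
                        cum = 0.0
                        for s in range(self.D):
                            cum += mig_e[s, d_det]
                            if w < cum:
                                new_events.append((t, d_det, s))
                                d_det = s
                                break
                    else:
                        w = rng.random() * out_cont
                        cum = 0.0
                        for s in range(self.D):
                            cum += mig_e[s, d_cont]
                            if w < cum:
                                cont_events.append((t, d_cont, s))
                                d_cont = s
                                break
            while bi < len(breaks) and breaks[bi] <= t:
                bi += 1

        # --- build the proposed genealogy ---------------------------------
        new = gen.copy()
        new.parent[sib] = gp
        new.edge_events[sib] = f_events[sib]
        t_star = float(coal_time)
        new.time[p] = t_star
        new.node_deme[p] = d_det
        new.edge_events[c] = new_events
        new.parent[c] = p
        if coal_partner[0] == "cont":
            new.parent[froot] = p
            new.edge_events[froot] = cont_events
            new.parent[p] = -1
            new.edge_events[p] = []
        else:
            w, t0, t1, evs = edges[coal_partner[1]]
            q = f_parent[w]
            below = [ev for ev in evs if ev[0] < t_star]
            above = [ev for ev in evs if ev[0] >= t_star]
            new.parent[w] = p
            new.edge_events[w] = below
            new.parent[p] = q
            new.edge_events[p] = above

        new_ll = self._seq_ll(new)
        log_alpha = (new_ll - ch.seq_ll) / ch.temp
        if math.log(rng.random() + 1e-300) < log_alpha:
            ch.gen = new
            ch.seq_ll = new_ll
            ch.stats = self._sufficient_stats(new)
            ch.coal_ld = self._coal_ld_from_stats(ch.scen, ch.stats)
            return True
        return False

    # -- main loop --------------------------------------------------------
    def run(self) -> McmcResult:
        cfg = self.cfg
        rng = self.rng
        chains = [self._initial_chain(T) for T in cfg.heat_temperatures]
        entries = self._param_entries()
        labels = [self.param_label(e) for e in entries]

        records: list[dict] = []
        rec_states: list[tuple[np.ndarray, DemographicScenario, float]] = []
        move_p = np.array([0.15, 0.20, 0.30, 0.20, 0.15])
        if cfg.sample_prior_only:
            move_p = np.array([0.15, 0.35, 0.20, 0.15, 0.15])
        movers = [self._move_param, self._move_gibbs, self._move_time,
                  self._move_regraft, self._move_scale]
        names = ["param", "gibbs", "time", "regraft", "scale"]

        for step in range(cfg.steps):
            for ch in chains:
                mi = int(rng.choice(5, p=move_p))
                ok = movers[mi](ch)
                self.accept[names[mi]][0] += int(ok)
                self.accept[names[mi]][1] += 1
            if len(chains) > 1 and step % cfg.swap_interval == 0:
                i = int(rng.integers(len(chains) - 1))
                a, b = chains[i], chains[i + 1]
                log_alpha = (1.0 / a.temp - 1.0 / b.temp) * (b.seq_ll - a.seq_ll)
                ok = math.log(rng.random() + 1e-300) < log_alpha
                if ok:
                    a.gen, b.gen = b.gen, a.gen
                    a.scen, b.scen = b.scen, a.scen
                    a.coal_ld, b.coal_ld = b.coal_ld, a.coal_ld
                    a.seq_ll, b.seq_ll = b.seq_ll, a.seq_ll
                    a.stats, b.stats = b.stats, a.stats
                self.accept["swap"][0] += int(ok)
                self.accept["swap"][1] += 1
            if step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thin == 0:
                cold = chains[0]
                rec = {"step": step, "coal_log_density": cold.coal_ld,
                       "seq_log_likelihood": cold.seq_ll,
                       "tmrca": cold.gen.tmrca}
                for entry, lab in zip(entries, labels):
                    if entry[0] == "theta":
                        rec[lab] = cold.scen.theta[entry[1], entry[2]]
                    else:
                        rec[lab] = cold.scen.mig[entry[1], entry[2], entry[3]]
                records.append(rec)
                ev_times = np.sort(np.concatenate([
                    cold.gen.time[cold.gen.n_tips:],
                    np.array([t for (t, _v, _a, _b) in cold.gen.migration_events()],
                             dtype=float)]))
                rec_states.append((ev_times, cold.scen, cold.gen.tmrca))

        trace = pd.DataFrame(records)
        ess: dict[str, float] = {}
        for lab in labels:
            x = trace[lab].to_numpy()
            ess[lab] = effective_sample_size(x) if x.size >= 10 else float(x.size)
            if ess[lab] < cfg.ess_threshold:
                logger.warning("ESS of %s = %.0f below threshold %.0f",
                               lab, ess[lab], cfg.ess_threshold)
        for name, (acc, tot) in self.accept.items():
            if tot > 0 and acc == 0 and name != "swap":
                warnings.warn(f"zero acceptance for move class {name!r}")

        skyline = self._build_skyline(rec_states, ess)
        acc_rates = {k: (v[0] / v[1] if v[1] else math.nan)
                     for k, v in self.accept.items()}
        return McmcResult(trace=trace, skyline=skyline, acceptance=acc_rates,
                          ess=ess, config=cfg)

    def _build_skyline(self, rec_states, ess) -> SkylineTrajectory:
        cfg = self.cfg
        horizon = cfg.time_horizon
        if horizon is None:
            horizon = 0.5 * (cfg.theta_bounds[0] + cfg.theta_bounds[1])
        bins = np.linspace(0.0, horizon, cfg.n_time_bins + 1)
        par_labels = ([f"theta_{d + 1}" for d in range(self.D)]
                      + [f"M_{s + 1}->{d + 1}" for s in range(self.D)
                         for d in range(self.D) if s != d])
        draws: dict[tuple[str, int], list[float]] = {
            (lab, b): [] for lab in par_labels for b in range(cfg.n_time_bins)}
        for (ev_times, scen, tmrca) in rec_states:
            knots = np.concatenate([[0.0], ev_times])
            for i in range(knots.size - 1):
                a, b = float(knots[i]), float(knots[i + 1])
                if b <= a:
                    continue
                b0 = int(np.searchsorted(bins, a, side="right") - 1)
                b1 = int(np.searchsorted(bins, b, side="left") - 1)
                for bin_i in range(max(b0, 0), min(b1, cfg.n_time_bins - 1) + 1):
                    lo = max(a, bins[bin_i])
                    hi = min(b, bins[bin_i + 1])
                    if hi <= lo:
                        continue
                    e = scen.epoch_at((lo + hi) / 2.0)
                    for d in range(self.D):
                        draws[(f"theta_{d + 1}", bin_i)].append(scen.theta[d, e])
                    for s in range(self.D):
                        for d2 in range(self.D):
                            if s != d2:
                                draws[(f"M_{s + 1}->{d2 + 1}", bin_i)].append(
                                    scen.mig[s, d2, e])
        rows = []
        for lab in par_labels:
            for bin_i in range(cfg.n_time_bins):
                vals = np.asarray(draws[(lab, bin_i)])
                rows.append({
                    "bin_start": bins[bin_i], "bin_stop": bins[bin_i + 1],
                    "parameter": lab,
                    "median": float(np.median(vals)) if vals.size else math.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else
                          (0.0 if vals.size == 1 else math.nan),
                    "n": int(vals.size),
                })
        table = pd.DataFrame(rows)
        ess_by_param: dict[str, float] = {}
        for lab in par_labels:
            matching = [v for k, v in ess.items() if k.startswith(lab + "_e")]
            if matching:
                ess_by_param[lab] = float(min(matching))
        return SkylineTrajectory(table=table, ess=ess_by_param)


def run_mcmc(aln: SequenceAlignment, config: McmcConfig | None = None) -> McmcResult:
    """Run the structured-coalescent sampler on a filtered alignment."""
    cfg = config or McmcConfig()
    if cfg.steps < 1_000_000:
        logger.info("scaled-down MCMC preset: %d steps (full-scale preset "
                    "available via paper_scale_config)", cfg.steps)
    return _Mcmc(aln, cfg).run()


class SkylineSampler:
    """Structured-coalescent skyline sampler with an sklearn-style surface.

    Constructor arguments mirror :class:`McmcConfig`; :meth:`fit` runs the
    sampler on an alignment and exposes ``trace_``, ``skyline_``,
    ``ess_`` and ``acceptance_`` fitted attributes.
    """

    _FIELDS = ("steps", "burn_in", "thin", "heat_temperatures", "theta_bounds",
               "m_bounds", "epoch_boundaries", "n_time_bins", "time_horizon",
               "seed", "ess_threshold", "sample_prior_only", "kappa",
               "base_freqs", "swap_interval")

    def __init__(self, **kwargs):
        cfg = McmcConfig(**kwargs)
        for f in self._FIELDS:
            setattr(self, f, getattr(cfg, f))

    def get_params(self, deep: bool = True) -> dict:
        return {f: getattr(self, f) for f in self._FIELDS}

    def set_params(self, **params) -> "SkylineSampler":
        for k, v in params.items():
            if k not in self._FIELDS:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: SequenceAlignment, y=None) -> "SkylineSampler":
        result = run_mcmc(X, McmcConfig(**self.get_params()))
        self.result_ = result
        self.trace_ = result.trace
        self.skyline_ = result.skyline
        self.ess_ = result.ess
        self.acceptance_ = result.acceptance
        return self
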