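"""Generative models: structured-coalescent genealogies, finite-sites
alignments, folded-SFS draws and temperature-like forcing series.

The simulator is the exact generative counterpart of the estimator's
model: piecewise-constant theta per deme and immigration rates in the
backwards-in-time receiving convention, all on the mutation time scale
(expected substitutions per site). Conversion to calendar years happens
only at calibration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .genealogy import Genealogy
from .scenario import DemographicScenario
from .substitution import HKYModel, jc_model


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genealogy(scenario: DemographicScenario, n_per_deme,
                       seed=None) -> Genealogy:
    """Backwards-in-time structured-coalescent simulation.

    While k_d lineages are in deme d during epoch e, pairs in d coalesce
    at total rate k_d (k_d - 1) / theta[d, e] and each lineage in d
    migrates to deme s at rate mig[s, d, e]; epoch boundaries truncate
    the exponential waiting-time draws.
    """
    rng = _as_rng(seed)
    n_per_deme = np.atleast_1d(np.asarray(n_per_deme, dtype=int))
    D = scenario.D
    if n_per_deme.size != D:
        raise ValueError(f"n_per_deme must have {D} entries")
    n = int(n_per_deme.sum())
    if n < 2:
        raise ValueError("need at least 2 samples in total")

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    node_deme = np.zeros(n_nodes, dtype=int)
    edge_events: dict[int, list[tuple[float, int, int]]] = {v: [] for v in range(n_nodes)}

    # active lineage bookkeeping: node id -> current deme
    active: dict[int, int] = {}
    v = 0
    for d in range(D):
        for _ in range(n_per_deme[d]):
            node_deme[v] = d
            active[v] = d
            v += 1
    next_node = n
    t = 0.0
    epoch = 0
    grid = scenario.grid

    while len(active) > 1:
        k = np.zeros(D, dtype=int)
        for d in active.values():
            k[d] += 1
        theta_e = scenario.theta[:, epoch]
        mig_e = scenario.mig[:, :, epoch]           # mig_e[s, d]: d -> s backwards
        coal_rate = k * (k - 1) / theta_e
        out_rate = mig_e.sum(axis=0)                 # total emigration rate per lineage in d
        mig_rate = k * out_rate
        total = float(coal_rate.sum() + mig_rate.sum())

        boundary = grid[epoch + 1] if epoch + 1 < grid.size else np.inf
        if total <= 0.0:
            if np.isinf(boundary):
                raise RuntimeError(
                    "absorbing state: all coalescence and migration rates are zero "
                    f"with {len(active)} lineages remaining")
            t = boundary
            epoch += 1
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait >= boundary:
            t = boundary
            epoch += 1
            continue
        t += wait

        u = rng.random() * total
        acc = 0.0
        event_done = False
        for d in range(D):
            acc += coal_rate[d]
            if u < acc:
                members = [node for node, dd in active.items() if dd == d]
                i, j = rng.choice(len(members), size=2, replace=False)
                a, b = members[int(i)], members[int(j)]
                p = next_node
                next_node += 1
                parent[a] = p
                parent[b] = p
                time[p] = t
                node_deme[p] = d
                del active[a], active[b]
                active[p] = d
                event_done = True
                break
        if not event_done:
            for d in range(D):
                acc += mig_rate[d]
                if u < acc:
                    members = [node for node, dd in active.items() if dd == d]
                    node = members[int(rng.integers(len(members)))]
                    w = rng.random() * out_rate[d]
                    s = 0
                    cum = 0.0
                    for s_cand in range(D):
                        cum += mig_e[s_cand, d]
                        if w < cum:
                            s = s_cand
                            break
                    edge_events[node].append((t, d, s))
                    active[node] = s
                    break

    gen = Genealogy(n, parent, time, node_deme, edge_events)
    return gen


def mutate(genealogy: Genealogy, L: int, subst_model: HKYModel | None = None,
           seed=None) -> SequenceAlignment:
    """Evolve sequences down the genealogy under a finite-sites model.

    The root sequence is drawn from the stationary base frequencies and
    each branch applies the exact substitution-process transition
    probabilities for its length (in expected substitutions/site).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = _as_rng(seed)
    model = subst_model or jc_model()
    n = genealogy.n_tips
    kids = genealogy.children_map()
    states = np.empty((genealogy.n_nodes, L), dtype=np.uint8)
    root = genealogy.root
    pi = model.stationary
    states[root] = rng.choice(4, size=L, p=pi)
    # preorder traversal
    stack = [root]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(kids[v])
    for v in order:
        if v == root:
            continue
        P = model.transition_matrix(genealogy.branch_length(v))
        cum = np.cumsum(P, axis=1)
        u = rng.random(L)
        parent_states = states[genealogy.parent[v]]
        states[v] = (u[:, None] > cum[parent_states]).sum(axis=1)

    per_deme_counter: dict[int, int] = {}
    ids = []
    for tip in range(n):
        d = int(genealogy.node_deme[tip]) + 1
        per_deme_counter[d] = per_deme_counter.get(d, 0) + 1
        ids.append(f"d{d}_{per_deme_counter[d]:03d}")
    return SequenceAlignment(ids, genealogy.node_deme[:n] + 1, states[:n],
                             locus_name="simulated")


@dataclass
class SimResult:
    """One simulated dataset; regeneration from (scenario, seed) is bit-identical."""

    genealogy: Genealogy
    alignment: SequenceAlignment
    true_scenario: DemographicScenario
    seed: int


def simulate_dataset(scenario: DemographicScenario, n_per_deme, L: int,
                     seed: int, subst_model: HKYModel | None = None) -> SimResult:
    rng = np.random.default_rng(seed)
    gen = simulate_genealogy(scenario, n_per_deme, rng)
    aln = mutate(gen, L, subst_model, rng)
    return SimResult(gen, aln, scenario, seed)


def simulate_folded_sfs(scenario: DemographicScenario, n_chrom: int,
                        L_sites: int, seed=None):
    """Poisson draws of folded minor-allele-class counts.

    Site counts are Poisson around L_sites times the expected per-site
    folded SFS of the (single-deme) scenario.
    """
    from .sfs import FoldedSFS, expected_folded_sfs

    if n_chrom < 4:
        raise ValueError("n_chrom must be >= 4")
    if scenario.D != 1:
        raise ValueError("folded-SFS simulation is single-deme")
    rng = _as_rng(seed)
    expected = expected_folded_sfs(scenario, n_chrom)   # per site
    eta = rng.poisson(expected * L_sites)
    return FoldedSFS(n_chrom=n_chrom, eta=eta, L_total=int(L_sites))


def simulate_temperature(ages, amplitude: float = 15.0, midpoint_age: float = 9500.0,
                         width: float = 800.0, level_modern: float = 0.0,
                         noise_sd: float = 0.0, noise_phi: float = 0.6,
                         cold_spike_age: float | None = None,
                         cold_spike_amplitude: float = 2.0,
                         cold_spike_width: float = 200.0,
                         seed=None) -> pd.DataFrame:
    """Sigmoidal deglacial warming ramp with optional AR(1) noise.

    Emulates a surface-air-temperature reconstruction: cold glacial
    plateau, a warming transition of ``amplitude`` degrees centred at
    ``midpoint_age`` years before present, and optionally a brief cold
    spike (an 8.2-kya-like event) of given amplitude and Gaussian width.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("age grid must be strictly ascending")
    rng = _as_rng(seed)
    ramp = 1.0 / (1.0 + np.exp((ages - midpoint_age) / width))
    values = level_modern - amplitude * (1.0 - ramp)
    if cold_spike_age is not None:
        values -= cold_spike_amplitude * np.exp(
            -0.5 * ((ages - cold_spike_age) / cold_spike_width) ** 2)
    if noise_sd > 0:
        eps = np.empty(ages.size)
        innov_sd = noise_sd * np.sqrt(1.0 - noise_phi**2)
        eps[0] = rng.normal(0.0, noise_sd)
        for i in range(1, ages.size):
            eps[i] = noise_phi * eps[i - 1] + rng.normal(0.0, innov_sd)
        values = values + eps
    return pd.DataFrame({"age_years": ages, "value": values})
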