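"""Timed, rooted, binary genealogies with per-branch deme paths.

Node indexing: tips 0..n-1 (time 0), internal nodes n..2n-2. The deme
path of the branch above node ``v`` starts in ``node_deme[v]`` at
``time[v]`` and is modified by the migration events stored (backwards in
time, ascending) in ``edge_events[v]`` as (time, from_deme, to_deme)
tuples. Demes are 0-based internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Genealogy:
    n_tips: int
    parent: np.ndarray           # (2n-1,), -1 at root
    time: np.ndarray             # (2n-1,), tips at 0
    node_deme: np.ndarray        # deme of the node at its own time
    edge_events: dict[int, list[tuple[float, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.node_deme = np.asarray(self.node_deme, dtype=int)
        for v in range(self.n_nodes):
            self.edge_events.setdefault(v, [])

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self, v: int) -> list[int]:
        return [int(c) for c in np.flatnonzero(self.parent == v)]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {v: [] for v in range(self.n_nodes)}
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                out[int(p)].append(v)
        return out

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return float(self.time[p] - self.time[v]) if p >= 0 else 0.0

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def total_branch_length(self) -> float:
        p = self.parent
        v = np.arange(self.n_nodes)[p >= 0]
        return float(np.sum(self.time[p[v]] - self.time[v]))

    # -- deme paths --------------------------------------------------------
    def deme_at(self, v: int, t: float) -> int:
        """Deme of the lineage above node v at time t (time[v] <= t < parent time)."""
        d = int(self.node_deme[v])
        for (et, a, b) in self.edge_events[v]:
            if et <= t:
                d = b
            else:
                break
        return d

    def migration_events(self) -> list[tuple[float, int, int, int]]:
        """All migration events as (time, lineage_node, from_deme, to_deme)."""
        out = []
        for v, evs in self.edge_events.items():
            for (t, a, b) in evs:
                out.append((t, v, a, b))
        out.sort()
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        root = self.root
        if self.edge_events.get(root):
            raise ValueError("root has no branch; it cannot carry migration events")
        kids = self.children_map()
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                if self.time[p] <= self.time[v]:
                    raise ValueError(f"parent {p} not older than child {v}")
                evs = self.edge_events[v]
                times = [t for t, _, _ in evs]
                if times != sorted(times):
                    raise ValueError(f"edge events on {v} not time-ordered")
                d = int(self.node_deme[v])
                for (t, a, b) in evs:
                    if not (self.time[v] < t < self.time[p]):
                        raise ValueError(f"event on edge {v} outside branch interval")
                    if a != d:
                        raise ValueError(f"event on edge {v} departs from deme {a}, lineage in {d}")
                    d = b
        for v in range(self.n_tips, self.n_nodes):
            cs = kids[v]
            if len(cs) != 2:
                raise ValueError(f"internal node {v} has {len(cs)} children")
            demes = {self.deme_at(c, np.nextafter(self.time[v], 0)) for c in cs}
            if demes != {int(self.node_deme[v])}:
                raise ValueError(f"children of node {v} not co-located at coalescence")

    # -- serialization -----------------------------------------------------
    def newick(self, precision: int = 10) -> str:
        kids = self.children_map()

        def fmt(v: int) -> str:
            bl = f"{self.branch_length(v):.{precision}g}"
            if v < self.n_tips:
                return f"t{v}:{bl}"
            a, b = kids[v]
            inner = f"({fmt(a)},{fmt(b)})"
            return inner if self.parent[v] < 0 else f"{inner}:{bl}"

        return fmt(self.root) + ";"

    def copy(self) -> "Genealogy":
        return Genealogy(
            self.n_tips, self.parent.copy(), self.time.copy(), self.node_deme.copy(),
            {v: list(evs) for v, evs in self.edge_events.items()})
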