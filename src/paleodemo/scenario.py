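"""Piecewise-constant demographic scenarios for 1 or 2 demes.

Time is mutation-scaled (expected substitutions per site) and runs
backwards from the present (t = 0). Within epoch e, deme d has
mutation-scaled diversity theta[d, e] (> 0) and ``mig[s, d, e]`` is the
scaled immigration rate M_{s->d} into deme d from deme s (receiving
convention): backwards in time a lineage currently in d jumps to s at
rate mig[s, d, e].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROWTH_PROFILES = ("constant", "exponential", "bottleneck", "piecewise")


@dataclass
class DemographicScenario:
    grid: np.ndarray            # epoch start times, ascending, grid[0] == 0
    theta: np.ndarray           # (D, E)
    mig: np.ndarray | None = None   # (D, D, E), zero diagonal
    growth: str = "piecewise"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 1 or self.grid[0] != 0.0:
            raise ValueError("epoch grid must be 1-D and start at 0")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("epoch grid must be strictly ascending")
        D, E = self.theta.shape
        if E != self.grid.size:
            raise ValueError("theta must have one column per epoch")
        if (self.theta <= 0).any():
            raise ValueError("all theta must be > 0")
        if self.mig is None:
            self.mig = np.zeros((D, D, E))
        self.mig = np.asarray(self.mig, dtype=float)
        if self.mig.shape != (D, D, E):
            raise ValueError(f"mig must have shape {(D, D, E)}")
        if (self.mig < 0).any():
            raise ValueError("migration rates must be >= 0")
        if np.any(np.abs(self.mig[np.arange(D), np.arange(D), :]) > 0):
            raise ValueError("mig diagonal must be zero")
        if self.growth not in GROWTH_PROFILES:
            raise ValueError(f"growth must be one of {GROWTH_PROFILES}")

    @property
    def D(self) -> int:
        return self.theta.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.grid.size

    def epoch_at(self, t: float) -> int:
        return int(np.searchsorted(self.grid, t, side="right") - 1)

    def theta_at(self, deme: int, t: float) -> float:
        return float(self.theta[deme, self.epoch_at(t)])

    # -- constructors --------------------------------------------------
    @classmethod
    def constant(cls, theta, mig: float | np.ndarray = 0.0) -> "DemographicScenario":
        """Constant-size scenario; scalar theta for one deme, vector for more.

        Scalar ``mig`` puts the same symmetric immigration rate on all
        off-diagonal entries.
        """
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        D = th.size
        M = np.zeros((D, D, 1))
        if np.isscalar(mig) or np.asarray(mig).ndim == 0:
            M[:, :, 0] = float(mig) * (1 - np.eye(D))
        else:
            M[:, :, 0] = np.asarray(mig, dtype=float)
            M[np.arange(D), np.arange(D), 0] = 0.0
        return cls(np.array([0.0]), th[:, None], M, growth="constant")

    @classmethod
    def exponential_growth(cls, theta_present, theta_ancient, t_span: float,
                           n_steps: int = 20, mig: float = 0.0) -> "DemographicScenario":
        """Exponential change discretized into ``n_steps`` log-linear epochs.

        theta declines (or rises) geometrically from theta_present at
        t = 0 to theta_ancient at t >= t_span.
        """
        tp = np.atleast_1d(np.asarray(theta_present, dtype=float))
        ta = np.atleast_1d(np.asarray(theta_ancient, dtype=float))
        D = tp.size
        grid = np.linspace(0.0, t_span, n_steps + 1)[:-1]
        grid = np.append(grid, t_span)
        mids = np.append(grid[1:] - np.diff(grid) / 2.0, t_span)
        frac = np.clip(mids / t_span, 0, 1)
        theta = np.exp(np.log(tp)[:, None] * (1 - frac)[None, :]
                       + np.log(ta)[:, None] * frac[None, :])
        E = grid.size
        M = np.zeros((D, D, E))
        for e in range(E):
            M[:, :, e] = mig * (1 - np.eye(D))
        out = cls(grid, theta, M, growth="exponential")
        return out

    @classmethod
    def bottleneck(cls, theta_present: float, theta_bottleneck: float,
                   theta_ancient: float, t_start: float, t_end: float,
                   ) -> "DemographicScenario":
        """Single-deme bottleneck between mutation-scaled times t_start..t_end."""
        if not 0 < t_start < t_end:
            raise ValueError("need 0 < t_start < t_end")
        grid = np.array([0.0, t_start, t_end])
        theta = np.array([[theta_present, theta_bottleneck, theta_ancient]])
        return cls(grid, theta, growth="bottleneck")

    @classmethod
    def piecewise(cls, grid, theta, mig=None) -> "DemographicScenario":
        return cls(np.asarray(grid, float), np.asarray(theta, float), mig,
                   growth="piecewise")
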