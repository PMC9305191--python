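"""Nucleotide substitution models (HKY family; JC as the default).

Rate matrices are normalized to one expected substitution per site per
unit branch length, so branch lengths are in expected substitutions/site.
Transition probabilities come from the symmetrized eigendecomposition,
which is exact and stable for reversible models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# base order matches paleodemo.alignment codes: A, C, G, T
_PURINE = np.array([True, False, True, False])


@dataclass
class HKYModel:
    kappa: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.freqs, dtype=float)
        if pi.shape != (4,) or (pi <= 0).any():
            raise ValueError("freqs must be 4 positive values")
        pi = pi / pi.sum()
        self.freqs = tuple(pi)
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = _PURINE[i] == _PURINE[j]
                Q[i, j] = (self.kappa if transition else 1.0) * pi[j]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(4)] = -Q.sum(axis=1)
        # normalize to 1 expected substitution / site / unit time
        mu = -float(np.sum(pi * np.diag(Q)))
        Q /= mu
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        left = U / d[:, None]      # rows scaled: P(t) = left @ e^{wt} @ right
        right = U.T * d[None, :]
        self._eig = (w, left, right)

    @property
    def stationary(self) -> np.ndarray:
        return np.asarray(self.freqs)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for a branch of length t (expected substitutions/site)."""
        w, left, right = self._eig
        P = (left * np.exp(w * t)) @ right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for an array of branch lengths, shape (len(ts), 4, 4)."""
        w, left, right = self._eig
        E = np.exp(np.multiply.outer(np.asarray(ts, dtype=float), w))  # (m,4)
        P = np.einsum("ik,mk,kj->mij", left, E, right)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def jc_model() -> HKYModel:
    """Jukes-Cantor: kappa = 1, equal base frequencies."""
    return HKYModel(kappa=1.0, freqs=(0.25, 0.25, 0.25, 0.25))


def jc_p_different(d: float) -> float:
    """JC probability that two sequences differ at a site, at distance d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
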