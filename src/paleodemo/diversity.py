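"""Single-locus diversity and neutrality statistics.

All statistics assume a gap/missing-free alignment (see
:func:`paleodemo.alignment.filter_sites`). Undefined statistics are
returned as ``nan`` sentinels, never silently 0.

Notation: n sequences, L sites, S segregating sites, h haplotypes,
H haplotype diversity (Nei 1987), pi nucleotide diversity per site
(mean pairwise proportion of differing sites, no multiple-hit
correction), theta_w Watterson's theta per site, Tajima's D and Fu's Fs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np

from .alignment import GAP, SequenceAlignment


def _check_clean(aln: SequenceAlignment) -> None:
    if (aln.seqs >= GAP).any():
        raise ValueError("alignment contains gaps or missing data; run filter_sites first")


def segregating_sites(aln: SequenceAlignment) -> int:
    """Number of columns with more than one residue (tri-allelic count once)."""
    _check_clean(aln)
    return int((aln.seqs != aln.seqs[0]).any(axis=0).sum())


def haplotype_diversity(aln: SequenceAlignment) -> tuple[int, float]:
    """Distinct-row count h and Nei's H = n/(n-1) * (1 - sum p_i^2)."""
    _check_clean(aln)
    if aln.n < 2:
        raise ValueError("need n >= 2")
    _, counts = np.unique(aln.seqs, axis=0, return_counts=True)
    n = aln.n
    p = counts / n
    H = (n / (n - 1)) * (1.0 - float(np.sum(p * p)))
    return len(counts), H


def pairwise_difference_matrix(aln: SequenceAlignment) -> np.ndarray:
    """Counts of differing sites for all sequence pairs (n x n)."""
    s = aln.seqs
    return (s[:, None, :] != s[None, :, :]).sum(axis=2)


def mean_pairwise_differences(aln: SequenceAlignment) -> float:
    """Mean number of differing sites over all C(n,2) pairs (per locus)."""
    _check_clean(aln)
    if aln.n < 2:
        raise ValueError("need n >= 2")
    d = pairwise_difference_matrix(aln)
    iu = np.triu_indices(aln.n, k=1)
    return float(d[iu].mean())


def nucleotide_diversity(aln: SequenceAlignment) -> float:
    """pi per site: mean pairwise proportion of differing sites."""
    return mean_pairwise_differences(aln) / aln.L


def harmonic_number(m: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, m + 1)))


def watterson_theta(aln: SequenceAlignment, per_site: bool = True) -> float:
    """Watterson's estimator S / a1 (optionally per site)."""
    S = segregating_sites(aln)
    a1 = harmonic_number(aln.n - 1)
    theta = S / a1
    return theta / aln.L if per_site else theta


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_D(aln: SequenceAlignment) -> float:
    """Tajima's (1989) D; nan when S = 0 (undefined, not zero)."""
    S = segregating_sites(aln)
    if S == 0:
        return math.nan
    if aln.n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    k = mean_pairwise_differences(aln)
    c = tajima_constants(aln.n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k - S / c["a1"]) / math.sqrt(var)


@lru_cache(maxsize=None)
def _log_stirling1_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n, from the exact big-int recurrence."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            prev_k = row[k] if k < len(row) else 0
            new[k] = row[k - 1] + (m - 1) * prev_k
        row = new
    return tuple(math.log(v) if v > 0 else -math.inf for v in row)


def _logsumexp(vals: list[float]) -> float:
    m = max(vals)
    if m == -math.inf:
        return -math.inf
    return m + math.log(sum(math.exp(v - m) for v in vals))


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens distribution of the
    number of alleles: P(K=k) = |s(n,k)| theta^k / theta^(n) (rising)."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = _log_stirling1_row(n)
    log_rising = sum(math.log(theta + j) for j in range(n))
    k = np.arange(1, n + 1)
    return np.array([ls[ki] + ki * math.log(theta) - log_rising for ki in k])


def fus_Fs(aln: SequenceAlignment) -> float:
    """Fu's (1997) Fs = ln(S'/(1-S')), S' = P(K >= h_obs | theta = pi_locus).

    Computed in log space from exact Stirling numbers. Returns nan when
    S = 0; signed infinity (with a warning) if S' underflows to 0 or 1.
    """
    S = segregating_sites(aln)
    if S == 0:
        return math.nan
    n = aln.n
    h_obs, _ = haplotype_diversity(aln)
    theta = mean_pairwise_differences(aln)  # per-locus pairwise differences
    logp = ewens_log_pmf(n, theta)
    log_Sp = _logsumexp(list(logp[h_obs - 1:]))
    log_1mSp = _logsumexp(list(logp[:h_obs - 1])) if h_obs > 1 else -math.inf
    if log_1mSp == -math.inf:
        warnings.warn("Fu's Fs: P(K < h_obs) underflows; returning -inf")
        return -math.inf
    if log_Sp == -math.inf:
        warnings.warn("Fu's Fs: P(K >= h_obs) underflows; returning +inf")
        return math.inf
    return log_Sp - log_1mSp


@dataclass
class DiversitySummary:
    n: int
    L: int
    S: int
    h: int
    H: float
    pi: float
    theta_w: float
    tajima_D: float
    fu_Fs: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(aln: SequenceAlignment) -> DiversitySummary:
    """All diversity indices for one (pre-filtered) alignment."""
    S = segregating_sites(aln)
    h, H = haplotype_diversity(aln)
    pi = nucleotide_diversity(aln)
    return DiversitySummary(
        n=aln.n, L=aln.L, S=S, h=h, H=H, pi=pi,
        theta_w=watterson_theta(aln),
        tajima_D=tajimas_D(aln) if (S > 0 and aln.n >= 4) else math.nan,
        fu_Fs=fus_Fs(aln),
    )
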