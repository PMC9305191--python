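"""Aligned-sequence containers, FASTA I/O, site filtering and subsampling.

Sequences are stored as a small-integer matrix (A,C,G,T,-,N -> 0..5).
Site coordinates are 0-based half-open internally; reports are 1-based.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT-N"
A, C, G, T, GAP, MISSING = range(6)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# IUPAC ambiguity codes other than N are treated as missing data.
_AMBIGUOUS = "RYSWKMBDHV"
for _b in _AMBIGUOUS:
    _CODE[ord(_b)] = MISSING
    _CODE[ord(_b.lower())] = MISSING

MARKER_CLASSES = ("control_region", "other_mtdna", "nuclear")


@dataclass
class SequenceAlignment:
    """Equal-length haploid sequences with per-sequence deme labels.

    demes are integer labels 1..D. ``seqs`` is an (n, L) uint8 matrix
    over the code space of :data:`ALPHABET`.
    """

    ids: list[str]
    demes: np.ndarray
    seqs: np.ndarray
    locus_name: str = "locus"
    marker_class: str = "control_region"

    def __post_init__(self) -> None:
        self.demes = np.asarray(self.demes, dtype=int)
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D matrix")
        n, L = self.seqs.shape
        if L < 1:
            raise ValueError("alignment has no sites")
        if len(self.ids) != n or len(self.demes) != n:
            raise ValueError("ids/demes length must match number of sequences")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"marker_class must be one of {MARKER_CLASSES}")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    @property
    def deme_labels(self) -> np.ndarray:
        return np.unique(self.demes)

    def sequence(self, i: int) -> str:
        return "".join(ALPHABET[c] for c in self.seqs[i])

    @classmethod
    def from_strings(cls, ids: Sequence[str], seqs: Sequence[str],
                     demes: Sequence[int] | None = None, **kw) -> "SequenceAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            bad = _unequal_ids(ids, seqs)
            raise ValueError(f"sequences of unequal length: {bad}")
        mat = encode_sequences(seqs)
        if demes is None:
            demes = np.ones(len(ids), dtype=int)
        return cls(list(ids), np.asarray(demes), mat, **kw)

    def take(self, rows: Iterable[int]) -> "SequenceAlignment":
        rows = list(rows)
        return SequenceAlignment(
            [self.ids[i] for i in rows], self.demes[rows], self.seqs[rows],
            locus_name=self.locus_name, marker_class=self.marker_class)


@dataclass
class FilterReport:
    """Bookkeeping for gap/missing-site removal (0-based indices)."""

    n_sites_input: int
    n_sites_removed_gap_missing: int
    n_sites_retained: int
    removed_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_sites_input != self.n_sites_removed_gap_missing + self.n_sites_retained:
            raise ValueError("filter report does not account for all columns")
        if list(self.removed_columns) != sorted(set(self.removed_columns)):
            raise ValueError("removed_columns must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "n_sites_input": self.n_sites_input,
            "n_sites_removed_gap_missing": self.n_sites_removed_gap_missing,
            "n_sites_retained": self.n_sites_retained,
            # 1-based in reports
            "removed_columns_1based": [i + 1 for i in self.removed_columns],
        }


def _unequal_ids(ids: Sequence[str], seqs: Sequence[str]) -> list[str]:
    from collections import Counter
    counts = Counter(len(s) for s in seqs)
    modal = counts.most_common(1)[0][0]
    return [i for i, s in zip(ids, seqs) if len(s) != modal]


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes < 0).any():
        bad = sorted({chr(b) for b in raw[codes < 0]})
        raise ValueError(f"unrecognized residue characters: {bad}")
    n_ambig = int(np.isin(raw, np.frombuffer(
        (_AMBIGUOUS + _AMBIGUOUS.lower()).encode(), dtype=np.uint8)).sum())
    if n_ambig:
        warnings.warn(f"{n_ambig} IUPAC ambiguity residues mapped to N", stacklevel=2)
    return codes.astype(np.uint8).reshape(len(seqs), -1)


def read_deme_map(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, deme) tab-separated table with header."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("deme map must have at least two columns (id, deme)")
    ids, demes = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)
    return dict(zip(ids, demes))


def read_alignment(path: str | Path, deme_map: Mapping[str, int] | str | Path,
                   locus_name: str | None = None,
                   marker_class: str = "control_region") -> SequenceAlignment:
    """Read a FASTA alignment with deme labels supplied externally.

    Every record id must be present in ``deme_map``; residues are
    uppercased and ambiguity codes other than N mapped to N (warning).
    """
    if not isinstance(deme_map, Mapping):
        deme_map = read_deme_map(deme_map)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences of unequal length: {_unequal_ids(ids, seqs)}")
    missing = [i for i in ids if i not in deme_map]
    if missing:
        raise ValueError(f"ids absent from deme map: {missing}")
    demes = np.array([deme_map[i] for i in ids], dtype=int)
    return SequenceAlignment(
        ids, demes, encode_sequences(seqs),
        locus_name=locus_name or Path(path).stem, marker_class=marker_class)


def write_alignment(aln: SequenceAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(aln.sequence(i)), id=aln.ids[i], description="")
               for i in range(aln.n)]
    SeqIO.write(records, str(path), "fasta")


def filter_sites(aln: SequenceAlignment) -> tuple[SequenceAlignment, FilterReport]:
    """Remove every column containing a gap or missing residue in any row."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    bad = (aln.seqs >= GAP).any(axis=0)
    keep = ~bad
    if not keep.any():
        raise ValueError("no sites retained after gap/missing filtering")
    report = FilterReport(
        n_sites_input=aln.L,
        n_sites_removed_gap_missing=int(bad.sum()),
        n_sites_retained=int(keep.sum()),
        removed_columns=list(np.flatnonzero(bad)),
    )
    filtered = SequenceAlignment(
        list(aln.ids), aln.demes.copy(), aln.seqs[:, keep],
        locus_name=aln.locus_name, marker_class=aln.marker_class)
    return filtered, report


def subsample(aln: SequenceAlignment, max_n: int, equalize: bool = False,
              seed: int | None = 0) -> SequenceAlignment:
    """Randomly cap per-deme sample sizes (without replacement).

    With ``equalize`` the cap is the smallest of (per-deme counts, max_n),
    so all demes end up with equal sizes; mirrors the reduction used to
    avoid uneven-sample-size bias. Deterministic for a fixed seed.
    """
    if max_n < 2:
        raise ValueError("max_n must be >= 2")
    rng = np.random.default_rng(seed)
    labels, counts = np.unique(aln.demes, return_counts=True)
    cap = {d: max_n for d in labels}
    if equalize:
        m = min(int(counts.min()), max_n)
        cap = {d: m for d in labels}
    keep: list[int] = []
    for d in labels:
        idx = np.flatnonzero(aln.demes == d)
        if len(idx) > cap[d]:
            idx = rng.choice(idx, size=cap[d], replace=False)
        keep.extend(int(i) for i in idx)
    keep.sort()
    return aln.take(keep)


def read_series(path: str | Path) -> pd.DataFrame:
    """Read a two-column (age_years, value) TSV time series.

    Returns a DataFrame sorted ascending by age. Duplicate ages and
    non-numeric rows are hard errors (with the offending line number).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("series must have two columns (age_years, value)")
    df = df.iloc[:, :2]
    df.columns = ["age_years", "value"]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(coerced.isna())[0]) + 2
            raise ValueError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = coerced.astype(float)
    if (df["age_years"] < 0).any():
        raise ValueError("ages must be >= 0")
    if df["age_years"].duplicated().any():
        dup = df.loc[df["age_years"].duplicated(), "age_years"].iloc[0]
        raise ValueError(f"duplicated age {dup}")
    return df.sort_values("age_years", ignore_index=True)
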