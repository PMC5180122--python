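"""Pairwise sequence divergence under Kimura's two-parameter (K2P) model.

The K2P model corrects observed differences for multiple hits, treating
transitions (purine<->purine, pyrimidine<->pyrimidine) and transversions
separately:

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the proportions of compared sites differing by a
transition and a transversion respectively.  Sites where either sequence
carries a gap or any ambiguity code are dropped per pair (pairwise
deletion).  Pairs whose (P, Q) fall outside the domain of the logarithm
are *saturated*: no finite distance exists and the pair is flagged and
excluded from summary means rather than clamped.

Distances are stored as proportions (substitutions per site); reports
multiply by 100 and print percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PairStatus",
    "PairCounts",
    "DistanceMatrix",
    "encode_sequence",
    "pair_counts",
    "k2p",
    "k2p_from_pq",
    "p_distance",
    "distance_matrix",
]

# Nucleotide codes: A=0, C=1, G=2, T=3.  With this encoding a transition
# is XOR 2 and a transversion is XOR 1 or XOR 3.  Anything else (gaps,
# N, IUPAC ambiguity codes) maps to MISSING and is excluded pairwise.
MISSING = 255
_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


class PairStatus(IntEnum):
    OK = 0
    SATURATED = 1
    INSUFFICIENT = 2


@dataclass(frozen=True)
class PairCounts:
    """Site counts for one sequence pair after pairwise deletion.

    L is the number of comparable sites (both sequences a plain A/C/G/T),
    ts and tv the transition and transversion differences among them.
    """

    L: int
    ts: int
    tv: int

    def __post_init__(self) -> None:
        if self.ts + self.tv > self.L:
            raise ValueError("ts + tv cannot exceed the number of compared sites")

    @property
    def P(self) -> float:
        return self.ts / self.L if self.L else math.nan

    @property
    def Q(self) -> float:
        return self.tv / self.L if self.L else math.nan


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes (non-ACGT -> MISSING)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def pair_counts(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> PairCounts:
    """Count comparable sites and transition/transversion differences.

    Accepts raw strings or arrays from :func:`encode_sequence`.  Sites
    where either sequence is gapped or ambiguous are excluded (pairwise
    deletion).  L == 0 signals insufficient overlap; downstream
    :func:`k2p` flags it rather than raising here.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError(
            f"sequences must be aligned to equal length ({a.size} vs {b.size})"
        )
    comparable = (a != MISSING) & (b != MISSING)
    xor = (a ^ b)[comparable]
    ts = int(np.count_nonzero(xor == 2))
    diff = int(np.count_nonzero(xor))
    return PairCounts(L=int(comparable.sum()), ts=ts, tv=diff - ts)


def k2p_from_pq(P: float, Q: float) -> tuple[float, PairStatus]:
    """K2P distance from transition/transversion proportions.

    Returns (distance, OK) inside the model's domain, (nan, SATURATED)
    where the log argument is non-positive (divergence too high for a
    finite estimate).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, PairStatus.SATURATED
    return -0.5 * math.log(w1 * math.sqrt(w2)), PairStatus.OK


def k2p(counts: PairCounts) -> tuple[float, PairStatus]:
    """K2P distance for one pair; flags saturated / insufficient pairs."""
    if counts.L == 0:
        return math.nan, PairStatus.INSUFFICIENT
    return k2p_from_pq(counts.P, counts.Q)


def p_distance(counts: PairCounts) -> tuple[float, PairStatus]:
    """Uncorrected proportion of differing sites (diagnostic companion)."""
    if counts.L == 0:
        return math.nan, PairStatus.INSUFFICIENT
    return (counts.ts + counts.tv) / counts.L, PairStatus.OK


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-cell diagnostics.

    d holds proportions, NaN wherever the flag is not OK; L the number of
    comparable sites per pair; flags a PairStatus code per cell.
    """

    ids: list[str]
    d: np.ndarray
    L: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate specimen ids in distance matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> tuple[float, PairStatus]:
        i, j = self.index(id_a), self.index(id_b)
        return float(self.d[i, j]), PairStatus(self.flags[i, j])

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        keep = [self.index(i) for i in ids]
        idx = np.ix_(keep, keep)
        return DistanceMatrix(
            ids=[self.ids[k] for k in keep],
            d=self.d[idx].copy(),
            L=self.L[idx].copy(),
            flags=self.flags[idx].copy(),
        )

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        vals = self.d * 100.0 if percent else self.d
        return pd.DataFrame(vals, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path, percent: bool = False) -> None:
        self.to_dataframe(percent=percent).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, percent: bool = False) -> "DistanceMatrix":
        """Read a square TSV; a PHYLIP-style lower triangle is mirrored."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy(dtype=float)
        n = vals.shape[0]
        if vals.shape[1] != n:
            raise ValueError("distance table is not square")
        upper = np.triu_indices(n, k=1)
        if np.isnan(vals[upper]).all() and n > 1:
            vals[upper] = vals.T[upper]  # lower-triangle input
        if percent:
            vals = vals / 100.0
        flags = np.where(np.isnan(vals), PairStatus.SATURATED, PairStatus.OK)
        np.fill_diagonal(flags, PairStatus.OK)
        return cls(
            ids=[str(c) for c in df.index],
            d=vals,
            L=np.zeros_like(vals, dtype=int),
            flags=flags.astype(np.int8),
        )


def distance_matrix(alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distances for a :class:`~barcodegap.io.LocusAlignment`.

    model is "k2p" or "p".  Deterministic and order-independent: permuting
    the input rows permutes the matrix identically.
    """
    rows = list(zip(alignment.ids, alignment.sequences))
    if len(rows) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    estimator = k2p if model == "k2p" else p_distance
    n = len(rows)
    codes = [encode_sequence(s) for _, s in rows]
    d = np.zeros((n, n))
    L = np.zeros((n, n), dtype=int)
    flags = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        L[i, i] = int(np.count_nonzero(codes[i] != MISSING))
        for j in range(i + 1, n):
            counts = pair_counts(codes[i], codes[j])
            dist, status = estimator(counts)
            d[i, j] = d[j, i] = dist
            L[i, j] = L[j, i] = counts.L
            flags[i, j] = flags[j, i] = status
    return DistanceMatrix(ids=[r[0] for r in rows], d=d, L=L, flags=flags)
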