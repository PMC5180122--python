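"""Barcoding-gap analysis and species delimitation within one morphospecies.

Given a clade partition and the pairwise K2P matrix, this module
summarises intra- and inter-clade divergence (in percent), tests for a
barcoding gap (strict: minimum inter-clade minus maximum intra-clade
distance), applies the 10x rule of thumb (mean inter-clade divergence at
least k times mean intra-clade divergence, k = 10 by default), and
combines the two into a verdict:

- single_species: one clade only;
- cryptic_species: multiple clades with gap and ratio support, or — when
  the gap is absent — inter-clade divergence at least as large as the
  smallest divergence among supplied congeneric reference species;
- species_complex: multiple clades whose intra/inter variation overlaps
  with no reference support;
- undetermined: too few defined cells to decide (e.g. all singletons).

Means are pooled arithmetic means of pairwise distances; saturated pairs
are excluded and counted, never clamped.  Singleton clades contribute to
inter- but not intra-clade variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .clades import CladePartition
from .distance import DistanceMatrix, PairStatus

__all__ = [
    "CellStats",
    "VariationSummary",
    "DelimitationStatus",
    "DelimitationVerdict",
    "variation_summary",
    "barcoding_gap",
    "ratio_rule",
    "delimit",
]


@dataclass(frozen=True)
class CellStats:
    """Mean/min/max K2P percent over the pairs of one summary cell."""

    mean: float | None
    min: float | None
    max: float | None
    n_pairs: int
    n_saturated: int

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


@dataclass
class VariationSummary:
    """Intra-/inter-clade K2P summaries (percent) for one morphospecies-locus."""

    morphospecies: str
    locus: str
    n_blocks: int
    intra: dict[int, CellStats]
    inter: dict[tuple[int, int], CellStats]
    mean_intra: float | None
    mean_inter: float | None
    max_intra: float | None
    min_inter: float | None
    n_intra_pairs: int
    n_inter_pairs: int
    n_saturated: int


class DelimitationStatus(Enum):
    SINGLE_SPECIES = "single_species"
    CRYPTIC_SPECIES = "cryptic_species"
    SPECIES_COMPLEX = "species_complex"
    UNDETERMINED = "undetermined"


@dataclass
class DelimitationVerdict:
    status: DelimitationStatus
    gap_size: float | None = None  # percent; min inter - max intra
    gap_present: bool | None = None
    ratio: float | None = None  # mean inter / mean intra
    ratio_pass: bool | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def is_cryptic(self) -> bool:
        return self.status is DelimitationStatus.CRYPTIC_SPECIES


def _cell(values: list[float], n_saturated: int) -> CellStats:
    if not values:
        return CellStats(None, None, None, 0, n_saturated)
    return CellStats(
        mean=float(np.mean(values)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        n_pairs=len(values),
        n_saturated=n_saturated,
    )


def variation_summary(
    partition: CladePartition, distmat: DistanceMatrix
) -> VariationSummary:
    """Pairwise K2P summaries (percent) within and between clades.

    Overall means pool all intra (resp. inter) pairs across cells,
    weighting every specimen pair equally.
    """
    missing = sorted(partition.specimens - set(distmat.ids))
    if missing:
        raise KeyError(f"specimens absent from distance matrix: {missing}")
    blocks = partition.blocks
    intra: dict[int, CellStats] = {}
    inter: dict[tuple[int, int], CellStats] = {}
    all_intra: list[float] = []
    all_inter: list[float] = []
    n_sat = 0
    for bi, block in enumerate(blocks):
        vals, sat = _pair_values(distmat, sorted(block), sorted(block), within=True)
        intra[bi] = _cell(vals, sat)
        all_intra.extend(vals)
        n_sat += sat
    for bi in range(len(blocks)):
        for bj in range(bi + 1, len(blocks)):
            vals, sat = _pair_values(
                distmat, sorted(blocks[bi]), sorted(blocks[bj]), within=False
            )
            inter[(bi, bj)] = _cell(vals, sat)
            all_inter.extend(vals)
            n_sat += sat
    return VariationSummary(
        morphospecies=partition.morphospecies,
        locus=partition.locus,
        n_blocks=len(blocks),
        intra=intra,
        inter=inter,
        mean_intra=float(np.mean(all_intra)) if all_intra else None,
        mean_inter=float(np.mean(all_inter)) if all_inter else None,
        max_intra=float(np.max(all_intra)) if all_intra else None,
        min_inter=float(np.min(all_inter)) if all_inter else None,
        n_intra_pairs=len(all_intra),
        n_inter_pairs=len(all_inter),
        n_saturated=n_sat,
    )


def _pair_values(
    distmat: DistanceMatrix, ids_a: Sequence[str], ids_b: Sequence[str], within: bool
) -> tuple[list[float], int]:
    values: list[float] = []
    saturated = 0
    if within:
        pairs = [
            (ids_a[i], ids_a[j])
            for i in range(len(ids_a))
            for j in range(i + 1, len(ids_a))
        ]
    else:
        pairs = [(a, b) for a in ids_a for b in ids_b]
    for a, b in pairs:
        d, status = distmat.get(a, b)
        if status is PairStatus.OK:
            values.append(d * 100.0)
        else:
            saturated += 1
    return values, saturated


def barcoding_gap(summary: VariationSummary) -> tuple[float | None, bool | None]:
    """Strict barcoding gap: (min inter - max intra, present?).

    Requires at least two clades with one defined intra and one defined
    inter cell; otherwise returns (None, None) — undecidable (e.g. all
    clades are singletons).
    """
    if summary.n_blocks < 2:
        return None, None
    if summary.max_intra is None or summary.min_inter is None:
        return None, None
    gap = summary.min_inter - summary.max_intra
    return gap, gap > 0


def ratio_rule(summary: VariationSummary, k: float = 10.0) -> tuple[float | None, bool]:
    """The 10x rule of thumb: mean inter >= k * mean intra.

    Zero mean intra with positive mean inter passes (ratio infinite);
    both zero fails.  Returns (ratio, pass?); ratio is None when mean
    inter is undefined.
    """
    if summary.mean_inter is None:
        return None, False
    if summary.mean_intra is None or summary.mean_intra == 0.0:
        if summary.mean_inter > 0.0:
            return math.inf, True
        return None, False
    ratio = summary.mean_inter / summary.mean_intra
    return ratio, ratio >= k


def delimit(
    partition: CladePartition,
    summary: VariationSummary,
    reference_distances: Iterable[float] | None = None,
    k: float = 10.0,
) -> DelimitationVerdict:
    """Combine gap and ratio evidence into a delimitation verdict.

    reference_distances, when given, are inter-species K2P percentages
    among congeneric reference species; clades whose mean inter-clade
    divergence reaches the smallest reference divergence are accepted as
    cryptic species even without a clean gap.
    """
    if partition.n_blocks == 1:
        return DelimitationVerdict(status=DelimitationStatus.SINGLE_SPECIES)
    gap, present = barcoding_gap(summary)
    ratio, ratio_ok = ratio_rule(summary, k=k)
    verdict = DelimitationVerdict(
        status=DelimitationStatus.UNDETERMINED,
        gap_size=gap,
        gap_present=present,
        ratio=ratio,
        ratio_pass=ratio_ok,
    )
    if summary.mean_inter is None or summary.mean_intra is None:
        verdict.notes.append(
            "insufficient defined cells (singleton clades or saturated pairs)"
        )
        return verdict
    if present and ratio_ok:
        verdict.status = DelimitationStatus.CRYPTIC_SPECIES
        return verdict
    refs = sorted(reference_distances) if reference_distances else []
    if not present and refs and summary.mean_inter >= refs[0]:
        verdict.status = DelimitationStatus.CRYPTIC_SPECIES
        verdict.notes.append(
            "no barcoding gap, but inter-clade divergence within the range "
            f"of congeneric reference species (>= {refs[0]:.2f}%)"
        )
        return verdict
    verdict.status = DelimitationStatus.SPECIES_COMPLEX
    if present and not ratio_ok:
        verdict.notes.append(
            f"gap present but inter/intra ratio {ratio:.1f} below {k:g}x rule"
        )
    else:
        verdict.notes.append("intra- and inter-clade variation overlap")
    return verdict
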