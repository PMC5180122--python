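"""Partitioning a morphospecies' specimens into candidate clades.

Two routes produce a partition: distance-threshold clustering (single or
average linkage cut at a per-locus divergence threshold) or extraction of
well-supported monophyletic groups from an externally inferred tree.
Downstream logic consumes the partition only, never the tree itself.

Tie-breaking is strict: pairs at exactly the threshold do NOT merge, so
runs are deterministic and permutation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix, PairStatus
from .io import SupportTree

__all__ = [
    "CladePartition",
    "CrossLocusContingency",
    "cluster_by_threshold",
    "partition_from_tree",
    "map_partition_across_loci",
    "order_blocks",
]


@dataclass
class CladePartition:
    """Disjoint non-empty specimen blocks covering one morphospecies-locus."""

    morphospecies: str
    locus: str
    blocks: list[frozenset]
    provenance: str

    def __post_init__(self) -> None:
        if any(not b for b in self.blocks):
            raise ValueError("empty clade block")
        all_ids = [i for b in self.blocks for i in b]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("clade blocks are not disjoint")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def specimens(self) -> frozenset:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def block_of(self, specimen_id: str) -> int:
        for k, b in enumerate(self.blocks):
            if specimen_id in b:
                return k
        raise KeyError(specimen_id)


def order_blocks(blocks: Iterable[frozenset]) -> list[frozenset]:
    """Deterministic clade order: size descending, then smallest member id."""
    return sorted(blocks, key=lambda b: (-len(b), min(b)))


def cluster_by_threshold(
    distmat: DistanceMatrix,
    threshold: float,
    linkage: str = "single",
    morphospecies: str = "",
    locus: str = "",
) -> CladePartition:
    """Cut agglomerative clustering at a distance threshold.

    Single linkage at a fixed cut equals the connected components of the
    graph whose edges are pairs with d < threshold, which is how it is
    computed.  Saturated or insufficient pairs are treated as exceeding
    any threshold.  Identical sequences (d == 0) always co-cluster.
    """
    n = distmat.n
    if n == 0:
        raise ValueError("empty distance matrix")
    d = distmat.d.copy()
    bad = distmat.flags != PairStatus.OK
    d[bad] = np.inf
    np.fill_diagonal(d, 0.0)
    if linkage == "single":
        adj = csr_matrix(d < threshold)
        _, labels = connected_components(adj, directed=False)
    elif linkage == "average":
        finite = d[np.isfinite(d)]
        sentinel = max(float(finite.max(initial=0.0)), threshold) * 4.0 + 1.0
        dd = np.where(np.isfinite(d), d, sentinel)
        Z = scipy_linkage(squareform(dd, checks=False), method="average")
        # fcluster merges at height <= t; nudge below the threshold so a
        # merge at exactly the threshold is excluded (strict less-than).
        labels = fcluster(Z, t=np.nextafter(threshold, 0.0), criterion="distance")
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    blocks: dict[int, set] = {}
    for sid, lab in zip(distmat.ids, labels):
        blocks.setdefault(int(lab), set()).add(sid)
    return CladePartition(
        morphospecies=morphospecies,
        locus=locus,
        blocks=order_blocks(frozenset(b) for b in blocks.values()),
        provenance=f"threshold-clustering(linkage={linkage}, threshold={threshold})",
    )


def partition_from_tree(
    tree: SupportTree,
    morphospecies_specimens: Sequence[str],
    min_support: float = 0.95,
    morphospecies: str = "",
    locus: str = "",
) -> CladePartition:
    """Clades = maximal supported monophyletic groups of the specimens.

    A node qualifies when its support is >= min_support and its leaf set
    consists only of the morphospecies' specimens; the maximal (outermost)
    qualifying nodes become blocks.  Specimens covered by no qualifying
    node become singletons.  Nodes with absent support never qualify.
    """
    wanted = set(morphospecies_specimens)
    in_tree = tree.leaf_names()
    missing = sorted(wanted - in_tree)
    if missing:
        raise KeyError(f"specimens absent from tree: {missing}")
    taken: set[str] = set()
    blocks: list[frozenset] = []
    # preorder: outermost qualifying clades claim their leaves first
    for leaves, support in tree.clades_with_support():
        if support is None or support < min_support:
            continue
        members = leaves & wanted
        if members != leaves or len(members) < 2:
            continue  # not monophyletic within the morphospecies, or trivial
        if members & taken:
            continue  # nested inside an already-taken clade
        blocks.append(frozenset(members))
        taken |= members
    blocks.extend(frozenset({s}) for s in sorted(wanted - taken))
    return CladePartition(
        morphospecies=morphospecies,
        locus=locus,
        blocks=order_blocks(blocks),
        provenance=f"tree(min_support={min_support})",
    )


@dataclass
class CrossLocusContingency:
    """Co-membership of shared specimens across two per-locus partitions.

    table[i, j] counts specimens in block i of partition A and block j of
    partition B; specimens sequenced at only one locus are listed
    separately (they cannot be placed at the other locus).
    """

    table: pd.DataFrame
    shared: frozenset
    only_a: frozenset
    only_b: frozenset

    @property
    def undecidable(self) -> bool:
        return len(self.shared) == 0

    @property
    def coherent(self) -> bool:
        """No crossing pairs: the table has no 2x2 all-positive submatrix.

        This is the weakest condition under which one partition is a
        refinement-consistent match of the other on shared specimens.
        Undecidable (no shared specimens) is reported as not coherent;
        check :attr:`undecidable` first.
        """
        if self.undecidable:
            return False
        t = self.table.to_numpy() > 0
        rows = [np.flatnonzero(r) for r in t]
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if len(np.intersect1d(rows[i], rows[j])) >= 2:
                    return False
        return True

    @property
    def b_coarsens_a(self) -> bool:
        """Every block of A maps into exactly one block of B."""
        if self.undecidable:
            return False
        return bool(((self.table.to_numpy() > 0).sum(axis=1) <= 1).all())

    @property
    def a_coarsens_b(self) -> bool:
        if self.undecidable:
            return False
        return bool(((self.table.to_numpy() > 0).sum(axis=0) <= 1).all())


def map_partition_across_loci(
    partition_a: CladePartition, partition_b: CladePartition
) -> CrossLocusContingency:
    """Contingency of shared specimens between two loci's partitions."""
    if (
        partition_a.morphospecies
        and partition_b.morphospecies
        and partition_a.morphospecies != partition_b.morphospecies
    ):
        raise ValueError("partitions belong to different morphospecies")
    a_ids = partition_a.specimens
    b_ids = partition_b.specimens
    shared = a_ids & b_ids
    table = pd.DataFrame(
        0,
        index=range(partition_a.n_blocks),
        columns=range(partition_b.n_blocks),
    )
    for sid in shared:
        table.iloc[partition_a.block_of(sid), partition_b.block_of(sid)] += 1
    return CrossLocusContingency(
        table=table,
        shared=frozenset(shared),
        only_a=frozenset(a_ids - b_ids),
        only_b=frozenset(b_ids - a_ids),
    )
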