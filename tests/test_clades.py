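"""Clade inference: threshold clustering, tree extraction, cross-locus maps."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.clades import (
    CladePartition,
    cluster_by_threshold,
    map_partition_across_loci,
    partition_from_tree,
)
from barcodegap.distance import DistanceMatrix, PairStatus
from barcodegap.io import read_newick_tree


def matrix_from_array(d, ids=None, saturated=()):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    flags = np.zeros((n, n), dtype=np.int8)
    for i, j in saturated:
        flags[i, j] = flags[j, i] = PairStatus.SATURATED
        d[i, j] = d[j, i] = np.nan
    return DistanceMatrix(ids=ids, d=d, L=np.full((n, n), 100), flags=flags)


def components_oracle(d, threshold, flags=None):
    """Independent union-find over edges d < threshold."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            bad = flags is not None and flags[i, j] != PairStatus.OK
            if not bad and d[i, j] < threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


class TestThresholdClustering:
    def test_two_well_separated_blocks(self):
        d = np.array(
            [
                [0.00, 0.01, 0.10, 0.12],
                [0.01, 0.00, 0.11, 0.10],
                [0.10, 0.11, 0.00, 0.01],
                [0.12, 0.10, 0.01, 0.00],
            ]
        )
        part = cluster_by_threshold(matrix_from_array(d), threshold=0.05)
        assert sorted(sorted(b) for b in part.blocks) == [
            ["s0", "s1"],
            ["s2", "s3"],
        ]

    def test_threshold_above_max_gives_one_clade(self):
        d = np.array([[0, 0.1], [0.1, 0]])
        part = cluster_by_threshold(matrix_from_array(d), threshold=0.2)
        assert part.n_blocks == 1

    def test_threshold_below_min_gives_singletons(self):
        d = np.array([[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]])
        part = cluster_by_threshold(matrix_from_array(d), threshold=0.05)
        assert part.n_blocks == 3

    def test_identical_sequences_always_co_cluster(self):
        d = np.zeros((2, 2))
        part = cluster_by_threshold(matrix_from_array(d), threshold=1e-9)
        assert part.n_blocks == 1

    def test_exact_threshold_does_not_merge(self):
        d = np.array([[0, 0.05], [0.05, 0]])
        part = cluster_by_threshold(matrix_from_array(d), threshold=0.05)
        assert part.n_blocks == 2
        part = cluster_by_threshold(
            matrix_from_array(d), threshold=0.05, linkage="average"
        )
        assert part.n_blocks == 2

    def test_saturated_pairs_never_link(self):
        d = np.array([[0, 0.01], [0.01, 0]])
        m = matrix_from_array(d, saturated=[(0, 1)])
        part = cluster_by_threshold(m, threshold=0.05)
        assert part.n_blocks == 2

    def test_empty_matrix_rejected(self):
        m = DistanceMatrix(
            ids=[], d=np.zeros((0, 0)), L=np.zeros((0, 0), int),
            flags=np.zeros((0, 0), np.int8),
        )
        with pytest.raises(ValueError, match="empty"):
            cluster_by_threshold(m, threshold=0.05)

    @given(
        n=st.integers(2, 12),
        threshold=st.floats(0.01, 0.3),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_single_linkage_equals_connected_components(self, n, threshold, data):
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 0.4, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        m = matrix_from_array(d.copy())
        part = cluster_by_threshold(m, threshold=threshold)
        got = {frozenset(m.index(s) for s in b) for b in part.blocks}
        assert got == set(components_oracle(d, threshold))

    @given(n=st.integers(3, 10), seed=st.integers(0, 5000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_raising_threshold_never_splits(self, n, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 0.4, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        m = matrix_from_array(d)
        counts = [
            cluster_by_threshold(m, threshold=t).n_blocks
            for t in (0.05, 0.1, 0.2, 0.3, 0.45)
        ]
        assert counts == sorted(counts, reverse=True)


class TestTreePartition:
    def test_supported_clades_extracted(self):
        tree = read_newick_tree("((A,B)0.99,(C,D)0.97);")
        part = partition_from_tree(tree, ["A", "B", "C", "D"], min_support=0.95)
        assert sorted(sorted(b) for b in part.blocks) == [["A", "B"], ["C", "D"]]

    def test_low_support_breaks_into_singletons(self):
        tree = read_newick_tree("((A,B)0.80,(C,D)0.97);")
        part = partition_from_tree(tree, ["A", "B", "C", "D"], min_support=0.95)
        assert sorted(sorted(b) for b in part.blocks) == [["A"], ["B"], ["C", "D"]]

    def test_missing_specimen_listed(self):
        tree = read_newick_tree("((A,B)0.99,C);")
        with pytest.raises(KeyError, match="Z9"):
            partition_from_tree(tree, ["A", "Z9"])

    def test_foreign_leaf_breaks_monophyly(self):
        # E is another morphospecies nested inside the supported clade
        tree = read_newick_tree("(((A,E)0.99,B)0.99,(C,D)0.97);")
        part = partition_from_tree(tree, ["A", "B", "C", "D"], min_support=0.95)
        assert frozenset({"C", "D"}) in part.blocks
        assert frozenset({"A"}) in part.blocks  # A cannot join B through E

    def test_rerooting_on_outgroup_invariant(self):
        unrooted = read_newick_tree("((A,B)0.99,(C,D)0.97,O);")
        rooted = read_newick_tree("(((A,B)0.99,(C,D)0.97),O);")
        specimens = ["A", "B", "C", "D"]
        p1 = partition_from_tree(unrooted, specimens)
        p2 = partition_from_tree(rooted, specimens)
        assert sorted(p1.blocks, key=min) == sorted(p2.blocks, key=min)

    @given(seed=st.integers(0, 3000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_exhaustive_node_scan(self, seed):
        rng = np.random.default_rng(seed)
        leaves = [f"t{i}" for i in range(12)]
        newick = _random_supported_newick(leaves, rng)
        tree = read_newick_tree(newick)
        wanted = set(rng.choice(leaves, size=8, replace=False))
        part = partition_from_tree(tree, sorted(wanted), min_support=0.95)
        # oracle: all qualifying node leaf-sets, keep the maximal ones
        qualifying = [
            ls
            for ls, sup in tree.clades_with_support()
            if sup is not None and sup >= 0.95 and ls <= wanted and len(ls) >= 2
        ]
        maximal = [
            q for q in qualifying
            if not any(q < other for other in qualifying)
        ]
        expected = set(map(frozenset, maximal))
        covered = set().union(*expected) if expected else set()
        expected |= {frozenset({s}) for s in wanted - covered}
        assert set(part.blocks) == expected


def _random_supported_newick(leaves, rng):
    """Random binary topology with random supports (some absent)."""

    def build(names):
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        left, right = build(names[:k]), build(names[k:])
        sup = rng.choice(["", "0.99", "0.97", "0.9", "0.5"])
        return f"({left},{right}){sup}"

    order = list(rng.permutation(leaves))
    return build(order) + ";"


class TestCrossLocus:
    def part(self, blocks, locus="COI"):
        return CladePartition(
            morphospecies="m", locus=locus,
            blocks=[frozenset(b) for b in blocks], provenance="test",
        )

    def test_identical_blocks_coherent_both_ways(self):
        a = self.part([{"A", "B"}, {"C", "D"}])
        b = self.part([{"A", "B"}, {"C", "D"}], locus="16S")
        c = map_partition_across_loci(a, b)
        assert c.coherent and c.a_coarsens_b and c.b_coarsens_a

    def test_coarsening_detected(self):
        # two fast-locus clades merged by the slow locus
        coi = self.part([{"A", "B"}, {"C", "D"}])
        s16 = self.part([{"A", "B", "C", "D"}], locus="16S")
        c = map_partition_across_loci(coi, s16)
        assert c.coherent and c.b_coarsens_a and not c.a_coarsens_b

    def test_crossing_pairs_incoherent(self):
        coi = self.part([{"A", "B"}, {"C", "D"}])
        s16 = self.part([{"A", "C"}, {"B", "D"}], locus="16S")
        c = map_partition_across_loci(coi, s16)
        assert not c.coherent

    def test_disjoint_specimens_undecidable(self):
        coi = self.part([{"A", "B"}])
        s16 = self.part([{"C", "D"}], locus="16S")
        c = map_partition_across_loci(coi, s16)
        assert c.undecidable

    def test_single_locus_specimens_listed(self):
        coi = self.part([{"A", "B"}])
        s16 = self.part([{"A", "B", "E"}], locus="16S")
        c = map_partition_across_loci(coi, s16)
        assert c.only_b == frozenset({"E"})
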