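"""Variation summaries, barcoding gap, 10x rule, delimitation verdicts."""

from __future__ import annotations

import numpy as np
import pytest

from barcodegap.clades import CladePartition, cluster_by_threshold
from barcodegap.distance import DistanceMatrix, PairStatus, distance_matrix
from barcodegap.gap import (
    DelimitationStatus,
    VariationSummary,
    barcoding_gap,
    delimit,
    ratio_rule,
    variation_summary,
)
from barcodegap.simulate import SimulationConfig, simulate_dataset


def partition(blocks, morph="m", locus="COI"):
    return CladePartition(
        morphospecies=morph, locus=locus,
        blocks=[frozenset(b) for b in blocks], provenance="test",
    )


def matrix(d, ids):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    return DistanceMatrix(
        ids=ids, d=d, L=np.full((n, n), 100), flags=np.zeros((n, n), np.int8)
    )


def summary_with(mean_intra, mean_inter, max_intra=None, min_inter=None, n_blocks=2):
    return VariationSummary(
        morphospecies="m", locus="COI", n_blocks=n_blocks,
        intra={}, inter={},
        mean_intra=mean_intra, mean_inter=mean_inter,
        max_intra=max_intra if max_intra is not None else mean_intra,
        min_inter=min_inter if min_inter is not None else mean_inter,
        n_intra_pairs=0 if mean_intra is None else 1,
        n_inter_pairs=0 if mean_inter is None else 1,
        n_saturated=0,
    )


class TestVariationSummary:
    def test_two_identical_clades_at_fixed_distance(self):
        ids = ["a1", "a2", "b1", "b2"]
        d = np.array(
            [
                [0.00, 0.00, 0.08, 0.08],
                [0.00, 0.00, 0.08, 0.08],
                [0.08, 0.08, 0.00, 0.00],
                [0.08, 0.08, 0.00, 0.00],
            ]
        )
        s = variation_summary(partition([{"a1", "a2"}, {"b1", "b2"}]), matrix(d, ids))
        assert s.mean_intra == pytest.approx(0.0)
        assert s.mean_inter == pytest.approx(8.0)  # percent

    def test_all_singletons_have_undefined_intra(self):
        ids = ["a", "b"]
        s = variation_summary(
            partition([{"a"}, {"b"}]), matrix([[0, 0.05], [0.05, 0]], ids)
        )
        assert s.mean_intra is None
        assert s.mean_inter == pytest.approx(5.0)

    def test_matches_bruteforce_over_labelled_pairs(self, simulated_dataset):
        aln = simulated_dataset.alignments["16S"]
        m = distance_matrix(aln)
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=m.n)
        blocks = [
            {sid for sid, l in zip(m.ids, labels) if l == k} for k in range(3)
        ]
        blocks = [b for b in blocks if b]
        s = variation_summary(partition(blocks, locus="16S"), m)
        intra, inter = [], []
        for i in range(m.n):
            for j in range(i + 1, m.n):
                if m.flags[i, j] != PairStatus.OK:
                    continue
                (inter, intra)[bool(labels[i] == labels[j])].append(m.d[i, j] * 100)
        assert s.mean_intra == pytest.approx(np.mean(intra))
        assert s.mean_inter == pytest.approx(np.mean(inter))
        assert s.max_intra == pytest.approx(np.max(intra))
        assert s.min_inter == pytest.approx(np.min(inter))
        assert s.n_intra_pairs == len(intra) and s.n_inter_pairs == len(inter)


class TestBarcodingGap:
    def test_gap_arithmetic(self):
        gap, present = barcoding_gap(summary_with(0.5, 5.0, max_intra=0.5, min_inter=5.0))
        assert gap == pytest.approx(4.5) and present

    def test_overlap_means_absent(self):
        gap, present = barcoding_gap(summary_with(2.0, 3.0, max_intra=3.5, min_inter=2.5))
        assert gap == pytest.approx(-1.0) and not present

    def test_single_clade_undefined(self):
        gap, present = barcoding_gap(summary_with(0.5, None, n_blocks=1))
        assert gap is None and present is None

    def test_all_singletons_undecidable(self):
        gap, present = barcoding_gap(summary_with(None, 5.0, max_intra=None))
        assert gap is None and present is None


class TestRatioRule:
    def test_benchmark_divergences_pass(self):
        # 16.5% between vs 0.68% within species: ratio ~24, over the 10x bar
        ratio, ok = ratio_rule(summary_with(0.68, 16.5))
        assert ok and ratio == pytest.approx(24.26, abs=0.01)

    def test_low_ratio_fails(self):
        # 2.28% vs 0.25%: ratio ~9.1, under the bar
        ratio, ok = ratio_rule(summary_with(0.25, 2.28))
        assert not ok and ratio == pytest.approx(9.12)

    def test_zero_intra_with_divergence_passes(self):
        ratio, ok = ratio_rule(summary_with(0.0, 5.0))
        assert ok and ratio == np.inf

    def test_both_zero_fails(self):
        _, ok = ratio_rule(summary_with(0.0, 0.0))
        assert not ok


class TestDelimit:
    def planted_cryptic(self, seed=11):
        cfg = SimulationConfig(
            n_morphospecies=1, clades_per_morphospecies=(3,),
            locus_fraction={"COI": 1.0, "16S": 1.0}, seed=seed,
        )
        ds = simulate_dataset(cfg)
        m = distance_matrix(ds.alignments["COI"])
        part = cluster_by_threshold(m, threshold=0.03, morphospecies="sp01", locus="COI")
        return part, variation_summary(part, m), ds

    def test_planted_clades_recovered_as_cryptic(self):
        part, s, ds = self.planted_cryptic()
        v = delimit(part, s)
        assert v.status is DelimitationStatus.CRYPTIC_SPECIES
        assert part.n_blocks == 3
        truth_blocks = {
            frozenset(v) for v in ds.truth.clades_in("sp01").values()
        }
        assert set(part.blocks) == truth_blocks

    def test_one_clade_is_single_species(self):
        part = partition([{"a", "b"}])
        v = delimit(part, summary_with(0.5, None, n_blocks=1))
        assert v.status is DelimitationStatus.SINGLE_SPECIES

    def test_overlap_without_reference_is_complex(self):
        # no gap, ratio ~9: an unresolved species complex
        part = partition([{"a", "b"}, {"c", "d"}])
        s = summary_with(0.25, 2.28, max_intra=2.5, min_inter=1.8)
        v = delimit(part, s)
        assert v.status is DelimitationStatus.SPECIES_COMPLEX

    def test_reference_range_rescues_low_divergence(self):
        # modest inter-clade divergence comparable to congeneric species
        part = partition([{"a", "b"}, {"c", "d"}])
        s = summary_with(0.4, 2.31, max_intra=1.0, min_inter=0.9)
        v = delimit(part, s, reference_distances=[2.0, 4.5, 7.1])
        assert v.status is DelimitationStatus.CRYPTIC_SPECIES
        assert any("reference" in n for n in v.notes)

    def test_all_singletons_undetermined(self):
        part = partition([{"a"}, {"b"}])
        v = delimit(part, summary_with(None, 5.0, max_intra=None))
        assert v.status is DelimitationStatus.UNDETERMINED

    def test_merging_clades_moves_toward_single_species(self):
        # coarsening the partition is monotone in the extremes: the
        # merged cross-pairs join the intra pool (max intra never
        # drops) and leave the inter pool (min inter never drops)
        part, s, _ = self.planted_cryptic()
        m = distance_matrix(
            simulate_dataset(
                SimulationConfig(
                    n_morphospecies=1, clades_per_morphospecies=(3,),
                    locus_fraction={"COI": 1.0, "16S": 1.0}, seed=11,
                )
            ).alignments["COI"]
        )
        blocks = sorted(part.blocks, key=min)
        merged = partition(
            [blocks[0] | blocks[1], blocks[2]],
            morph=part.morphospecies, locus="COI",
        )
        s_merged = variation_summary(merged, m)
        assert s_merged.max_intra >= s.max_intra - 1e-9
        assert s_merged.min_inter >= s.min_inter - 1e-9
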