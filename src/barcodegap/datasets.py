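"""Bundled example data: the Antarctic polychaete survey encodings.

`load_species_table` returns the packaged primary/secondary species
table for the 15-morphospecies deep-sea Antarctic polychaete survey
(sequence-free: names, MB labels, cryptic flags, origins and per-locus
sequence counts only), ready for the richness ledger.

`scenario_fixtures` reconstructs the four textbook morphospecies of that
survey as clade-label fixtures — published clade structure plus the
delimitation verdicts it implies, without distances — one per evidence
scenario:

- Scalibregma inflatum: three clades, coherent at COI and 16S (S1);
- Hesionidae sp. A: two COI clades that 16S merges (S2);
- Lumbrineris kerguelensis-cingulata: six lettered 16S clades forming an
  unresolved species complex (S3);
- Laonice weddellia: a single clade at both loci (S4).

Specimen ids are synthetic placeholders consistent with the published
per-clade sequence counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .clades import CladePartition, map_partition_across_loci
from .gap import DelimitationStatus, DelimitationVerdict
from .ledger import SpeciesRow, read_species_table

__all__ = ["load_species_table", "scenario_fixtures", "ScenarioFixture"]


def load_species_table() -> list[SpeciesRow]:
    """The packaged 15-morphospecies species table as ledger rows."""
    path = resources.files("barcodegap.data") / "antarctic_polychaetes.tsv"
    with resources.as_file(path) as p:
        return read_species_table(p)


@dataclass
class ScenarioFixture:
    morphospecies: str
    expected_scenario: str
    coi_partition: CladePartition | None
    s16_partition: CladePartition | None
    coi_verdict: DelimitationVerdict | None
    s16_verdict: DelimitationVerdict | None

    @property
    def contingency(self):
        if self.coi_partition is None or self.s16_partition is None:
            return None
        return map_partition_across_loci(self.coi_partition, self.s16_partition)


def _ids(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:02d}" for i in range(start, start + n)]


def _partition(morph: str, locus: str, blocks: list[list[str]]) -> CladePartition:
    return CladePartition(
        morphospecies=morph,
        locus=locus,
        blocks=[frozenset(b) for b in blocks],
        provenance="published clade structure",
    )


def _verdict(status: DelimitationStatus) -> DelimitationVerdict:
    return DelimitationVerdict(
        status=status, notes=["verdict taken from published clade structure"]
    )


def scenario_fixtures() -> list[ScenarioFixture]:
    S = DelimitationStatus
    fixtures: list[ScenarioFixture] = []

    # Scalibregma inflatum: 3 cryptic species, COI 6/1/3 and 16S 14/1/4
    # sequences per clade, clade membership coherent across loci.
    morph = "Scalibregma inflatum"
    c1, c2, c3 = _ids("SCA", 14), _ids("SCA", 1, 15), _ids("SCA", 4, 16)
    fixtures.append(
        ScenarioFixture(
            morphospecies=morph,
            expected_scenario="S1",
            coi_partition=_partition(morph, "COI", [c1[:6], c2, c3[:3]]),
            s16_partition=_partition(morph, "16S", [c1, c2, c3]),
            coi_verdict=_verdict(S.CRYPTIC_SPECIES),
            s16_verdict=_verdict(S.CRYPTIC_SPECIES),
        )
    )

    # Hesionidae sp. A: COI resolves 2 cryptic species (5 + 8
    # sequences); the 24 16S sequences fall in a single clade.
    morph = "Hesionidae sp. A"
    coi_a, coi_b = _ids("HES", 5), _ids("HES", 8, 6)
    s16_all = _ids("HES", 24)  # 16S covers further specimens with no COI
    fixtures.append(
        ScenarioFixture(
            morphospecies=morph,
            expected_scenario="S2",
            coi_partition=_partition(morph, "COI", [coi_a, coi_b]),
            s16_partition=_partition(morph, "16S", [s16_all]),
            coi_verdict=_verdict(S.CRYPTIC_SPECIES),
            s16_verdict=_verdict(S.SINGLE_SPECIES),
        )
    )

    # Lumbrineris kerguelensis-cingulata: 16S-only, six lettered clades
    # (5/1/5/2/1/2 sequences) that cannot be resolved into species.
    morph = "Lumbrineris kerguelensis-cingulata"
    sizes = [5, 1, 5, 2, 1, 2]
    blocks, start = [], 1
    for n in sizes:
        blocks.append(_ids("LUM", n, start))
        start += n
    fixtures.append(
        ScenarioFixture(
            morphospecies=morph,
            expected_scenario="S3",
            coi_partition=None,
            s16_partition=_partition(morph, "16S", blocks),
            coi_verdict=None,
            s16_verdict=_verdict(S.SPECIES_COMPLEX),
        )
    )

    # Laonice weddellia: one clade at both loci (7 COI, 23 16S).
    morph = "Laonice weddellia"
    lao = _ids("LAO", 23)
    fixtures.append(
        ScenarioFixture(
            morphospecies=morph,
            expected_scenario="S4",
            coi_partition=_partition(morph, "COI", [lao[:7]]),
            s16_partition=_partition(morph, "16S", [lao]),
            coi_verdict=_verdict(S.SINGLE_SPECIES),
            s16_verdict=_verdict(S.SINGLE_SPECIES),
        )
    )
    return fixtures
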