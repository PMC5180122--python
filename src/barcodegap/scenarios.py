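"""Reconciling per-locus delimitation verdicts into evidence scenarios.

Dual-locus barcode surveys of one morphospecies fall into four evidence
classes:

- S1_coherent_cryptic: every sequenced locus supports cryptic species
  and, when both loci are present, the clade partitions agree on shared
  specimens (a single-locus cryptic signal also lands here);
- S2_coi_only_cryptic: the faster COI marker resolves cryptic species
  that the slower 16S merges into one clade;
- S3_undetermined_complex: some locus reports a species complex or is
  undetermined, and no locus establishes cryptic species (conflicting
  dual-cryptic partitions are also parked here, conservatively);
- S4_no_cryptic: every locus supports a single species.

Delimited species are named with MB labels: each species gets "MB" plus
an integer unique within its morphospecies; clades inside an unresolved
species complex share one integer and are distinguished by letters
(MB1a, MB1b, ...).  A morphospecies that stays a single species keeps
the bare label "MB".  Specimens lacking the discriminating locus that
cannot be placed through the cross-locus contingency go into a bare
"MB" unassigned bucket.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from enum import Enum

from .clades import CladePartition, CrossLocusContingency, order_blocks
from .gap import DelimitationStatus, DelimitationVerdict

__all__ = ["Scenario", "MBLabel", "ScenarioResult", "classify_scenario", "assign_mb_labels"]


class Scenario(Enum):
    S1_coherent_cryptic = "S1"
    S2_coi_only_cryptic = "S2"
    S3_undetermined_complex = "S3"
    S4_no_cryptic = "S4"


@dataclass(frozen=True)
class MBLabel:
    """An MB-style species label: base integer plus optional clade letter.

    base None renders the bare "MB" used for unsplit species and
    unassigned specimens; letters appear only on species-complex clades.
    """

    base: int | None = None
    letter: str | None = None

    def __str__(self) -> str:
        if self.base is None:
            return "MB"
        return f"MB{self.base}{self.letter or ''}"


@dataclass
class ScenarioResult:
    morphospecies: str
    scenario: Scenario
    loci_used: frozenset
    species: list[tuple[str, frozenset]] = field(default_factory=list)
    unassigned: frozenset = frozenset()
    notes: list[str] = field(default_factory=list)


def classify_scenario(
    morphospecies: str,
    coi_verdict: DelimitationVerdict | None = None,
    s16_verdict: DelimitationVerdict | None = None,
    contingency: CrossLocusContingency | None = None,
) -> ScenarioResult:
    """Assign one of the four evidence scenarios from per-locus verdicts.

    With both loci present and cryptic, the shared-specimen contingency
    decides between S1 (coherent) and S3 (conflicting partitions).  A
    morphospecies sequenced at a single locus can yield S1, S3 or S4 but
    never S2.
    """
    if coi_verdict is None and s16_verdict is None:
        raise ValueError(f"{morphospecies}: no locus verdicts to classify")
    loci = frozenset(
        locus
        for locus, v in (("COI", coi_verdict), ("16S", s16_verdict))
        if v is not None
    )
    notes: list[str] = []
    S = DelimitationStatus
    statuses = {
        locus: v.status
        for locus, v in (("COI", coi_verdict), ("16S", s16_verdict))
        if v is not None
    }
    cryptic = {l for l, s in statuses.items() if s is S.CRYPTIC_SPECIES}
    single = {l for l, s in statuses.items() if s is S.SINGLE_SPECIES}

    if cryptic == set(statuses):  # every available locus cryptic
        if len(statuses) == 1:
            if "COI" in statuses:
                notes.append(
                    "cryptic signal from COI only because 16S was not sequenced"
                )
            scenario = Scenario.S1_coherent_cryptic
        elif contingency is not None and not contingency.undecidable:
            if contingency.coherent:
                scenario = Scenario.S1_coherent_cryptic
            else:
                scenario = Scenario.S3_undetermined_complex
                notes.append("both loci cryptic but partitions conflict")
        else:
            scenario = Scenario.S3_undetermined_complex
            notes.append("no shared specimens: cross-locus coherence undecidable")
    elif "COI" in cryptic:
        scenario = Scenario.S2_coi_only_cryptic
    elif "16S" in cryptic:
        # mirror of S2 never observed in dual-locus surveys; parked as S3
        scenario = Scenario.S3_undetermined_complex
        notes.append("16S cryptic while COI is not: conflicting loci")
    elif single == set(statuses):
        scenario = Scenario.S4_no_cryptic
    else:
        scenario = Scenario.S3_undetermined_complex
    return ScenarioResult(
        morphospecies=morphospecies,
        scenario=scenario,
        loci_used=loci,
        notes=notes,
    )


def assign_mb_labels(
    result: ScenarioResult,
    coi_partition: CladePartition | None = None,
    s16_partition: CladePartition | None = None,
    contingency: CrossLocusContingency | None = None,
    coi_verdict: DelimitationVerdict | None = None,
    s16_verdict: DelimitationVerdict | None = None,
) -> ScenarioResult:
    """Fill the species list of a classified morphospecies with MB labels.

    Clades are numbered deterministically (size descending, then
    lexicographically smallest specimen id).  Specimens sequenced only
    at the non-discriminating locus are mapped through the contingency
    when their block lands entirely in one discriminating clade, and put
    in the bare-"MB" unassigned bucket otherwise.
    """
    disc, other = _discriminating(
        result.scenario, coi_partition, s16_partition, coi_verdict, s16_verdict
    )
    all_specimens = frozenset()
    for p in (coi_partition, s16_partition):
        if p is not None:
            all_specimens |= p.specimens

    if result.scenario is Scenario.S4_no_cryptic or disc is None or disc.n_blocks == 1:
        result.species = [(str(MBLabel()), all_specimens)]
        result.unassigned = frozenset()
        return result

    blocks = order_blocks(disc.blocks)
    complex_mode = result.scenario is Scenario.S3_undetermined_complex
    labelled: list[tuple[str, set]] = []
    for k, block in enumerate(blocks):
        if complex_mode:
            label = MBLabel(base=1, letter=_letter(k))
        else:
            label = MBLabel(base=k + 1)
        labelled.append((str(label), set(block)))

    placed = set().union(*(m for _, m in labelled))
    unassigned = set()
    for sid in sorted(all_specimens - placed):
        target = _map_through(sid, disc, other, contingency)
        if target is not None:
            labelled[target][1].add(sid)
        else:
            unassigned.add(sid)
    result.species = [(lab, frozenset(mem)) for lab, mem in labelled]
    result.unassigned = frozenset(unassigned)
    return result


def _discriminating(
    scenario: Scenario,
    coi: CladePartition | None,
    s16: CladePartition | None,
    coi_verdict: DelimitationVerdict | None,
    s16_verdict: DelimitationVerdict | None,
) -> tuple[CladePartition | None, CladePartition | None]:
    """Choose the partition whose clades define the species labels."""
    if scenario is Scenario.S2_coi_only_cryptic:
        return coi, s16
    if scenario is Scenario.S1_coherent_cryptic:
        # coherent partitions agree on shared specimens; label from the
        # finer one so clades unsampled at one locus are not lost
        # (ties go to COI, the conventional primary barcode)
        candidates = [
            (part.n_blocks, pref, part)
            for part, pref, verdict in (
                (coi, 1, coi_verdict),
                (s16, 0, s16_verdict),
            )
            if part is not None and verdict is not None and verdict.is_cryptic
        ]
        if not candidates:
            return (coi, s16) if coi is not None else (s16, None)
        candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)
        best = candidates[0][2]
        return best, (coi if best is s16 else s16)
    if scenario is Scenario.S3_undetermined_complex:
        # prefer the locus carrying the complex/undetermined verdict,
        # falling back on the partition with more blocks
        S = DelimitationStatus
        candidates = []
        for part, verdict in ((coi, coi_verdict), (s16, s16_verdict)):
            if part is None:
                continue
            is_complex = verdict is not None and verdict.status in (
                S.SPECIES_COMPLEX,
                S.UNDETERMINED,
            )
            candidates.append((is_complex, part.n_blocks, part))
        if not candidates:
            return None, None
        candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)
        best = candidates[0][2]
        rest = coi if best is s16 else s16
        return best, rest
    return None, None


def _letter(k: int) -> str:
    """a, b, ..., z, aa, ab, ... — clades beyond 26 keep unique letters."""
    letters = string.ascii_lowercase
    out = ""
    k += 1
    while k > 0:
        k, rem = divmod(k - 1, 26)
        out = letters[rem] + out
    return out


def _map_through(
    sid: str,
    disc: CladePartition,
    other: CladePartition | None,
    contingency: CrossLocusContingency | None,
) -> int | None:
    """Place a specimen lacking the discriminating locus, if unambiguous.

    Its block at the other locus must contain shared specimens that all
    fall in a single discriminating clade.
    """
    if other is None or sid not in other.specimens:
        return None
    block = other.blocks[other.block_of(sid)]
    targets = set()
    for peer in block:
        if peer == sid or peer not in disc.specimens:
            continue
        targets.add(disc.block_of(peer))
    if len(targets) != 1:
        return None
    # map the block index to its position in the ordered labelling
    ordered = order_blocks(disc.blocks)
    return ordered.index(disc.blocks[targets.pop()])
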