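"""Before/after species accounting for a barcoding survey.

The ledger reconciles the morphology-only (primary) species list with
the secondary list produced by sequencing plus morphological
re-examination.  Every secondary species has an origin:

- retained: continues the primary identification (possibly renamed; a
  1-for-1 replacement that is itself a cryptic lineage keeps the
  morphospecies' cryptic flag but adds nothing to the counts);
- cryptic_split: an additional genetically distinct lineage within the
  morphospecies;
- morphological_reassignment: specimens moved to a different
  morphospecies during secondary examination.

A species complex (one MB integer with clade letters) counts as a
single species no matter how many lettered clades it holds.  The
reconciliation identity

    total_after = primary + cryptic_additions + reassignment_additions

holds on every tally.  The headline richness percentage is the
after/before ratio x 100 (35 species from 15 gives 233), a convention
stated in all output headers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Origin",
    "SpeciesRow",
    "SpeciesLedger",
    "tally",
    "rows_from_scenarios",
    "richness_percent",
    "cryptic_prevalence",
    "read_species_table",
]

_MB_RE = re.compile(r"^MB(?P<base>\d+)?(?P<letter>[a-z]+)?$")


class Origin(Enum):
    RETAINED = "retained"
    CRYPTIC_SPLIT = "cryptic_split"
    REASSIGNMENT = "morphological_reassignment"


class LedgerError(ValueError):
    """Inconsistent species labelling in the input table."""


@dataclass(frozen=True)
class SpeciesRow:
    """One secondary-identification row (one clade or species)."""

    primary: str
    secondary: str
    mb_label: str
    cryptic: bool
    origin: Origin
    n_coi: int = 0
    n_16s: int = 0

    def mb_parts(self) -> tuple[int | None, str | None]:
        m = _MB_RE.match(self.mb_label)
        if not m:
            raise LedgerError(f"unparseable MB label {self.mb_label!r}")
        base = m.group("base")
        return (int(base) if base else None, m.group("letter"))


@dataclass
class SpeciesLedger:
    primary_names: list[str]
    species: list[tuple[str, Origin, bool]]  # (name, origin, is_complex)
    cryptic_morphospecies: list[str]

    @property
    def primary(self) -> int:
        return len(self.primary_names)

    @property
    def total_after(self) -> int:
        return len(self.species)

    @property
    def cryptic_additions(self) -> int:
        return sum(1 for _, o, _c in self.species if o is Origin.CRYPTIC_SPLIT)

    @property
    def reassignment_additions(self) -> int:
        return sum(1 for _, o, _c in self.species if o is Origin.REASSIGNMENT)

    def reconciles(self) -> bool:
        return (
            self.total_after
            == self.primary + self.cryptic_additions + self.reassignment_additions
        )

    def summary(self) -> dict:
        count, frac = cryptic_prevalence(self)
        return {
            "primary": self.primary,
            "cryptic_additions": self.cryptic_additions,
            "reassignment_additions": self.reassignment_additions,
            "total": self.total_after,
            "richness_percent": richness_percent(self),
            "cryptic_morphospecies": count,
            "cryptic_prevalence": round(frac, 4),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"species": n, "origin": o.value, "complex": "yes" if c else "no"}
            for n, o, c in self.species
        ]
        with open(path, "w") as fh:
            fh.write("# richness_percent is the after/before ratio x 100\n")
            pd.DataFrame(
                rows, columns=["species", "origin", "complex"]
            ).to_csv(fh, sep="\t", index=False)


def tally(rows: Iterable[SpeciesRow]) -> SpeciesLedger:
    """Collapse labelled rows into the species ledger.

    Rows sharing a primary morphospecies, secondary name and MB integer
    are clades of one species (a complex) and count once.  The same MB
    integer appearing both plain and lettered within a morphospecies is
    an error.
    """
    rows = list(rows)
    primaries: list[str] = []
    by_species: dict[tuple[str, str, int | None], list[SpeciesRow]] = {}
    plain_or_lettered: dict[tuple[str, int], set[bool]] = {}
    for row in rows:
        if row.primary not in primaries:
            primaries.append(row.primary)
        base, letter = row.mb_parts()
        key = (row.primary, row.secondary, base)
        by_species.setdefault(key, []).append(row)
        if base is not None:
            plain_or_lettered.setdefault((row.primary, base), set()).add(
                letter is not None
            )
    for (primary, base), kinds in plain_or_lettered.items():
        if kinds == {True, False}:
            raise LedgerError(
                f"{primary}: MB{base} appears both plain and with clade letters"
            )
    species: list[tuple[str, Origin, bool]] = []
    cryptic_morphs: list[str] = []
    for (primary, secondary, base), members in by_species.items():
        origins = {m.origin for m in members}
        if len(origins) > 1:
            raise LedgerError(f"{secondary}: clades of one species disagree on origin")
        is_complex = any(m.mb_parts()[1] for m in members)
        label = f"MB{base}" if base is not None else "MB"
        species.append((f"{secondary} ({label})", origins.pop(), is_complex))
        if any(m.cryptic for m in members) and primary not in cryptic_morphs:
            cryptic_morphs.append(primary)
    ledger = SpeciesLedger(
        primary_names=primaries,
        species=species,
        cryptic_morphospecies=cryptic_morphs,
    )
    if not ledger.reconciles():
        raise LedgerError(
            "ledger does not reconcile: total_after != primary + additions "
            f"({ledger.total_after} != {ledger.primary} + "
            f"{ledger.cryptic_additions} + {ledger.reassignment_additions}); "
            "check that each primary morphospecies has exactly one retained row"
        )
    return ledger


def rows_from_scenarios(
    scenario_results: Sequence,
    reassignments: Iterable[SpeciesRow] = (),
) -> list[SpeciesRow]:
    """Convert pipeline ScenarioResults into ledger rows.

    The first species of each morphospecies (label order) is the
    retained lineage; the rest are cryptic splits when the scenario
    establishes cryptic species (S1/S2).  Reassignments cannot be
    derived from sequence data and enter as extra annotated rows.
    """
    out: list[SpeciesRow] = []
    for res in scenario_results:
        from .scenarios import Scenario  # local import avoids a cycle

        cryptic = res.scenario in (
            Scenario.S1_coherent_cryptic,
            Scenario.S2_coi_only_cryptic,
        )
        seen_bases: set[int | None] = set()
        for label, _members in res.species:
            m = _MB_RE.match(label)
            base = int(m.group("base")) if m and m.group("base") else None
            first_of_species = base not in seen_bases
            seen_bases.add(base)
            if not first_of_species and not m.group("letter"):
                continue
            origin = (
                Origin.RETAINED
                if len(seen_bases) == 1
                else (Origin.CRYPTIC_SPLIT if cryptic else Origin.RETAINED)
            )
            out.append(
                SpeciesRow(
                    primary=res.morphospecies,
                    secondary=res.morphospecies,
                    mb_label=label,
                    cryptic=cryptic,
                    origin=origin,
                )
            )
    out.extend(reassignments)
    return out


def richness_percent(ledger: SpeciesLedger) -> int:
    """After/before species ratio x 100, rounded to the nearest integer."""
    if ledger.primary == 0:
        raise ValueError("no primary morphospecies")
    return round(100.0 * ledger.total_after / ledger.primary)


def cryptic_prevalence(ledger: SpeciesLedger) -> tuple[int, float]:
    """(count, fraction) of primary morphospecies flagged cryptic."""
    if ledger.primary == 0:
        raise ValueError("no primary morphospecies")
    count = len(ledger.cryptic_morphospecies)
    return count, count / ledger.primary


def read_species_table(path: str | Path) -> list[SpeciesRow]:
    """Read a labelled species table (TSV) into ledger rows."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"primary", "secondary", "mb_label", "cryptic", "origin"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            SpeciesRow(
                primary=r["primary"],
                secondary=r["secondary"],
                mb_label=r["mb_label"],
                cryptic=str(r["cryptic"]).strip().lower() in ("yes", "true", "1"),
                origin=Origin(r["origin"]),
                n_coi=int(r.get("n_coi", 0) or 0),
                n_16s=int(r.get("n_16s", 0) or 0),
            )
        )
    return rows
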