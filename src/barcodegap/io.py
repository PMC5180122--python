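"""Readers and writers for the formats the pipeline touches.

Alignments come in as aligned multi-FASTA (one file per locus), specimen
metadata as CSV/TSV with columns specimen_id, morphospecies and
optionally site, trees as Newick with posterior supports on internal
nodes.  Reports go out as TSV.

FASTA header dialect: ``specimen_id|morphospecies|locus`` with ``|`` as
separator; the morphospecies and locus fields are optional when a
metadata table is supplied.  Gap character is ``-`` only (``.`` is
rejected); N and the IUPAC ambiguity codes are accepted and excluded
pairwise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOCI = ("COI", "16S")

# A/C/G/T, IUPAC ambiguity codes, N and the gap character.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Rows of unequal length, or otherwise not an alignment."""


class UnknownSpecimenError(KeyError):
    """A sequence header does not resolve to a known specimen."""


class AlphabetError(ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class TreeParseError(ValueError):
    """Malformed Newick input."""


class DuplicateLeafError(ValueError):
    """A tree contains the same leaf name more than once."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen: opaque id, morphology-based identification, site.

    loci_present records which barcode fragments were sequenced for the
    specimen and must be non-empty.
    """

    specimen_id: str
    morphospecies: str
    loci_present: frozenset = frozenset()
    site: str | None = None

    def __post_init__(self) -> None:
        if not self.loci_present:
            raise ValueError(f"specimen {self.specimen_id!r} has no loci")
        unknown = set(self.loci_present) - set(LOCI)
        if unknown:
            raise ValueError(f"unknown loci {sorted(unknown)} for {self.specimen_id!r}")


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus, upper-cased, equal length."""

    locus: str
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate specimen ids in alignment: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"rows have unequal lengths {sorted(lengths)}; input must be aligned"
            )
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - ALLOWED_CHARS
            if bad:
                raise AlphabetError(
                    f"illegal character(s) {sorted(bad)} in sequence {sid!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, specimen_id: str) -> str:
        return self.sequences[self.ids.index(specimen_id)]

    def subset(self, ids: Iterable[str]) -> "LocusAlignment":
        wanted = list(ids)
        missing = [i for i in wanted if i not in self.ids]
        if missing:
            raise UnknownSpecimenError(f"ids not in alignment: {missing}")
        return LocusAlignment(
            locus=self.locus,
            ids=wanted,
            sequences=[self.sequence(i) for i in wanted],
        )


@dataclass
class SupportTree:
    """A rooted tree over specimen ids with posterior supports in [0, 1].

    Missing supports are recorded as None, never coerced to zero.
    """

    tree: dendropy.Tree
    outgroup: frozenset = frozenset()

    def leaf_names(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def clades_with_support(self) -> list[tuple[frozenset, float | None]]:
        """(leaf set, support) for every internal node, preorder."""
        out = []
        for node in self.tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            out.append((leaves, _parse_support(node.label)))
        return out

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"node support {value} outside [0, 1]")
    return value


def read_metadata(path: str | Path) -> dict[str, SpecimenRecord]:
    """Read the specimen table (CSV or TSV, sniffed from the header line)."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"specimen_id", "morphospecies"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    records: dict[str, SpecimenRecord] = {}
    for _, row in df.iterrows():
        sid = row["specimen_id"]
        if sid in records:
            raise ValueError(f"duplicate specimen_id {sid!r} in metadata")
        loci = row.get("loci_present")
        loci_set = (
            frozenset(l for l in str(loci).split(";") if l)
            if isinstance(loci, str)
            else frozenset(LOCI)
        )
        site = row.get("site")
        records[sid] = SpecimenRecord(
            specimen_id=sid,
            morphospecies=row["morphospecies"],
            loci_present=loci_set,
            site=site if isinstance(site, str) else None,
        )
    return records


def write_metadata(records: Mapping[str, SpecimenRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "morphospecies": r.morphospecies,
            "site": r.site or "",
            "loci_present": ";".join(sorted(r.loci_present)),
        }
        for r in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fasta_alignment(
    path: str | Path,
    locus: str,
    metadata: Mapping[str, SpecimenRecord] | None = None,
) -> LocusAlignment:
    """Read an aligned multi-FASTA for one locus.

    Headers are ``specimen_id[|morphospecies[|locus]]``.  When metadata
    is given, every specimen_id must resolve to a record; a locus field
    in the header must match the requested locus.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        sid = fields[0]
        if len(fields) >= 3 and fields[2] and fields[2] != locus:
            raise AlignmentError(
                f"record {sid!r} labelled locus {fields[2]!r}, expected {locus!r}"
            )
        if metadata is not None and sid not in metadata:
            raise UnknownSpecimenError(f"specimen {sid!r} not in metadata")
        ids.append(sid)
        seqs.append(str(rec.seq).upper())
    return LocusAlignment(locus=locus, ids=ids, sequences=seqs)


def write_fasta_alignment(
    alignment: LocusAlignment,
    path: str | Path,
    metadata: Mapping[str, SpecimenRecord] | None = None,
) -> None:
    """Write the alignment back out in the package's header dialect."""
    records = []
    for sid, seq in zip(alignment.ids, alignment.sequences):
        header = sid
        if metadata is not None and sid in metadata:
            header = f"{sid}|{metadata[sid].morphospecies}|{alignment.locus}"
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(records, str(path), "fasta-2line")


def read_newick_tree(path_or_string: str | Path) -> SupportTree:
    """Parse a Newick tree with optional internal-node support labels."""
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Multiple occurrences of the same taxa" in str(exc):
            raise DuplicateLeafError(f"duplicate leaf names: {exc}") from exc
        raise TreeParseError(f"could not parse Newick input: {exc}") from exc
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DuplicateLeafError(f"duplicate leaf names: {dupes}")
    for node in tree.preorder_internal_node_iter():
        _parse_support(node.label)  # validate range early
    return SupportTree(tree=tree)


def write_report_tables(results, outdir: str | Path) -> dict[str, Path]:
    """Write the per-morphospecies species table and the K2P summary table.

    results is an iterable of MorphospeciesResult (see pipeline module)
    or anything exposing the same attributes.  Emits:

    - species_table.tsv: one row per delimited species (primary name,
      MB label, cryptic verdict, scenario, per-locus sequence counts);
    - distance_summary.tsv: mean intra- and inter-clade K2P percent per
      morphospecies per locus, with pair counts.

    Returns the paths written.  Empty input yields header-only tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_rows = []
    summary_rows = []
    for res in results:
        scenario = res.scenario_result.scenario.name if res.scenario_result else ""
        labelled = res.scenario_result.species if res.scenario_result else []
        if not labelled:
            labelled = [("MB", frozenset())]
        for label, members in labelled:
            species_rows.append(
                {
                    "primary_morphospecies": res.morphospecies,
                    "mb_label": label,
                    "cryptic": "yes" if res.cryptic else "no",
                    "scenario": scenario,
                    "n_specimens": len(members),
                    "n_COI": res.locus_counts.get("COI", 0),
                    "n_16S": res.locus_counts.get("16S", 0),
                }
            )
        for locus, summary in sorted(res.summaries.items()):
            summary_rows.append(
                {
                    "morphospecies": res.morphospecies,
                    "locus": locus,
                    "n_clades": summary.n_blocks,
                    "mean_intra_pct": _fmt(summary.mean_intra),
                    "mean_inter_pct": _fmt(summary.mean_inter),
                    "max_intra_pct": _fmt(summary.max_intra),
                    "min_inter_pct": _fmt(summary.min_inter),
                    "n_intra_pairs": summary.n_intra_pairs,
                    "n_inter_pairs": summary.n_inter_pairs,
                    "n_saturated_excluded": summary.n_saturated,
                }
            )
    species_cols = [
        "primary_morphospecies", "mb_label", "cryptic", "scenario",
        "n_specimens", "n_COI", "n_16S",
    ]
    summary_cols = [
        "morphospecies", "locus", "n_clades", "mean_intra_pct", "mean_inter_pct",
        "max_intra_pct", "min_inter_pct", "n_intra_pairs", "n_inter_pairs",
        "n_saturated_excluded",
    ]
    paths = {
        "species_table": outdir / "species_table.tsv",
        "distance_summary": outdir / "distance_summary.tsv",
    }
    pd.DataFrame(species_rows, columns=species_cols).to_csv(
        paths["species_table"], sep="\t", index=False
    )
    pd.DataFrame(summary_rows, columns=summary_cols).to_csv(
        paths["distance_summary"], sep="\t", index=False
    )
    return paths


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.2f}"
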