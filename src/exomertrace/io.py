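"""Core record types and readers/writers for the external formats the
pipeline touches.

Formats handled: FASTA proteomes, aligned FASTA, Newick species/gene trees,
TSV presence/absence matrices, BLAST 12-column tabular hit files
(outfmt-6-like) and HMMER per-target tabular files.

Conventions: the only internal gap character is ``'-'`` (``'.'`` is
normalized to ``'-'`` on read); a taxon's *genus* is the substring before
the first space or underscore; Newick branch lengths default to 1.0 when
missing; polytomies are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "SequenceRecord",
    "Alignment",
    "SearchHit",
    "PresenceAbsenceMatrix",
    "FormatError",
    "genus_of",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "read_blast_tab",
    "read_hmmer_tab",
    "read_presence_matrix",
    "write_presence_matrix",
]


class FormatError(ValueError):
    """Malformed input file; the message locates the offending record/line."""


def genus_of(taxon: str) -> str:
    """First token of a taxon label, split on space or underscore."""
    return taxon.replace("_", " ").split(" ")[0] if taxon else ""


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence with organism and family annotation.

    ``residues`` is an uppercase string over the 20 amino-acid letters plus
    X; proteome records must be gapless (aligned rows live in
    :class:`Alignment`).
    """

    id: str
    residues: str
    taxon: str = ""
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")

    @property
    def genus(self) -> str:
        return genus_of(self.taxon)

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            taxon=self.taxon,
            annotation=self.annotation,
        )


@dataclass
class Alignment:
    """Fixed-width aligned sequence rows, the substrate of distances and HMMs."""

    records: list[SequenceRecord]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("alignment needs at least one row")
        widths = {len(r.residues) for r in self.records}
        if len(widths) != 1:
            bad = [(r.id, len(r.residues)) for r in self.records]
            raise FormatError(f"ragged alignment rows: {bad}")
        self.n_columns = widths.pop()
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate row ids in alignment: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def row(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def all_gap_columns(self) -> list[int]:
        return [
            j
            for j in range(self.n_columns)
            if all(r.residues[j] == GAP for r in self.records)
        ]


@dataclass
class SearchHit:
    """A scored similarity hit between a query and a target sequence."""

    query_id: str
    target_id: str
    raw_score: float
    evalue: float
    source: str = "builtin"  # builtin | blast_tab | hmmer_tab
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for hit {self.query_id}->{self.target_id}")


def _normalize_residues(raw: str) -> str:
    return raw.upper().replace(".", GAP)


def read_fasta(path: str | Path, taxon: str = "") -> list[SequenceRecord]:
    """Read a proteome FASTA file into gapless :class:`SequenceRecord`\\ s.

    Headers of the form ``id taxon words`` keep the first token as the id and
    the remainder as the taxon unless an explicit ``taxon`` is supplied.
    Duplicate ids and gap characters are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _normalize_residues(str(rec.seq))
        if GAP in residues:
            raise FormatError(
                f"{path}: sequence {rec.id!r} contains gap characters; "
                "use read_alignment for aligned FASTA"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=residues, taxon=taxon or desc)
        )
    if not records:
        raise FormatError(f"{path}: empty or non-FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.taxon or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA; all-gap columns warn but are retained."""
    path = Path(path)
    rows: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        rows.append(
            SequenceRecord(
                id=rec.id, residues=_normalize_residues(str(rec.seq)), taxon=desc
            )
        )
    if not rows:
        raise FormatError(f"{path}: empty or non-FASTA file")
    aln = Alignment(rows)
    gap_cols = aln.all_gap_columns()
    if gap_cols:
        warnings.warn(
            f"{path}: {len(gap_cols)} all-gap column(s) retained "
            f"(first at {gap_cols[0]})",
            stacklevel=2,
        )
    return aln


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(aln.records, path)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree; missing branch lengths default to 1.0.

    ``source`` may be a path or a Newick string. A warning is emitted when
    any edge length was defaulted.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        offset = max(text.rfind("("), text.rfind(")"))
        raise FormatError(
            f"unbalanced parentheses in Newick (around character {offset})"
        )
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    defaulted = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            defaulted += 1
        elif edge.length < 0:
            raise FormatError(
                f"negative branch length {edge.length} in Newick tree"
            )
    if defaulted:
        warnings.warn(
            f"{defaulted} branch length(s) missing; defaulted to 1.0",
            stacklevel=2,
        )
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate tip labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


_BLAST_COLUMNS = [
    "query", "target", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]


def read_blast_tab(path: str | Path) -> list[SearchHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``)."""
    path = Path(path)
    hits: list[SearchHit] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise FormatError(
                f"{path}:{lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        meta = dict(zip(_BLAST_COLUMNS[2:10], fields[2:10]))
        hits.append(
            SearchHit(
                query_id=fields[0],
                target_id=fields[1],
                raw_score=bitscore,
                evalue=evalue,
                source="blast_tab",
                metadata=meta,
            )
        )
    return hits


def read_hmmer_tab(path: str | Path) -> list[SearchHit]:
    """Parse HMMER per-target tabular output (``--tblout`` dialect).

    Only the target name, query name, full-sequence E-value and bit score
    are interpreted; ``#`` comment lines are skipped.
    """
    path = Path(path)
    hits: list[SearchHit] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(
                f"{path}:{lineno}: too few whitespace-separated columns "
                f"({len(fields)}) for HMMER per-target format"
            )
        try:
            evalue = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        hits.append(
            SearchHit(
                query_id=fields[2],
                target_id=fields[0],
                raw_score=score,
                evalue=evalue,
                source="hmmer_tab",
            )
        )
    return hits


class PresenceAbsenceMatrix:
    """Taxa x components boolean table, the machine-readable dot plot.

    Thin wrapper around a boolean :class:`pandas.DataFrame` with taxa as the
    index and component names as columns.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValueError("duplicate taxa or component names")
        self.frame = frame.astype(bool)

    @classmethod
    def from_dict(
        cls, cells: dict[str, dict[str, bool]], taxa: Sequence[str] | None = None,
        components: Sequence[str] | None = None,
    ) -> "PresenceAbsenceMatrix":
        all_components = list(components) if components is not None else sorted(
            {c for row in cells.values() for c in row}
        )
        all_taxa = list(taxa) if taxa is not None else list(cells)
        full = {
            t: {c: bool(cells.get(t, {}).get(c, False)) for c in all_components}
            for t in all_taxa
        }
        frame = pd.DataFrame.from_dict(full, orient="index")
        frame = frame.reindex(all_taxa).reindex(columns=all_components)
        return cls(frame)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def components(self) -> list[str]:
        return list(self.frame.columns)

    def present(self, taxon: str, component: str) -> bool:
        return bool(self.frame.at[taxon, component])

    def column(self, component: str) -> dict[str, bool]:
        return {t: bool(v) for t, v in self.frame[component].items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return self.frame.equals(other.frame)


def write_presence_matrix(matrix: PresenceAbsenceMatrix, path: str | Path) -> None:
    out = matrix.frame.astype(int)
    out.to_csv(path, sep="\t", index_label="taxon")


def read_presence_matrix(path: str | Path) -> PresenceAbsenceMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    bad = frame.map(lambda v: v not in (0, 1, True, False))
    if bad.to_numpy().any():
        row, col = next(zip(*bad.to_numpy().nonzero()))
        raise FormatError(
            f"{path}: non-boolean cell at taxon {frame.index[row]!r}, "
            f"component {frame.columns[col]!r}"
        )
    return PresenceAbsenceMatrix(frame.astype(bool))
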