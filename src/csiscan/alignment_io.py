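"""Aligned-FASTA and taxon-partition I/O plus shared coordinate utilities.

The substrate of every analysis stage is a rectangular protein multiple
sequence alignment (MSA): each row is a gapped amino-acid sequence of
identical length.  Rows are identified by their FASTA ID; the remainder of
the FASTA description line is kept as a free-text taxon label used only for
reporting.  A taxon partition splits the row IDs into an in-group (the clade
whose exclusive signatures are sought) and an out-group (the reference taxa
that establish exclusivity).

Coordinates: alignment columns are 0-based half-open internally; every
user-facing report converts to 1-based inclusive positions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: characters accepted in input and rewritten to the canonical gap
GAP_DIALECTS = ".*"

_VALID = frozenset(AMINO_ACIDS + UNKNOWN + GAP)


class AlignmentError(ValueError):
    """Raised on malformed alignments or partitions."""


@dataclasses.dataclass(frozen=True)
class Row:
    seq_id: str
    taxon_label: str
    residues: str


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A validated rectangular protein MSA."""

    rows: tuple[Row, ...]
    n_cols: int

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("alignment needs at least 2 rows")
        seen: set[str] = set()
        for row in self.rows:
            if row.seq_id in seen:
                raise AlignmentError(f"duplicate sequence ID {row.seq_id!r}")
            seen.add(row.seq_id)
            if len(row.residues) != self.n_cols:
                raise AlignmentError(
                    f"row {row.seq_id!r} has {len(row.residues)} columns, "
                    f"expected {self.n_cols}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        """Build from (seq_id, residues) pairs; labels default to empty."""
        rows = tuple(Row(i, "", normalize_residues(s, i)) for i, s in pairs)
        if not rows:
            raise AlignmentError("empty alignment")
        return cls(rows=rows, n_cols=len(rows[0].residues))

    @property
    def seq_ids(self) -> tuple[str, ...]:
        return tuple(r.seq_id for r in self.rows)

    def row(self, seq_id: str) -> Row:
        for r in self.rows:
            if r.seq_id == seq_id:
                return r
        raise AlignmentError(f"unknown sequence ID {seq_id!r}")

    def __contains__(self, seq_id: str) -> bool:
        return any(r.seq_id == seq_id for r in self.rows)

    def subset(self, seq_ids: Sequence[str]) -> "Alignment":
        wanted = set(seq_ids)
        rows = tuple(r for r in self.rows if r.seq_id in wanted)
        return Alignment(rows=rows, n_cols=self.n_cols)


@dataclasses.dataclass(frozen=True)
class TaxonPartition:
    """Disjoint in-group / out-group ID sets, plus IDs that were assigned
    but absent from the alignment (tolerated: mirrors species lacking the
    homolog; specificity is assessed over members that carry it)."""

    ingroup: frozenset[str]
    outgroup: frozenset[str]
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ingroup or not self.outgroup:
            raise AlignmentError("both in-group and out-group must be non-empty")
        overlap = self.ingroup & self.outgroup
        if overlap:
            raise AlignmentError(
                f"IDs assigned to both groups: {sorted(overlap)}"
            )

    @property
    def member_ids(self) -> frozenset[str]:
        return self.ingroup | self.outgroup

    def swapped(self) -> "TaxonPartition":
        return TaxonPartition(self.outgroup, self.ingroup, self.missing)


@dataclasses.dataclass(frozen=True)
class ColumnSpan:
    """Half-open 0-based alignment column interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AlignmentError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_residues(seq: str, seq_id: str = "?") -> str:
    """Uppercase, map gap dialects ('.', '*') to '-', validate alphabet."""
    out = []
    for pos, ch in enumerate(seq.upper()):
        if ch in GAP_DIALECTS:
            ch = GAP
        if ch not in _VALID:
            raise AlignmentError(
                f"row {seq_id!r}: invalid character {ch!r} at position {pos + 1}"
            )
        out.append(ch)
    return "".join(out)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned protein FASTA file.

    All records must have equal length after gap-dialect normalization.
    The FASTA description after the ID becomes the taxon label.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    rows = []
    for rec in records:
        label = rec.description[len(rec.id):].strip() if rec.description else ""
        rows.append(Row(rec.id, label, normalize_residues(str(rec.seq), rec.id)))
    n_cols = len(rows[0].residues)
    for row in rows:
        if len(row.residues) != n_cols:
            raise AlignmentError(
                f"{path}: ragged row {row.seq_id!r} "
                f"({len(row.residues)} columns, expected {n_cols})"
            )
    return Alignment(rows=tuple(rows), n_cols=n_cols)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.residues), id=r.seq_id, description=r.taxon_label)
        for r in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_partition(path: str | Path, alignment: Alignment) -> TaxonPartition:
    """Read a two-column TSV (seq_id <TAB> ingroup|outgroup).

    IDs absent from the alignment are collected into ``missing`` rather than
    rejected; an ID assigned to both groups is an error.
    """
    ingroup: set[str] = set()
    outgroup: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 'seq_id<TAB>group', got {line!r}"
                )
            seq_id, group = parts
            if group == "ingroup":
                ingroup.add(seq_id)
            elif group == "outgroup":
                outgroup.add(seq_id)
            else:
                raise AlignmentError(
                    f"{path}:{lineno}: group must be 'ingroup' or 'outgroup', "
                    f"got {group!r}"
                )
    return partition_from_sets(ingroup, outgroup, alignment)


def partition_from_sets(
    ingroup: Iterable[str], outgroup: Iterable[str], alignment: Alignment
) -> TaxonPartition:
    """Validate ID sets against an alignment, tolerating absent IDs."""
    ingroup, outgroup = set(ingroup), set(outgroup)
    overlap = ingroup & outgroup
    if overlap:
        raise AlignmentError(f"IDs assigned to both groups: {sorted(overlap)}")
    present = set(alignment.seq_ids)
    missing = (ingroup | outgroup) - present
    return TaxonPartition(
        ingroup=frozenset(ingroup & present),
        outgroup=frozenset(outgroup & present),
        missing=frozenset(missing),
    )


def write_partition(partition: TaxonPartition, path: str | Path) -> None:
    with open(path, "w") as handle:
        for seq_id in sorted(partition.ingroup):
            handle.write(f"{seq_id}\tingroup\n")
        for seq_id in sorted(partition.outgroup):
            handle.write(f"{seq_id}\toutgroup\n")


def ungapped_index(alignment: Alignment, seq_id: str, column: int) -> int:
    """1-based count of non-gap residues of ``seq_id`` in columns [0, column].

    If the column itself holds a gap the count up to the nearest preceding
    residue is returned (0 if the prefix is all gaps).  This maps alignment
    columns onto residue positions of a reference sequence for reporting.
    """
    row = alignment.row(seq_id)
    if not 0 <= column < alignment.n_cols:
        raise AlignmentError(f"column {column} out of range [0, {alignment.n_cols})")
    return sum(1 for ch in row.residues[: column + 1] if ch != GAP)


def complete_deletion_length(alignment: Alignment) -> int:
    """Number of columns containing no gap in any row.

    This is the "complete deletion" convention of phylogenetics software:
    the length of the alignment that survives discarding every column with
    at least one gap.
    """
    return sum(
        1
        for c in range(alignment.n_cols)
        if all(r.residues[c] != GAP for r in alignment.rows)
    )
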