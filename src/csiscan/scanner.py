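"""Conserved signature indel (CSI) detection.

A CSI is an insertion or deletion in a protein alignment that is present in
(essentially) every member of a taxonomic in-group and absent outside it,
and that sits inside conserved flanking sequence — evidence that the gap
pattern reflects a real, reliably positioned genetic event rather than an
alignment artifact.  The scan proceeds in four stages:

1. ``conservation_profile`` — score every column for conservation across
   all partition rows (majority residue share >= ``conservation_fraction``).
2. ``find_indel_candidates`` — find maximal runs of columns whose gap
   pattern discriminates in-group from out-group (insert: in-group carries
   residues, out-group gapped; deletion: mirrored).
3. ``score_flanks`` — count conserved columns within a window of
   ``flank_window_aa`` reference residues on each side of the candidate;
   candidates with fewer than ``min_flank_conserved`` conserved positions on
   either side are rejected and never reported.
4. ``classify_specificity`` — a call is ``exclusive`` when no out-group row
   shows any trace of the indel, else ``shared_with_exceptions`` with the
   violating out-group rows enumerated.

``scan_csi`` composes the stages into the full procedure.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Literal

from .alignment_io import (
    GAP,
    UNKNOWN,
    Alignment,
    AlignmentError,
    ColumnSpan,
    TaxonPartition,
    ungapped_index,
)

IndelType = Literal["insert", "deletion"]
Specificity = Literal["exclusive", "shared_with_exceptions"]


@dataclasses.dataclass(frozen=True)
class ScanConfig:
    """All scan thresholds.

    flank_window_aa
        Residues of the reference sequence on each side of a candidate
        within which conserved positions are counted (default 40).
    min_flank_conserved
        Minimum conserved columns required on each side (default 5).
    conservation_fraction
        Minimum share of all partition rows carrying a column's majority
        residue for the column to count as conserved (default 0.8; 1.0
        demands strict identity).  Gaps and 'X' count in the denominator
        but never as matches.
    ingroup_presence_fraction
        Share of in-group rows that must carry residues in an insert
        region (default 1.0, i.e. "exclusively found"; relax to admit
        candidates that are only "mainly" discriminating).
    outgroup_absence_fraction
        Share of out-group rows that must be fully gapped in an insert
        region (default 1.0).  Both fractions apply with the groups'
        roles mirrored for deletions.
    merge_gap_cols
        Maximum number of non-discriminating columns bridged when merging
        adjacent candidate runs of the same type (default 0).
    """

    flank_window_aa: int = 40
    min_flank_conserved: int = 5
    conservation_fraction: float = 0.8
    ingroup_presence_fraction: float = 1.0
    outgroup_absence_fraction: float = 1.0
    merge_gap_cols: int = 0

    def __post_init__(self) -> None:
        if self.min_flank_conserved > self.flank_window_aa:
            raise ValueError("min_flank_conserved must be <= flank_window_aa")
        for name in (
            "conservation_fraction",
            "ingroup_presence_fraction",
            "outgroup_absence_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.merge_gap_cols < 0 or self.flank_window_aa < 0:
            raise ValueError("window sizes must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class ColumnConservation:
    majority_residue: str | None
    majority_fraction: float
    is_conserved: bool


@dataclasses.dataclass(frozen=True)
class ConservationProfile:
    columns: tuple[ColumnConservation, ...]

    def __getitem__(self, column: int) -> ColumnConservation:
        return self.columns[column]

    def __len__(self) -> int:
        return len(self.columns)


@dataclasses.dataclass(frozen=True)
class IndelCandidate:
    span: ColumnSpan
    type: IndelType
    per_row_lengths: dict[str, int]  # seq_id -> non-gap residues within span


@dataclasses.dataclass(frozen=True)
class CSICall:
    candidate: IndelCandidate
    ingroup_length_min: int
    ingroup_length_max: int
    left_flank_conserved: int
    right_flank_conserved: int
    specificity: Specificity
    exception_ids: tuple[str, ...]
    reference_id: str
    reference_position: int  # 1-based ungapped residue preceding the span

    @property
    def span(self) -> ColumnSpan:
        return self.candidate.span

    @property
    def type(self) -> IndelType:
        return self.candidate.type


def conservation_profile(
    alignment: Alignment, partition: TaxonPartition, config: ScanConfig
) -> ConservationProfile:
    """Per-column majority-residue conservation over all partition rows.

    Rows outside the partition are ignored.  A column is conserved when its
    most frequent residue (gaps and unknown 'X' never qualify) is carried
    by at least ``conservation_fraction`` of the partition rows.
    """
    rows = [r for r in alignment.rows if r.seq_id in partition.member_ids]
    n = len(rows)
    columns = []
    for c in range(alignment.n_cols):
        counts = Counter(r.residues[c] for r in rows)
        counts.pop(GAP, None)
        counts.pop(UNKNOWN, None)
        if counts:
            # deterministic tie-break: highest count, then alphabetical
            residue, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            fraction = count / n
        else:
            residue, fraction = None, 0.0
        columns.append(
            ColumnConservation(
                majority_residue=residue,
                majority_fraction=fraction,
                is_conserved=fraction >= config.conservation_fraction
                and residue is not None,
            )
        )
    return ConservationProfile(columns=tuple(columns))


def _column_type(
    alignment: Alignment,
    partition: TaxonPartition,
    config: ScanConfig,
    column: int,
) -> IndelType | None:
    """Classify a column as insert-discriminating, deletion-discriminating,
    or neither.

    A column belongs to an insert region when at least
    ``outgroup_absence_fraction`` of out-group rows are gapped and at least
    one in-group row carries a residue (the material of the insert, even
    where length variation leaves some in-group rows gapped); deletion is
    the exact mirror.  Under strict default fractions the two predicates
    are mutually exclusive; with relaxed fractions a column satisfying both
    is assigned to the side whose presence dominates, or to neither on a
    tie.
    """
    in_rows = [r for r in alignment.rows if r.seq_id in partition.ingroup]
    out_rows = [r for r in alignment.rows if r.seq_id in partition.outgroup]
    in_present = sum(1 for r in in_rows if r.residues[column] != GAP) / len(in_rows)
    out_present = sum(1 for r in out_rows if r.residues[column] != GAP) / len(out_rows)
    is_insert = (1.0 - out_present) >= config.outgroup_absence_fraction and in_present > 0
    is_deletion = (1.0 - in_present) >= config.outgroup_absence_fraction and out_present > 0
    if is_insert and is_deletion:
        if in_present > out_present:
            return "insert"
        if out_present > in_present:
            return "deletion"
        return None
    if is_insert:
        return "insert"
    if is_deletion:
        return "deletion"
    return None


def _residues_in_span(row_residues: str, span: ColumnSpan) -> int:
    return sum(1 for ch in row_residues[span.start : span.end] if ch != GAP)


def _region_presence_ok(
    alignment: Alignment,
    partition: TaxonPartition,
    config: ScanConfig,
    span: ColumnSpan,
    indel_type: IndelType,
) -> bool:
    """Region-level presence test: the fraction of carrier-group rows
    (in-group for inserts, out-group for deletions) holding at least one
    residue inside the span must reach ``ingroup_presence_fraction``.
    Rows fully gapped within the region count toward absence."""
    carrier = partition.ingroup if indel_type == "insert" else partition.outgroup
    rows = [r for r in alignment.rows if r.seq_id in carrier]
    present = sum(1 for r in rows if _residues_in_span(r.residues, span) > 0)
    return present / len(rows) >= config.ingroup_presence_fraction


def find_indel_candidates(
    alignment: Alignment, partition: TaxonPartition, config: ScanConfig
) -> list[IndelCandidate]:
    """Maximal runs of partition-discriminating columns.

    Column-level test: an insert column has at least
    ``outgroup_absence_fraction`` of out-group rows gapped and some
    in-group material; deletion columns are the mirror.  Runs of the same
    type separated by at most ``merge_gap_cols`` non-discriminating
    columns are merged.  Region-level test: at least
    ``ingroup_presence_fraction`` of the carrier group's rows must hold
    residues somewhere in the run, so that length-variable indels (e.g. a
    43-or-44 aa insert) are kept as one region while a stray single-row
    insertion is rejected.  Candidates are sorted by span start.
    """
    types = [
        _column_type(alignment, partition, config, c)
        for c in range(alignment.n_cols)
    ]
    # collect maximal same-type runs
    runs: list[tuple[int, int, IndelType]] = []
    c = 0
    while c < alignment.n_cols:
        t = types[c]
        if t is None:
            c += 1
            continue
        start = c
        while c < alignment.n_cols and types[c] == t:
            c += 1
        runs.append((start, c, t))
    # bridge short non-discriminating gaps between same-type runs
    merged: list[tuple[int, int, IndelType]] = []
    for run in runs:
        if (
            merged
            and merged[-1][2] == run[2]
            and run[0] - merged[-1][1] <= config.merge_gap_cols
        ):
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(run)
    candidates = []
    member_rows = [r for r in alignment.rows if r.seq_id in partition.member_ids]
    for start, end, t in merged:
        span = ColumnSpan(start, end)
        if not _region_presence_ok(alignment, partition, config, span, t):
            continue
        per_row = {
            r.seq_id: _residues_in_span(r.residues, span) for r in member_rows
        }
        candidates.append(IndelCandidate(span=span, type=t, per_row_lengths=per_row))
    return candidates


def _flank_window_columns(
    alignment: Alignment,
    span: ColumnSpan,
    reference_id: str,
    window_aa: int,
    side: Literal["left", "right"],
) -> list[int]:
    """Columns forming one flank window: walking outward from the span,
    the columns where the reference row carries a residue, up to
    ``window_aa`` such residues (truncated at the alignment edge).
    Columns where the reference is gapped do not occupy window slots."""
    ref = alignment.row(reference_id).residues
    columns = []
    if side == "left":
        rng = range(span.start - 1, -1, -1)
    else:
        rng = range(span.end, alignment.n_cols)
    for c in rng:
        if len(columns) >= window_aa:
            break
        if ref[c] != GAP:
            columns.append(c)
    return columns


def score_flanks(
    alignment: Alignment,
    candidate: IndelCandidate,
    profile: ConservationProfile,
    config: ScanConfig,
    reference_id: str,
) -> tuple[int, int]:
    """Count conserved columns in the left and right flank windows.

    The window is measured in reference-sequence residues, not raw
    alignment columns, so the neighborhood matches what a reader counts on
    the reference protein.  At an alignment edge the window is truncated
    and the count can only shrink.
    """
    if reference_id not in alignment:
        raise AlignmentError(f"reference {reference_id!r} not in alignment")
    counts = []
    for side in ("left", "right"):
        cols = _flank_window_columns(
            alignment, candidate.span, reference_id, config.flank_window_aa, side
        )
        counts.append(sum(1 for c in cols if profile[c].is_conserved))
    return counts[0], counts[1]


def classify_specificity(
    alignment: Alignment,
    candidate: IndelCandidate,
    partition: TaxonPartition,
    config: ScanConfig,
) -> tuple[Specificity, tuple[str, ...]]:
    """Exclusive vs shared-with-exceptions.

    For an insert, any out-group row carrying at least one residue inside
    the span is an exception; for a deletion, any out-group row with at
    least one gap inside the span (i.e. sharing part of the deletion).
    Exceptions are always enumerated, never silently admitted.
    """
    span = candidate.span
    exceptions = []
    for row in alignment.rows:
        if row.seq_id not in partition.outgroup:
            continue
        n_res = _residues_in_span(row.residues, span)
        if candidate.type == "insert" and n_res > 0:
            exceptions.append(row.seq_id)
        elif candidate.type == "deletion" and n_res < len(span):
            exceptions.append(row.seq_id)
    exceptions.sort()
    if exceptions:
        return "shared_with_exceptions", tuple(exceptions)
    return "exclusive", ()


def scan_csi(
    alignment: Alignment,
    partition: TaxonPartition,
    config: ScanConfig | None = None,
    reference_id: str | None = None,
) -> list[CSICall]:
    """Full CSI scan: profile -> candidates -> flank filter -> classify.

    Candidates failing the flank filter (fewer than ``min_flank_conserved``
    conserved columns on either side) are dropped, mirroring the practice
    of not pursuing indels that lack conserved neighborhoods.  Zero calls
    is a normal outcome.  Output is ordered by span start.
    """
    config = config or ScanConfig()
    if reference_id is None:
        reference_id = default_reference(alignment, partition)
    if reference_id not in alignment:
        raise AlignmentError(f"reference {reference_id!r} not in alignment")
    profile = conservation_profile(alignment, partition, config)
    calls = []
    for candidate in find_indel_candidates(alignment, partition, config):
        left, right = score_flanks(alignment, candidate, profile, config, reference_id)
        if left < config.min_flank_conserved or right < config.min_flank_conserved:
            continue
        specificity, exceptions = classify_specificity(
            alignment, candidate, partition, config
        )
        in_lengths = [
            n
            for seq_id, n in candidate.per_row_lengths.items()
            if seq_id in partition.ingroup
        ]
        ref_pos = (
            ungapped_index(alignment, reference_id, candidate.span.start - 1)
            if candidate.span.start > 0
            else 0
        )
        calls.append(
            CSICall(
                candidate=candidate,
                ingroup_length_min=min(in_lengths),
                ingroup_length_max=max(in_lengths),
                left_flank_conserved=left,
                right_flank_conserved=right,
                specificity=specificity,
                exception_ids=exceptions,
                reference_id=reference_id,
                reference_position=ref_pos,
            )
        )
    calls.sort(key=lambda call: call.span.start)
    return calls


def default_reference(alignment: Alignment, partition: TaxonPartition) -> str:
    """First in-group row in alignment order (the figure-style top line)."""
    for row in alignment.rows:
        if row.seq_id in partition.ingroup:
            return row.seq_id
    raise AlignmentError("no in-group row present in the alignment")
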