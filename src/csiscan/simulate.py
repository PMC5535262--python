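"""Seeded synthetic protein MSAs with planted clade-specific indels.

The generator emulates the statistical structure of the alignments a CSI
study works from: a core protein of a few hundred residues, a dozen or so
in-group homologs and a comparable out-group panel, substitution divergence
between rows, and one or more in-group-specific insertions or deletions
embedded in conserved flanking sequence.  Each planted indel may designate
out-group "exception" rows that share it, emulating signatures that are
"mainly" rather than exclusively clade-specific.

The model is deliberately simple: a uniform-random ancestor copied to every
row, i.i.d. uniform substitutions per row outside frozen flanks, and indel
blocks realized directly from the plan.  There is no phylogeny-aware
evolution and no empirical substitution matrix; the scanner under test is
conservation-threshold-based, so matrix realism adds nothing to what the
fixtures can show.

Every run is a pure function of the spec (which includes the seed): the
same spec yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .alignment_io import (
    AMINO_ACIDS,
    GAP,
    Alignment,
    ColumnSpan,
    Row,
    TaxonPartition,
)
from .scanner import (
    CSICall,
    ScanConfig,
    _flank_window_columns,
    conservation_profile,
)


class SpecError(ValueError):
    """Raised on an invalid synthetic-alignment specification."""


@dataclasses.dataclass(frozen=True)
class PlantedIndel:
    """One planned indel.

    position
        1-based ancestor residue index.  An insert is placed immediately
        after this residue; a deletion removes ancestor residues
        ``[position, position + length)`` from the in-group.
    length_aa
        Integer, or a ``(min, max)`` per-row range (inserts only) from
        which each in-group row's realized length is drawn.
    exception_outgroup_rows
        Number of out-group rows sharing the full-length indel.
    """

    position: int
    length_aa: int | tuple[int, int]
    type: Literal["insert", "deletion"]
    exception_outgroup_rows: int = 0

    @property
    def length_range(self) -> tuple[int, int]:
        if isinstance(self.length_aa, int):
            return (self.length_aa, self.length_aa)
        return self.length_aa


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Study-scale defaults: 12 in-group and 10 out-group homologs of a
    600 aa core with moderate substitution divergence and 40 aa frozen
    flanks around every planted indel."""

    seed: int
    n_ingroup: int = 12
    n_outgroup: int = 10
    core_length_aa: int = 600
    substitution_rate: float = 0.15
    planted_indels: tuple[PlantedIndel, ...] = ()
    frozen_flank_aa: int = 40

    def __post_init__(self) -> None:
        if self.n_ingroup < 1 or self.n_outgroup < 1:
            raise SpecError("both groups need at least one row")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SpecError("substitution_rate must be in [0, 1)")
        footprints: list[tuple[int, int]] = []
        for indel in self.planted_indels:
            lo, hi = indel.length_range
            if lo < 1 or lo > hi:
                raise SpecError(f"invalid length range ({lo}, {hi})")
            if indel.type == "deletion" and lo != hi:
                raise SpecError("per-row length ranges are supported for inserts only")
            if lo != hi and self.n_ingroup < 2:
                raise SpecError("a length range needs at least 2 in-group rows")
            if indel.exception_outgroup_rows > self.n_outgroup:
                raise SpecError("more exception rows than out-group rows")
            f = self.frozen_flank_aa
            if indel.type == "insert":
                start, end = indel.position - f + 1, indel.position + f
            else:
                start, end = indel.position - f, indel.position + hi - 1 + f
            if start < 1 or end > self.core_length_aa:
                raise SpecError(
                    f"indel at {indel.position} with flanks exceeds the core"
                )
            footprints.append((start, end))
        footprints.sort()
        for (_, e1), (s2, _) in zip(footprints, footprints[1:]):
            if s2 <= e1:
                raise SpecError("planted indels overlap (frozen flanks included)")


@dataclasses.dataclass(frozen=True)
class TruthEntry:
    """Realized ground truth for one planted indel."""

    span: ColumnSpan
    type: Literal["insert", "deletion"]
    ingroup_length_min: int
    ingroup_length_max: int
    per_row_lengths: dict[str, int]
    specificity: Literal["exclusive", "shared_with_exceptions"]
    exception_ids: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    entries: tuple[TruthEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


_AA = np.array(list(AMINO_ACIDS))


def _substituted_copy(
    ancestor: np.ndarray, frozen: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-row copy with i.i.d. substitutions outside frozen positions.

    Replacement residues are drawn uniformly from the 19 alternatives.
    """
    row = ancestor.copy()
    if rate == 0.0:
        return row
    hit = (rng.random(len(ancestor)) < rate) & ~frozen
    for i in np.flatnonzero(hit):
        choices = _AA[_AA != row[i]]
        row[i] = rng.choice(choices)
    return row


def simulate_msa(
    spec: SyntheticSpec,
) -> tuple[Alignment, TaxonPartition, SyntheticTruth]:
    """Realize a synthetic alignment, its partition, and its ground truth.

    In-group rows are named ``in01..``, out-group rows ``out01..``.  For a
    length-range insert the first two in-group rows are pinned to the range
    endpoints so the realized range always equals the planned one; the
    remaining rows draw uniformly.  Exception rows carry the full-length
    indel.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.core_length_aa
    ancestor = rng.choice(_AA, size=L)

    in_ids = [f"in{i + 1:02d}" for i in range(spec.n_ingroup)]
    out_ids = [f"out{i + 1:02d}" for i in range(spec.n_outgroup)]

    # ancestor positions exempt from substitution (1-based -> 0-based mask)
    frozen = np.zeros(L, dtype=bool)
    for indel in spec.planted_indels:
        lo, hi = indel.length_range
        f = spec.frozen_flank_aa
        if indel.type == "insert":
            frozen[indel.position - f : indel.position + f] = True
        else:
            frozen[indel.position - f - 1 : indel.position + hi - 1 + f] = True

    base_rows = {
        seq_id: _substituted_copy(ancestor, frozen, spec.substitution_rate, rng)
        for seq_id in in_ids + out_ids
    }

    indels = sorted(spec.planted_indels, key=lambda x: x.position)
    plans = []
    for indel in indels:
        lo, hi = indel.length_range
        exceptions = sorted(
            str(x)
            for x in rng.choice(out_ids, size=indel.exception_outgroup_rows, replace=False)
        )
        if indel.type == "insert":
            lengths = {}
            for k, seq_id in enumerate(in_ids):
                if lo == hi:
                    lengths[seq_id] = lo
                elif k == 0:
                    lengths[seq_id] = lo
                elif k == 1:
                    lengths[seq_id] = hi
                else:
                    lengths[seq_id] = int(rng.integers(lo, hi + 1))
            for seq_id in exceptions:
                lengths[seq_id] = hi
            width = max(lengths.values())
            block = rng.choice(_AA, size=width)
        else:
            lengths, width, block = {}, hi, None
        plans.append((indel, exceptions, lengths, width, block))

    # assemble columns ancestor-position by ancestor-position, splicing
    # insert blocks and gapping deletion regions as they are reached
    all_ids = in_ids + out_ids
    columns: dict[str, list[str]] = {seq_id: [] for seq_id in all_ids}
    spans: list[ColumnSpan] = [None] * len(plans)  # type: ignore[list-item]
    deletion_of: dict[int, int] = {}  # ancestor pos (1-based) -> plan index
    insert_after: dict[int, int] = {}
    for idx, (indel, *_rest) in enumerate(plans):
        if indel.type == "deletion":
            lo, _ = indel.length_range
            for p in range(indel.position, indel.position + lo):
                deletion_of[p] = idx
        else:
            insert_after[indel.position] = idx

    col = 0
    for p in range(1, L + 1):
        didx = deletion_of.get(p)
        for seq_id in all_ids:
            if didx is not None:
                indel, exceptions, *_ = plans[didx]
                carrier_gap = seq_id in in_ids or seq_id in exceptions
                columns[seq_id].append(GAP if carrier_gap else base_rows[seq_id][p - 1])
            else:
                columns[seq_id].append(base_rows[seq_id][p - 1])
        if didx is not None:
            indel, *_ = plans[didx]
            if p == indel.position:  # first deleted column opens the span
                lo, _ = indel.length_range
                spans[didx] = ColumnSpan(col, col + lo)
        col += 1
        iidx = insert_after.get(p)
        if iidx is not None:
            indel, exceptions, lengths, width, block = plans[iidx]
            for seq_id in all_ids:
                n = lengths.get(seq_id, 0)
                for j in range(width):
                    columns[seq_id].append(block[j] if j < n else GAP)
            spans[iidx] = ColumnSpan(col, col + width)
            col += width

    rows = tuple(
        Row(
            seq_id,
            f"synthetic {'ingroup' if seq_id in in_ids else 'outgroup'} taxon",
            "".join(columns[seq_id]),
        )
        for seq_id in all_ids
    )
    alignment = Alignment(rows=rows, n_cols=col)
    partition = TaxonPartition(frozenset(in_ids), frozenset(out_ids))

    entries = []
    for idx, (indel, exceptions, lengths, width, _block) in enumerate(plans):
        span = spans[idx]
        if indel.type == "insert":
            in_lengths = [lengths[s] for s in in_ids]
            per_row = {s: lengths.get(s, 0) for s in all_ids}
        else:
            in_lengths = [0]
            per_row = {
                s: 0 if (s in in_ids or s in exceptions) else len(span)
                for s in all_ids
            }
        entries.append(
            TruthEntry(
                span=span,
                type=indel.type,
                ingroup_length_min=min(in_lengths),
                ingroup_length_max=max(in_lengths),
                per_row_lengths=per_row,
                specificity="exclusive" if not exceptions else "shared_with_exceptions",
                exception_ids=tuple(exceptions),
            )
        )
    return alignment, partition, SyntheticTruth(entries=tuple(entries))


def _default_partition(
    alignment: Alignment, partition: TaxonPartition | None
) -> TaxonPartition:
    if partition is not None:
        return partition
    row_ids = list(alignment.seq_ids)
    half = max(1, len(row_ids) // 2)
    return TaxonPartition(frozenset(row_ids[:half]), frozenset(row_ids[half:]))


def _column_conserved(
    matrix: dict[str, list[str]], member_ids: list[str], c: int, fraction: float
) -> bool:
    counts: dict[str, int] = {}
    for seq_id in member_ids:
        ch = matrix[seq_id][c]
        if ch != GAP and ch != "X":
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return False
    return max(counts.values()) / len(member_ids) >= fraction


def _deconserve_column(
    matrix: dict[str, list[str]],
    member_ids: list[str],
    c: int,
    fraction: float,
    rng: np.random.Generator,
) -> None:
    """Substitute majority-carrying rows until the column's majority
    fraction falls below the conservation threshold."""
    budget = 2 * len(member_ids)
    while _column_conserved(matrix, member_ids, c, fraction):
        budget -= 1
        if budget < 0:
            raise SpecError(
                f"cannot de-conserve column {c} at threshold {fraction}"
            )
        residues = {s: matrix[s][c] for s in member_ids if matrix[s][c] != GAP}
        counts: dict[str, int] = {}
        for ch in residues.values():
            counts[ch] = counts.get(ch, 0) + 1
        majority = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        carriers = sorted(s for s, ch in residues.items() if ch == majority)
        victim = carriers[int(rng.integers(len(carriers)))]
        # replace with the currently rarest residue so no new majority
        # can form while we knock this one down
        rare = min(AMINO_ACIDS, key=lambda a: (counts.get(a, 0), a))
        matrix[victim][c] = rare


def degrade_flanks(
    alignment: Alignment,
    truth: SyntheticTruth,
    side: Literal["left", "right"],
    target_conserved: int,
    config: ScanConfig,
    seed: int,
    partition: TaxonPartition | None = None,
    reference_id: str | None = None,
) -> Alignment:
    """Substitute flank residues until exactly ``target_conserved`` columns
    in the chosen flank window of every planted indel satisfy the
    conservation predicate.

    The window is the same reference-residue window the scanner uses, so a
    fixture degraded to k conserved columns exercises the flank filter at
    exactly k.  Deterministic under ``seed``; raises if the target exceeds
    the current conserved count.
    """
    rng = np.random.default_rng(seed)
    partition = _default_partition(alignment, partition)
    if reference_id is None:
        reference_id = next(r for r in alignment.seq_ids if r in partition.ingroup)
    matrix = {r.seq_id: list(r.residues) for r in alignment.rows}
    member_ids = [r.seq_id for r in alignment.rows if r.seq_id in partition.member_ids]
    fraction = config.conservation_fraction

    for entry in truth:
        window = _flank_window_columns(
            alignment, entry.span, reference_id, config.flank_window_aa, side
        )
        conserved = [
            c for c in window if _column_conserved(matrix, member_ids, c, fraction)
        ]
        if target_conserved > len(conserved):
            raise SpecError(
                f"target {target_conserved} exceeds current conserved "
                f"count {len(conserved)} in the {side} window"
            )
        excess = len(conserved) - target_conserved
        if excess == 0:
            continue
        chosen = rng.choice(np.array(conserved), size=excess, replace=False)
        for c in sorted(int(x) for x in chosen):
            _deconserve_column(matrix, member_ids, c, fraction, rng)

    rows = tuple(
        Row(r.seq_id, r.taxon_label, "".join(matrix[r.seq_id]))
        for r in alignment.rows
    )
    return Alignment(rows=rows, n_cols=alignment.n_cols)


def sculpt_flank_conservation(
    alignment: Alignment,
    truth: SyntheticTruth,
    side: Literal["left", "right"],
    keep_distances: set[int],
    extent_aa: int,
    config: ScanConfig,
    seed: int,
    partition: TaxonPartition | None = None,
    reference_id: str | None = None,
) -> Alignment:
    """Place conserved flank columns at exact reference-residue distances.

    Within the first ``extent_aa`` reference residues outward from each
    planted indel on the chosen side, every column whose distance (1-based,
    nearest first) is *not* in ``keep_distances`` is substituted below the
    conservation threshold; kept columns are untouched.  This builds
    boundary fixtures such as "the 5th conserved residue sits exactly at
    window position 40".
    """
    rng = np.random.default_rng(seed)
    partition = _default_partition(alignment, partition)
    if reference_id is None:
        reference_id = next(r for r in alignment.seq_ids if r in partition.ingroup)
    if keep_distances - set(range(1, extent_aa + 1)):
        raise SpecError("keep_distances must lie within [1, extent_aa]")
    matrix = {r.seq_id: list(r.residues) for r in alignment.rows}
    member_ids = [r.seq_id for r in alignment.rows if r.seq_id in partition.member_ids]
    fraction = config.conservation_fraction

    for entry in truth:
        window = _flank_window_columns(
            alignment, entry.span, reference_id, extent_aa, side
        )
        for distance, c in enumerate(window, start=1):
            if distance in keep_distances:
                continue
            _deconserve_column(matrix, member_ids, c, fraction, rng)

    rows = tuple(
        Row(r.seq_id, r.taxon_label, "".join(matrix[r.seq_id]))
        for r in alignment.rows
    )
    return Alignment(rows=rows, n_cols=alignment.n_cols)


def evaluate_recovery(
    truth: SyntheticTruth, calls: list[CSICall]
) -> tuple[float, float, list[tuple[int, CSICall]]]:
    """Score scanner output against planted ground truth.

    A call matches a truth entry iff their spans are identical and their
    types agree.  Precision is matched calls over total calls (1.0 when
    there are no calls); recall is matched truth entries over total truth
    (1.0 when the truth is empty).
    """
    matches: list[tuple[int, CSICall]] = []
    matched_truth: set[int] = set()
    matched_calls = 0
    for call in calls:
        for i, entry in enumerate(truth):
            if i in matched_truth:
                continue
            if entry.span == call.span and entry.type == call.type:
                matches.append((i, call))
                matched_truth.add(i)
                matched_calls += 1
                break
    precision = matched_calls / len(calls) if calls else 1.0
    recall = len(matched_truth) / len(truth) if len(truth) else 1.0
    return precision, recall, matches
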