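"""Independent brute-force CSI scanner used as a test oracle.

Enumerates every column interval of a (tiny) alignment and tests the call
predicate directly — column-level gap-pattern discrimination, maximality,
region-level carrier presence, flank conservation, specificity — without
sharing any code with the production scanner.  Only ``merge_gap_cols = 0``
semantics are implemented.
"""

from collections import Counter

from csiscan.alignment_io import GAP, UNKNOWN, Alignment, TaxonPartition
from csiscan.scanner import ScanConfig

CallTuple = tuple  # (start, end, type, len_min, len_max, left, right, spec, exceptions, ref_pos)


def brute_force_calls(
    alignment: Alignment,
    partition: TaxonPartition,
    config: ScanConfig,
    reference_id: str,
) -> list[CallTuple]:
    assert config.merge_gap_cols == 0
    rows = {r.seq_id: r.residues for r in alignment.rows}
    in_ids = sorted(partition.ingroup & set(rows))
    out_ids = sorted(partition.outgroup & set(rows))
    member_ids = in_ids + out_ids
    n = alignment.n_cols
    ref = rows[reference_id]

    def col_type(c: int) -> str | None:
        in_pres = sum(rows[s][c] != GAP for s in in_ids) / len(in_ids)
        out_pres = sum(rows[s][c] != GAP for s in out_ids) / len(out_ids)
        ins = (1.0 - out_pres) >= config.outgroup_absence_fraction and in_pres > 0
        dele = (1.0 - in_pres) >= config.outgroup_absence_fraction and out_pres > 0
        if ins and dele:
            if in_pres > out_pres:
                return "insert"
            if out_pres > in_pres:
                return "deletion"
            return None
        if ins:
            return "insert"
        if dele:
            return "deletion"
        return None

    def conserved(c: int) -> bool:
        counts = Counter(rows[s][c] for s in member_ids)
        counts.pop(GAP, None)
        counts.pop(UNKNOWN, None)
        if not counts:
            return False
        return max(counts.values()) / len(member_ids) >= config.conservation_fraction

    def flank_count(start: int, end: int, step: int) -> int:
        edge = start - 1 if step < 0 else end
        seen = count = 0
        c = edge
        while 0 <= c < n and seen < config.flank_window_aa:
            if ref[c] != GAP:
                seen += 1
                if conserved(c):
                    count += 1
            c += step
        return count

    def span_res(seq_id: str, start: int, end: int) -> int:
        return sum(rows[seq_id][c] != GAP for c in range(start, end))

    calls = []
    for start in range(n):
        t = col_type(start)
        if t is None:
            continue
        for end in range(start + 1, n + 1):
            if any(col_type(c) != t for c in range(start, end)):
                continue
            left_ok = start == 0 or col_type(start - 1) != t
            right_ok = end == n or col_type(end) != t
            if not (left_ok and right_ok):
                continue
            carriers = in_ids if t == "insert" else out_ids
            present = sum(span_res(s, start, end) > 0 for s in carriers)
            if present / len(carriers) < config.ingroup_presence_fraction:
                continue
            left = flank_count(start, end, -1)
            right = flank_count(start, end, +1)
            if left < config.min_flank_conserved or right < config.min_flank_conserved:
                continue
            if t == "insert":
                exceptions = tuple(
                    s for s in out_ids if span_res(s, start, end) > 0
                )
            else:
                exceptions = tuple(
                    s for s in out_ids if span_res(s, start, end) < end - start
                )
            in_lengths = [span_res(s, start, end) for s in in_ids]
            ref_pos = sum(ref[c] != GAP for c in range(start))
            calls.append(
                (
                    start,
                    end,
                    t,
                    min(in_lengths),
                    max(in_lengths),
                    left,
                    right,
                    "shared_with_exceptions" if exceptions else "exclusive",
                    exceptions,
                    ref_pos,
                )
            )
    calls.sort(key=lambda x: x[0])
    return calls


def call_as_tuple(call) -> CallTuple:
    """Project a production CSICall onto the oracle's tuple form."""
    return (
        call.span.start,
        call.span.end,
        call.type,
        call.ingroup_length_min,
        call.ingroup_length_max,
        call.left_flank_conserved,
        call.right_flank_conserved,
        call.specificity,
        call.exception_ids,
        call.reference_position,
    )
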