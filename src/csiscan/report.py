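"""Publication-style signature rendering and machine-readable call export.

Signature alignments follow the figure convention used for conserved
signature indels: the top sequence is printed verbatim, every other row
shows a dash wherever its residue is identical to the top line and its own
residue where it differs, and the indel block is highlighted.  Because '-'
is reserved for identity, gaps in non-top rows are displayed with a
distinct character (default '␣') so the rendering stays information
preserving: the original windowed sub-alignment can be reconstructed
exactly from the render plus the top row.
"""

from __future__ import annotations

import dataclasses
import io
import json

from .alignment_io import GAP, Alignment, AlignmentError, ColumnSpan, ungapped_index
from .scanner import CSICall

IDENTITY_CHAR = "-"
DEFAULT_GAP_DISPLAY = "␣"  # ␣ OPEN BOX

TSV_COLUMNS = [
    "reference_id",
    "reference_position",
    "type",
    "span_start",
    "span_end",
    "length_min",
    "length_max",
    "left_flank_conserved",
    "right_flank_conserved",
    "specificity",
    "exception_ids",
]


@dataclasses.dataclass(frozen=True)
class SignatureRender:
    header: str
    rows: tuple[tuple[str, str, str], ...]  # (seq_id, label, rendered string)
    highlight: ColumnSpan  # relative to the rendered window
    flank_context_aa: int
    window: ColumnSpan  # absolute alignment columns rendered
    gap_display: str = DEFAULT_GAP_DISPLAY


def _window_around(
    alignment: Alignment, span: ColumnSpan, top_id: str, context_aa: int
) -> ColumnSpan:
    """Extend the span by ``context_aa`` reference residues on each side."""
    ref = alignment.row(top_id).residues
    start, seen = span.start, 0
    for c in range(span.start - 1, -1, -1):
        if seen >= context_aa:
            break
        if ref[c] != GAP:
            seen += 1
        start = c
    end, seen = span.end, 0
    for c in range(span.end, alignment.n_cols):
        if seen >= context_aa:
            break
        if ref[c] != GAP:
            seen += 1
        end = c + 1
    return ColumnSpan(start, end)


def render_signature(
    alignment: Alignment,
    call: CSICall,
    top_id: str | None = None,
    flank_context_aa: int = 40,
    gap_display: str = DEFAULT_GAP_DISPLAY,
) -> SignatureRender:
    """Render one CSI call as a partial alignment window.

    The window covers the call span plus ``flank_context_aa`` reference
    residues of context on each side (default 40, matching the scan window
    so the flank-filter evidence is visible).
    """
    top_id = top_id if top_id is not None else call.reference_id
    if top_id not in alignment:
        raise AlignmentError(f"top row {top_id!r} not in alignment")
    if gap_display == IDENTITY_CHAR:
        raise ValueError("gap display character may not collide with the identity dash")
    window = _window_around(alignment, call.span, top_id, flank_context_aa)
    top = alignment.row(top_id)
    rendered: list[tuple[str, str, str]] = [
        (top.seq_id, top.taxon_label, top.residues[window.start : window.end])
    ]
    for row in alignment.rows:
        if row.seq_id == top_id:
            continue
        chars = []
        for c in range(window.start, window.end):
            ch = row.residues[c]
            if ch == GAP:
                chars.append(gap_display)
            elif ch == top.residues[c]:
                chars.append(IDENTITY_CHAR)
            else:
                chars.append(ch)
        rendered.append((row.seq_id, row.taxon_label, "".join(chars)))
    first = ungapped_index(alignment, top_id, window.start)
    last = ungapped_index(alignment, top_id, window.end - 1)
    header = (
        f"{top.seq_id} residues {max(first, 1)}-{max(last, 1)}; "
        f"{call.type} of {call.ingroup_length_min}"
        + (
            f"-{call.ingroup_length_max}"
            if call.ingroup_length_max != call.ingroup_length_min
            else ""
        )
        + " aa"
    )
    return SignatureRender(
        header=header,
        rows=tuple(rendered),
        highlight=ColumnSpan(call.span.start - window.start, call.span.end - window.start),
        flank_context_aa=flank_context_aa,
        window=window,
        gap_display=gap_display,
    )


def reconstruct_window(render: SignatureRender) -> list[tuple[str, str]]:
    """Invert a render back to the windowed sub-alignment (id, residues)."""
    top_id, _, top_seq = render.rows[0]
    out = [(top_id, top_seq)]
    for seq_id, _, rendered in render.rows[1:]:
        chars = []
        for ch, top_ch in zip(rendered, top_seq):
            if ch == render.gap_display:
                chars.append(GAP)
            elif ch == IDENTITY_CHAR:
                chars.append(top_ch)
            else:
                chars.append(ch)
        out.append((seq_id, "".join(chars)))
    return out


def call_to_dict(call: CSICall) -> dict:
    """Full per-row detail, JSON-ready, with deterministic key order."""
    return {
        "reference_id": call.reference_id,
        "reference_position": call.reference_position,
        "type": call.type,
        "span": {"start": call.span.start, "end": call.span.end},
        "length_min": call.ingroup_length_min,
        "length_max": call.ingroup_length_max,
        "left_flank_conserved": call.left_flank_conserved,
        "right_flank_conserved": call.right_flank_conserved,
        "specificity": call.specificity,
        "exception_ids": list(call.exception_ids),
        "per_row_lengths": {
            k: call.candidate.per_row_lengths[k]
            for k in sorted(call.candidate.per_row_lengths)
        },
    }


def _call_to_tsv_row(call: CSICall) -> list[str]:
    return [
        call.reference_id,
        str(call.reference_position),
        call.type,
        str(call.span.start + 1),  # 1-based inclusive for reports
        str(call.span.end),
        str(call.ingroup_length_min),
        str(call.ingroup_length_max),
        str(call.left_flank_conserved),
        str(call.right_flank_conserved),
        call.specificity,
        ";".join(call.exception_ids),
    ]


def export_calls(
    calls: list[CSICall],
    format: str,
    alignment: Alignment | None = None,
    flank_context_aa: int = 40,
) -> str:
    """Serialize calls deterministically as ``tsv``, ``json`` or ``text``.

    The text format embeds a signature render per call and therefore
    requires the source alignment.
    """
    if format == "tsv":
        buf = io.StringIO()
        buf.write("\t".join(TSV_COLUMNS) + "\n")
        for call in calls:
            buf.write("\t".join(_call_to_tsv_row(call)) + "\n")
        return buf.getvalue()
    if format == "json":
        return json.dumps([call_to_dict(c) for c in calls], indent=2, sort_keys=True) + "\n"
    if format == "text":
        if alignment is None:
            raise ValueError("text export requires the alignment")
        blocks = []
        for i, call in enumerate(calls, start=1):
            render = render_signature(alignment, call, flank_context_aa=flank_context_aa)
            width = max(len(f"{sid} {lbl}".strip()) for sid, lbl, _ in render.rows)
            lines = [f"## CSI {i}: {render.header}"]
            marker = (
                " " * (width + 2 + render.highlight.start)
                + "=" * len(render.highlight)
            )
            lines.append(marker)
            for sid, lbl, seq in render.rows:
                name = f"{sid} {lbl}".strip()
                lines.append(f"{name:<{width}}  {seq}")
            blocks.append("\n".join(lines))
        return ("\n\n".join(blocks) + "\n") if blocks else "# no CSI calls\n"
    raise ValueError(f"unknown export format {format!r}")
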