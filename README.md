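# csiscan

Conserved signature indel (CSI) discovery in protein multiple sequence
alignments.

## The problem

A CSI is an insertion or deletion in a protein that is shared by all members
of a taxonomic group and absent (or nearly absent) from everything outside
it, and that sits inside conserved flanking sequence. Because such indels
are rare, vertically inherited genetic events introduced in a common
ancestor, they make highly specific molecular markers for a clade and often
point at group-specific functional features — the canonical example being
the multiple bifidobacteria-specific indels in the class Ib (NrdE) and
class III (NrdD) ribonucleotide reductase subunits, including a large
43–44 aa insert at the class III allosteric regulatory site.

`csiscan` is for comparative genomicists who have a pre-aligned protein
family and an in-group/out-group hypothesis and want the indel scanning,
flank-conservation filtering, specificity classification, and
publication-style signature rendering done reproducibly instead of by eye.

## The method

Given an alignment `A` with rows split into an in-group `I` and an
out-group `O`, the scan is:

1. **Conservation profile.** A column is *conserved* when its majority
   residue is carried by at least a fraction `c` (default 0.8) of all
   partition rows; gaps and `X` count in the denominator, never as matches.
2. **Candidate indel regions.** A column belongs to an *insert* region when
   at least a fraction `q` (default 1.0) of out-group rows are gapped and
   some in-group row carries a residue; *deletion* regions are the exact
   mirror. Maximal runs of same-type columns form candidates, kept only if
   at least a fraction `p` (default 1.0) of the carrier group's rows hold
   residues somewhere in the region — so a 43-or-44 aa length-variable
   insert stays one region while a single-row insertion is discarded.
3. **Flank filter.** On each side of a candidate, conserved columns are
   counted within a window of `w = 40` reference-sequence residues; a
   candidate with fewer than `m = 5` conserved columns on either side is
   rejected and never reported.
4. **Specificity.** A surviving call is `exclusive` when no out-group row
   shows any trace of the indel, otherwise `shared_with_exceptions` with
   every violating out-group row enumerated — exceptions never pass
   silently.

Calls report the indel type, the in-group length range (supporting
"43 or 44 aa" style variation), per-side flank-conservation counts, and the
1-based position on a reference sequence. A seeded simulator generates
study-scale alignments with planted indels and ground truth, so every stage
is testable end to end without external data.

## Worked example

Simulate a class III RNR-like alignment (12 in-group / 10 out-group rows,
600 aa core, 15% substitution divergence) with a planted 4 aa insert and a
planted 43-or-44 aa insert, then scan it:

```sh
$ csiscan simulate --spec spec.yaml --seed 5 --out-prefix rnr
wrote rnr.fasta (+.partition.tsv, .truth.json)

$ csiscan scan --alignment rnr.fasta --partition rnr.partition.tsv --out-dir out
INFO scan complete: 2 candidates, 0 rejected by flanks, 2 calls
2 CSI call(s) (0 candidate(s) rejected by flank filter); results in out
```

with `spec.yaml`:

```yaml
n_ingroup: 12
n_outgroup: 10
core_length_aa: 600
substitution_rate: 0.15
planted_indels:
  - {position: 200, length_aa: 4, type: insert}
  - {position: 430, length_aa: [43, 44], type: insert}
```

`out/calls.tsv` then contains (1-based alignment columns):

```text
reference_id  reference_position  type    span_start  span_end  length_min  length_max  left_flank_conserved  right_flank_conserved  specificity  exception_ids
in01          200                 insert  201         204       4           4           40                    40                     exclusive
in01          434                 insert  435         478       43          44          40                    40                     exclusive
```

Both planted inserts are recovered exactly: a 4 aa insert after reference
residue 200 and a 43–44 aa insert after residue 434 (the reference carries
the first insert, shifting its coordinate by 4), each exclusive to the
in-group and flanked by 40 conserved residues per side — comfortably past
the ≥ 5 filter. `out/report.txt` renders each call in the signature-figure
convention: top row verbatim, dashes for identity with the top line, `␣`
for alignment gaps, the indel block marked:

```text
## CSI 1: in01 residues 161-244; insert of 4 aa
                                             ====
in01 synthetic ingroup taxon    IRLTWKKNPLPYRHKKEA...
in02 synthetic ingroup taxon    ------------------...
```

`csiscan render --format html` wraps the same content with the highlight as
a styled span, and `csiscan validate` checks inputs without scanning.

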