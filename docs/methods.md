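# Methods

## Scope and model

`csiscan` detects conserved signature indels (CSIs): insertions or
deletions in a protein multiple sequence alignment that discriminate a
taxonomic in-group from an out-group panel and sit inside conserved
flanking sequence. The package assumes the alignment is given (it never
realigns), that rows are correctly assigned to groups by the user, and
that the out-group panel the user supplies is representative — specificity
is always assessed against exactly the rows provided, so widening the
out-group (e.g. with additional database homologs) is the user's
responsibility. There is no statistical significance model for a CSI; the
method is a deterministic filter cascade, and its output is evidence to be
read, not a p-value.

Partition IDs absent from the alignment are tolerated and reported rather
than rejected: real in-groups contain species that simply lack the homolog,
and a signature is defined over the members that carry it.

## Scan parameters

| parameter | default | meaning |
|---|---|---|
| `conservation_fraction` | 0.8 | minimum share of all partition rows carrying a column's majority residue for the column to count as conserved; 1.0 demands strict identity |
| `flank_window_aa` | 40 | reference-sequence residues examined on each side of a candidate |
| `min_flank_conserved` | 5 | conserved columns required on each side (inclusive boundary) |
| `ingroup_presence_fraction` | 1.0 | share of carrier-group rows that must hold residues somewhere in a candidate region |
| `outgroup_absence_fraction` | 1.0 | per-column share of the non-carrier group that must be gapped |
| `merge_gap_cols` | 0 | non-discriminating columns bridged between same-type runs |

"Conserved" has no universal definition in the signature-indel literature;
published signature figures show near-identity flanks, so the operational
choice here is a configurable majority-share threshold with 0.8 as a
permissive default and 1.0 available for strict identity. Gaps and the
unknown residue `X` stay in the denominator and never match, which is the
conservative direction: missing data weakens, never strengthens, a
conservation claim. Conservation is computed over *all* partition rows
(in-group and out-group together), again the conservative choice among the
plausible readings (in-group only would be laxer); it is not separately
configurable.

The flank window is measured in reference-sequence residues, not raw
alignment columns, because that is how a reader counts a "neighboring
40 aa" on a protein; columns where the reference is gapped are skipped
entirely and consume no window slot. The window is taken per side, matching
the idea of being flanked *on both sides*, and truncates at alignment
edges (a candidate at the edge can therefore never pass a positive
`min_flank_conserved`).

Strict default fractions (1.0/1.0) implement "exclusively found".
Relaxing them admits "mainly found" signatures; every out-group row that
violates the strict pattern is then enumerated as an exception — for an
insert, any out-group row with at least one residue in the span; for a
deletion, any out-group row with at least one gap there. Exceptions are
never silently absorbed into a pass.

## Candidate semantics

Column-level test: an insert column has at least
`outgroup_absence_fraction` of out-group rows gapped *and* at least one
in-group residue; deletions are the exact mirror, which makes the
insert/deletion duality under partition swap hold by construction. A
column that satisfies both relaxed predicates at once is assigned to the
side with the higher presence fraction, and to neither on an exact tie —
a deterministic resolution of a degenerate case that cannot arise under
strict defaults.

Region-level test: after maximal same-type runs are formed (bridging up to
`merge_gap_cols` non-discriminating columns), a run survives only if the
carrier group's *region* presence reaches `ingroup_presence_fraction` —
the fraction of carrier rows holding at least one residue anywhere in the
run. The presence requirement is deliberately region-level rather than
per-column: a length-variable indel (some rows inserting 43 residues,
others 44) leaves its ragged final column below any per-column presence
threshold, yet it is one biological event and is reported as one call with
an in-group length range (43, 44). Conversely a stray single-row insertion
has region presence 1/|I| and is discarded. Rows fully gapped within a
region count toward absence.

In-group length ranges are reported as (min, max) over in-group rows
rather than rejecting length variation. For deletion calls the in-group
length is 0 by definition; the size of the deleted block is the span
width.

Overlapping candidates cannot arise: runs are maximal and typed. Output
order is by span start; zero calls is a normal outcome. Internally all
columns are 0-based half-open; every user-facing report is 1-based
inclusive, and the reference coordinate given for a call is the 1-based
ungapped reference residue immediately preceding the span (0 when the span
opens the alignment).

## Rendering

Signature alignments follow the figure convention: top row verbatim, `-`
in other rows for identity with the top line, the row's own residue where
it differs. Since `-` is reserved for identity, gaps display as `␣`
(configurable to `.`); overloading `-` for both identity and gaps would
make the rendering non-invertible. With distinct characters the windowed
sub-alignment is exactly reconstructible from the render plus the top row,
and the suite asserts that round trip. Default rendering context is 40
reference residues per side so the evidence behind the flank filter is
visible in the report.

## The synthetic generator

`simulate_msa` emulates the statistical structure of the alignments CSI
surveys are run on: a uniform-random ancestor of `core_length_aa` (default
600 aa, protein-scale), copied to `n_ingroup` = 12 and `n_outgroup` = 10
rows, per-row i.i.d. substitutions at `substitution_rate` = 0.15 (moderate
inter-order divergence; uniform over the 19 alternative residues), and
planted indels realized as shared blocks — present in all in-group rows,
absent from out-group rows except designated exception rows, which carry
the full-length indel. A 40 aa frozen flank on each side of every planted
indel is exempt from substitution, guaranteeing fully conserved
neighborhoods before any deliberate degradation. Planted indels must not
overlap, frozen flanks included.

Per-row length ranges are supported for inserts; the first two in-group
rows are pinned to the range endpoints so the realized range always equals
the planned one, and the remaining rows draw uniformly. Deletions take a
single integer length (the deletions such surveys report are short —
1–4 aa — and a ragged deletion is not a construct the scanner's output
distinguishes from a ragged insert under partition swap).

Two fixture-shaping tools build boundary cases. `degrade_flanks`
substitutes randomly chosen flank residues until *exactly* a target number
of window columns remain conserved (victims are majority carriers;
replacements are the currently rarest residue, so no new majority can
form). `sculpt_flank_conservation` instead de-conserves every window
column except a stated set of reference-residue distances, building
fixtures like "the 5th conserved residue sits exactly at window position
40 / 41". Both are deterministic under their seed. `evaluate_recovery`
scores calls against truth (match = identical span and type; precision is
1.0 on an empty call set, recall 1.0 on empty truth).

What the generator does *not* emulate, and what passing tests therefore do
not show: tree-structured evolution (no phylogeny, no rate heterogeneity,
no empirical substitution matrix), alignment-program artifacts (every gap
is a planted event, never a misalignment), indel birth–death processes, or
compositional bias. In real alignments the main failure modes are
alignment ambiguity around indels and flank divergence — the simulator
models the latter (via degradation) but not the former. Perfect recovery
on synthetic fixtures demonstrates the scanner's logic, not robustness to
aligner error.

Substitution noise never creates or removes gaps, so on simulated data
candidate discovery is exact by construction and recovery exercises the
flank and specificity stages; the brute-force oracle comparison on random
gapped alignments covers the candidate-finding logic itself. The
monotonicity of call count when `outgroup_absence_fraction` is lowered is
likewise a fixture-level property: in pathological alignments, lowering
the threshold can fuse two runs across a separating column and reduce the
*count* while enlarging the called territory; planted-indel fixtures
cannot produce this because frozen-flank columns contain no gaps at all.

## Numerical and degenerate-input choices

Majority residues tie-break alphabetically (deterministic profiles).
All-gap columns have no majority and are never conserved. Alignments need
at least two rows; partitions need both groups non-empty; duplicate row
IDs, ragged rows, and non-amino-acid characters are validation errors
naming the offender, while `.` and `*` are accepted as gap dialects and
normalized to `-`. The pipeline consumes no randomness, so repeated runs
over identical inputs are byte-identical (asserted down to the serialized
artifacts); only the simulator takes seeds.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
100 random tiny alignments (≤ 8 rows × ≤ 12 columns) for the oracle
comparison, 100 study-scale simulations (22 rows, ~650-column alignments,
four planted indels each) for recovery, an 11-point flank-count sweep, and
two boundary fixtures for the window default — a few seconds end to end on
one core.

## Known limitations

Besides the generator's idealizations listed above: no database-wide
specificity search (the out-group panel *is* the universe the scan sees);
no handling of paralog mixtures or recombination; flank conservation is a
count of independently conserved columns, blind to order and spacing
within the window; and the scanner treats every row independently, so
duplicated strains of one species weight the fractions accordingly.
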