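# Methods

## Model and procedure

The caller treats a splice junction as a pure coordinate object: a pair
(left_end, right_start) on one chromosome whose intervening sequence is
absent from a transcript. No splice-site motif is consulted anywhere — the
method is deliberately signature-free so that non-canonical and
minor-spliceosome junctions are detectable on the same footing as canonical
ones. Evidence comes exclusively from reads that fail contiguous alignment:

1. **Initial alignment.** Reads with at least one full-length exact match on
   either genome strand are set aside (they are used later only as the RPKM
   denominator/numerator substrate). Only unmapped reads continue. A
   mismatch-tolerant initial phase can be delegated to any SAM-producing
   external aligner through an adapter; the built-in engine is exact-match
   only, which is the correct semantics for the split phase and a
   conservative stand-in for the initial phase on error-free data.
2. **Splitting.** Each unmapped read of length L is cut at every position
   p ∈ [m, L−m]; m defaults to the read-length rule (15 nt below 75 nt, 30 nt
   at or above) and may be overridden. Reads with L < 2m are counted and
   skipped. Parts are streamed, never materialized wholesale: the part count
   is 2(L−2m+1) per read and grows quadratically in file size if written out.
3. **Part alignment.** Full-length exact matching over both strands via a
   k-mer position index (k = the smallest min-split size in use, so every
   queried part is at least k long; shorter queries fall back to a direct
   scan). A part with more than `max_alignments` total matches is suppressed
   entirely — reported-hit semantics mirror a best-k alignment run with
   alignment suppression above the cap. Parts containing N never match.
4. **Matched pairs.** For each (read, p), every combination of a reported
   left-part hit and right-part hit on the same chromosome and strand, in
   genomic order, with gap in [min_d, max_d] and both intervals inside one
   gene span, is one pair. On the minus strand the read's left part lies
   genomically right of its right part, so the interval roles flip. Gene
   scope is the union of transcript spans per gene name; with overlapping
   genes the smallest containing span wins (tie: lexicographic), preferring
   the most specific assignment.
5. **Support clustering.** Pairs support each other when both boundaries
   agree within the buffer (default 5 nt, boundary-inclusive). Candidates
   are built greedily: the most frequent exact junction among unassigned
   pairs anchors a candidate and absorbs all unassigned pairs within the
   buffer; ties prefer smaller coordinates. Anchoring rather than
   transitive chaining is deliberate: chaining under a ±5 nt relation could
   merge genuinely distinct junctions ~10 nt apart, whereas the buffer's
   purpose is only to absorb alignment wobble caused by repeated sequence
   around the splice. The implementation sweeps exact-junction keys sorted
   by (left_end, right_start) with a bisected window per anchor and a
   lazy-deletion max-heap for anchor selection; a quadratic reference
   implementation built from the full pairwise support matrix is kept for
   oracle testing.
6. **Rescue.** A read whose short side was suppressed for multi-mapping
   produces no pair, but its longer side is still informative. For each
   such read (no pairs anywhere, long side's length ≥ the suppressed
   side's), the long side's inner boundary is compared against candidate
   boundaries on the same chromosome and strand; within the buffer, the
   nearest candidate (tie: leftmost) gains one rescue read. One read
   rescues at most one candidate, and rescue only tops up existing
   candidates — it can never seed one, since candidates are born from pairs.
7. **Calling.** Candidates with ≥ `supp` distinct supporting *reads*
   (members counted once per read, plus rescues) become calls. Counting
   reads rather than (read, split) pairs matters: one read split at several
   positions can generate near-identical pairs and would otherwise fabricate
   support. The excised sequence [left_end, right_start) is extracted from
   the genome; novelty is assigned by annotated-intron lookup.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_d` / `max_d` | 2 / 50,000 nt | admissible excision lengths; gaps of 0–1 nt are contiguous genome and would have mapped in phase 1 |
| `supp` | 2 | minimum distinct supporting reads per reported junction |
| `buffer` | 5 nt | boundary agreement tolerance for support, rescue and run comparison |
| `max_alignments` | 2 | suppression cap for multi-mapping parts; raising it trades runtime for sensitivity |
| `min_split_size` | auto (15/30) | smallest part length; lowering it increases sensitivity and part count |
| `known_tolerance` | 0 nt | boundary tolerance for calling a junction "known" against the annotation |

## Coordinate conventions

Internal coordinates are 0-based half-open everywhere (refFlat's native
convention); the junction table prints 1-based inclusive boundaries
(left boundary = last exonic base on the left, right boundary = first
exonic base on the right), the single conversion in the system. EST input
is accepted as GTF (1-based inclusive, as table-browser exports deliver) or
BED (0-based half-open) and normalized on read.

## Evaluation machinery

- **EST validation** is monotone in its buffer and uses two independent
  existence tests (some EST end near the left boundary, some EST start near
  the right); specificity ratios with empty denominators are reported as
  absent, never 0.
- **Sensitivity** counts a call as a detected known junction of a gene when
  it matches one of the gene's annotated junctions (union over isoforms)
  within the tolerance; genes with zero detected junctions are excluded from
  the denominator entirely, making the metric a lower bound restricted to
  expressed, detected genes. The stored per-call novelty label is not
  consulted, since it may have been assigned under a different tolerance.
- **RPKM** uses the exonic-union length of a gene and assigns a read to a
  gene when its initial-phase alignment start lies in that union — the
  conventional RPKM reading, since neither choice is dictated by the metric
  itself. Bins are lower-inclusive: [0,5), [5,10), [10,50), [50,100),
  [100,∞); the value 100 belongs to the top bin.
- **Group comparison** is a frequency screen, not a statistical test:
  junction keys are unified exactly, per-group frequencies are sample
  fractions, and the difference threshold is strict (>0.5 for "over 50%").

## Signature search

Donor queries are 25 nt (last 10 exonic + first 15 intronic), acceptor
queries 46 nt (last 40 intronic + first 6 exonic), branch queries run from
10 nt upstream of the branch base through the intron's 3'-terminal base —
all read 5'→3' of the transcript, with minus-strand introns
reverse-complemented. Branch queries exist only for U12-type introns.
Intron records whose context overruns the chromosome are skipped with a
warning rather than truncated.

The search engine seeds on an exact shared 7-mer and scores with affine-gap
local alignment where a gap of length g costs `gap_open + g·gap_extend`
(2 + 2g at the defaults, with mismatch −1 — the stated penalties are
subtracted, the only sensible reading). E-values use E = K·m·n·e^(−λS);
for the two-valued ±1 score, λ has a closed form (the log of the larger
root of p·x² − x + q = 0, p = match probability under the subject
composition) and K the lattice closed form (q−p)²/q — ln 3 and 1/3 for
uniform composition. Degenerate compositions (match probability ≥ ½) fall
back to the uniform parameters. E-value parity with other BLAST
implementations is explicitly not promised; scores are exact local-alignment
optima (verified against exhaustive dynamic programming in tests), and
downstream decisions use scores and the hit/no-hit outcome at the chosen
threshold.

## Synthetic data: what it does and does not emulate

The generator produces a uniform-random genome with non-overlapping genes
(defaults: ten 3-exon genes, 400 nt exons, 600 nt introns), plants novel
junctions inside gene spans, and emits strand-specific, error-free 50 nt
reads: per planted junction, a configurable number of spanning reads whose
flank offsets are uniform among those leaving ≥ min_split on both sides,
plus exon-interior contiguous reads as the expression substrate. Planted
junctions are guaranteed recoverable by construction: both min_split-length
flanks are verified unique genome-wide (both strands, exhaustive scan,
re-drawn on collision), so the boundary-exact split of every spanning read
aligns uniquely. ESTs are generated exactly at truth boundaries, so any
validation buffer ≥ 0 validates every true call.

Reads default to the forward strand (a strand-specific library) because
support clustering is per-strand: unstranded simulation would split a
junction's planted support across two strand-separated candidates and make
stated support counts nondeterministic. A `reverse_fraction` knob exists
for exercising strand handling. The error knob defaults to 0 because the
split-phase aligner is exact; it exists for external-adapter runs.

Consequences for interpretation: passing tests demonstrate the inference
machinery is correct under its own assumptions (exact alignment, unique
flanks, adequate support). They do not demonstrate robustness to sequencing
error, biased coverage, paralogy/repeat families beyond what suppression
handles, or incomplete annotation — real-data properties the generator
deliberately does not model. One real phenomenon the synthetic data *does*
reproduce is boundary wobble: when the genome repeats bases across a
junction, the junction position is genuinely ambiguous within the repeat,
and the anchor of a support cluster can sit a base or two off the planted
truth (always within the buffer). This is why recovery is asserted within
the buffer rather than exactly, and why annotated junctions occasionally
classify as novel at tolerance 0.

## Numerical and design choices

- All generator randomness is integer-only draws from one PCG64 stream per
  scenario seed; outputs are byte-identical across runs and platforms.
- Anchor ties (equal support counts) resolve to smaller coordinates;
  rescue ties to the leftmost candidate; overlapping-gene ties to the
  lexicographically smaller name. All tie-breaks are deterministic; the
  pipeline seed field is reserved but unused by default.
- Degenerate inputs: empty read streams, header-only outputs, zero-call
  metric requests (reported absent), empty subject databases (empty result)
  are all defined, tested paths rather than errors; malformed records in
  any input format are rejected with the offending line or record named.
- Run comparison matches calls greedily nearest-first by total boundary
  offset, each call matched at most once, giving an exhaustive disjoint
  common/unique partition.
- Problem sizes in the test-suite and acceptance scenarios (tens of
  kilobases of genome, hundreds of reads) were chosen as the smallest
  scales at which every contract — including the 50 kb distance boundary —
  is exercised end to end.

## Known limitations

- The internal aligner is exact-match only; mismatch-tolerant initial
  alignment requires the external adapter, and quality strings are carried
  but never scored.
- Junction support is not an expression estimate; no quantification beyond
  distinct-read counts is attempted, and the group screen performs no
  statistical inference.
- Canonical-motif filtering is intentionally absent (the target is
  non-canonical splicing), so low-complexity regions rely entirely on the
  multi-mapping suppression and support thresholds for noise control.
- Chromosome name aliasing ("chr1" vs "1") is not performed; inputs must
  agree on naming.
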