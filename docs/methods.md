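# Methods

spanweld closes assembly gaps — runs of `N` between contigs of a scaffold —
using uncorrected long reads (PacBio CLR-like, ~13% error dominated by
indels). The pipeline trades sensitivity for accuracy at every step: it
would rather leave a gap open than insert a wrong sequence. This note
describes the model behind each stage, the parameters that matter, the
synthetic data the tests run on, and where the implementation makes choices
the problem leaves open.

## Repeat annotation

Repeats are the reason gaps exist and the main way gap closing goes wrong:
a read from one repeat copy aligned to another copy supports a false join.
Four annotations are computed on contig coordinates and then merged:

1. **Low complexity** — SDUST-style triplet statistic over 64 bp windows
   (score = Σ c_t(c_t−1)/2 / (n−1) over triplet counts c_t, threshold 2.0).
2. **Tandem repeats** — for every period p ≤ 100, runs where
   seq[i] = seq[i+p] (gaps ≤ 3 tolerated, ≥ 80% match density, run length
   ≥ max(60 − p, p)) mask `[run, run + p)`.
3. **Self-alignment repeats** — positions covered by ≥ 4
   (`max_coverage_self`) local self-alignments of the assembly, the trivial
   self-match excluded.
4. **Read-coverage repeats** — two parts. Positions whose read-alignment
   depth exceeds C_max, where C_max is the smallest m with
   P(Poisson(C) > m) < 10⁻³ for global read coverage C (uniform sampling
   implies Poisson depth at any position; depth far above that tail means
   multiple genomic copies collapsed onto one assembly locus). And
   positions where *improper* alignments — reads whose unaligned tails are
   not explained by a contig boundary — are deeper than C/2: an
   interspersed repeat inside a read produces exactly such clipped
   alignments on every other copy.

The tail probability 10⁻³ is configurable (`cmax_tail_prob`); it keeps
C_max near C + 3√C so that essentially no single-copy locus is masked
while two-fold collapsed repeats (depth ≈ 2C) are caught at any realistic
coverage.

**Properness and contig boundaries.** An alignment is proper when each
unaligned read tail is either ≤ 100 bp (`proper_alignment_allowance`) or
abuts a contig boundary — a read reaching into a gap necessarily has a
long tail that no aligner can place. The strict read-tail-only rule is
available (`is_proper(..., at_target_ends=False)`) but is not what the
pipeline uses: with it, every gap-spanning read would count as improper
and every gap flank would mask itself as repetitive.

**Homogenization.** The union of the four masks is projected through every
read alignment onto read coordinates and back through *all* alignments of
each read, so a repeat detected on one copy masks every copy a read
connects it to. The projection iterates to a fixpoint (≤ 5 rounds), which
makes the operation idempotent by construction. Coordinate projection uses
the alignment trace when present, linear interpolation otherwise; the
error is bounded by the local indel imbalance, which is negligible at
masking granularity.

## Alignment filtering

An alignment survives iff it (i) is proper (boundary-aware, above);
(ii) has ≥ 500 bp (`min_anchor_length`) of its reference interval outside
the homogenized mask; (iii) does not overlap another retained alignment of
the same read by more than the allowance in read coordinates — such a read
maps ambiguously and is discarded entirely, accuracy over sensitivity; and
(iv) touches a contig end within the allowance — an alignment buried
inside a contig cannot help close a gap.

## Scaffold graph

Each contig i contributes four nodes (pre, begin, end, post). Contig edges
{begin, end} are structural; input-gap edges record the existing
scaffolding; span edges carry reads whose consecutive filtered alignments
exit one contig and enter another (orientation handled by flipping
begin/end for minus-strand alignments); extension edges carry reads
running past a contig end. Transitive edges are never added: a read
touching contigs i, i+1, i+2 yields edges (i, i+1) and (i+1, i+2) only.

Small contigs can be skipped by individual low-quality reads, producing a
cycle: an edge (i, i+2) parallel to the stepwise path. For cycles with up
to 3 intermediate contigs, the skipping reads are re-aligned to the
skipped contigs at increased sensitivity (error ceiling +5 points, seed
length 12→8); a read confirmed on every intermediate has its evidence
rewritten onto the stepwise edges, otherwise it is dropped.

Remaining conflicts (a contig end with ≥ 2 span edges) are resolved by a
dominance rule: the edge with the most reads is kept only if its effective
support — read count, multiplied by 6 (`existing_gap_bonus`) when the edge
coincides with an input gap — is at least 3× (`best_pile_up_margin`) every
competitor's; otherwise all competing edges are deleted. Ties therefore
delete both. Span edges with fewer than 3 reads (`min_spanning_reads`) are
discarded — one or two CLR reads cannot support an accurate consensus —
unless `allow_single_reads` is set, in which case the raw read sequence
may be inserted. Each surviving span edge becomes a pile-up, merged with
the extension reads of its two flanking contig ends.

## Pile-up consensus

**Cropping.** All reads of a pile-up are trimmed, through their alignment
traces, to common reference positions on each flank, chosen to keep as
much flank as possible (capped at 800 bp; reads preventing a usable flank
of at least `min_anchor_length`/2 are dropped down to the minimum read
count) and reverse-complemented into a common orientation.

**Chaining.** Read-to-read local alignments of each pair are chained on a
DAG: node weight = −(mean bp covered on the two reads); alignments x, y
are chainable iff x begins strictly before y on both reads in the same
orientation, gapSizeDiff(x,y) = |gap_A − gap_B| < 1000 (`max_indel`),
both gaps < 10 000 (`max_chain_gap`), and the relative overlap (overlap /
shorter alignment, the larger of the two read-wise ratios) ≤ 0.3
(`max_relative_overlap`); edge weight = gapSizeDiff + 0.1·max(|gap_A|,
|gap_B|). The minimum-weight path is the chain; ties break toward more
aligned bases, then the leftmost start.

**Reference selection.** Each read is tiled into 100 bp windows; a
window's intrinsic QV is the mean per-base difference rate of the chained
alignments covering it (worst value 1.0 when uncovered). A window is bad
if it falls in the worst 8% (`bad_fraction`) of all windows pooled over
the pile-up; the spanning read with the fewest bad windows (ties: longer
read, then smaller id) becomes the reference.

**Consensus.** Reads are projected onto reference coordinates through
their chains, indels left-normalized so equivalent alignments vote
identically. Columns where one base holds ≥ 80% of the votes are emitted
directly; runs of unclean columns are voted as whole anchored segment
strings — the decisive design point: at 13% error a read's own nearby
errors change how a pairwise aligner phrases a variant (substitution here
vs insertion there), so per-column pluralities split and can never fix the
reference's indel errors, while segment strings capture the variant
atomically. Segments whose strings are all distinct fall back to a small
partial-order alignment (match +2, mismatch/gap −2; consensus = heaviest
edge path, each edge paying a depth-scaled toll of 0.55·depth so detours
through weakly supported extra nodes cannot outscore a well-supported
direct edge). Because the first round's votes are conditioned on an
error-laden reference, up to three further rounds re-align every read
directly to the evolving consensus (globally for spanning reads,
end-anchored for extension reads) and vote again. Error-free pile-ups
short-circuit: every column is clean and the consensus equals the reads.

Measured on 2 kb truths at 13% error, consensus identity is ≈ 0.96 at
depth 5, ≈ 0.99 at depth 10, ≈ 0.998 at depth 20, rising monotonically
with depth. A de-Bruijn-based consensus could do better below depth ~8;
this is the known fidelity gap of the substitute, and why the pipeline
requires ≥ 3 spanning reads and is benchmarked at 20×.

**Anchoring.** The consensus ends are aligned to the flanking contigs
(end-anchored, ≥ 95% identity over ≥ `min_anchor_length`/2 required); the
insert sites are the innermost exact-match runs of ≥ 24 bp
(`anchor_exact_run`, chosen so placement is unambiguous at 13% read
error). Contig sequence outside the anchors is never modified; anchoring
failure leaves the gap open.

## Closing modes and validation

`intra_only` (default) fills only gaps already present in input scaffolds;
`intra_and_inter` additionally joins scaffold ends supported by enough
spanning reads; `free_scaffolding` rebuilds scaffolds from the read-
supported joins alone. Candidate discovery is mode-independent.

Validation re-maps all reads to the gap-closed assembly. For each closed
gap, the region 1000 bp (`region_context`) around the former gap (clipped
to its contig) must be fully spanned by ≥ 3 unchained local alignments,
and the minimum continuous alignment coverage — the count of alignments
completely covering a sliding 500 bp window (`weak_coverage_window`) —
must exceed the threshold, by default half the haploid coverage
(0.5·C/ploidy). Failing insertions revert to the original N-run
byte-identically (inter-scaffold joins revert to separate scaffolds).
Regions shorter than the window are evaluated at the single window
covering them. The built-in aligner splits alignments wherever the
running alignment score falls 60 below its maximum (X-drop), so a wrong
insert flanked by correct sequence is *not* spanned by any single local
alignment — this is what makes the validation test discriminative.

## Built-in aligner

A contract, not a fixed algorithm: any aligner producing traced local
alignments at a stated error ceiling is conformant, and external PAF (with
`cg:Z` traces) can be supplied instead. The reference implementation uses
exact k-mer seeds (k=12, hyper-frequent k-mers dropped), greedy colinear
clustering with a drift band of 0.25·min(Δq,Δt)+12 (a max-based band would
chain straight across tandem periods), banded edit-distance extension
(edlib) capped at 800 bp beyond the seeded region — seeds are dense enough
at ≤ 25% error that genuine alignments never continue longer unseeded —
Kadane trimming to the maximal-scoring segment (match +1, error −3), and
X-drop splitting. Adequate for the ≤ 5 Mb genomes this package targets;
not a general-purpose mapper.

## Synthetic data

The generator emulates the study conditions end to end: a uniform-base
genome with planted interspersed repeat families (diverged copies of a
master sequence) and tandem arrays; gaps introduced by replacing known
truth sequence with N-runs of identical length (≥ 10 bp, ≥ 3 kb from any
pre-existing gap), placed preferentially straddling repeat boundaries —
repeats cause real gaps, and random placement would make the benchmark too
easy; reads sampled uniformly with log-normal lengths (mean 25 kb, sd =
`len_param`/5 = 25 kb, long-tailed, truncated at sequence ends) and
i.i.d. per-base errors at 13% split 55% insertion / 25% deletion / 20%
substitution. A gap is *closable* when ≥ 3 reads span it plus 500 bp on
either side, decided from the recorded read origins — the sensitivity
ceiling for any closer.

What this does not emulate: non-uniform coverage, chimeric reads,
position-dependent error rates, heterozygosity, and repeat structures
longer than the reads. Passing tests therefore demonstrate algorithmic
correctness under the stated error model, not performance on arbitrary
real genomes.

Default study sizes (chosen to exercise every code path while keeping a
full run in minutes on one core): 500 kb genome, 10×2 kb + 8×800 bp
repeat families at 3–5% divergence plus one 17-mer×30 tandem array, 20
gaps of 50–5000 bp, 20× coverage. The coverage-trend analysis uses a
250 kb genome with 10 gaps at 5–25×.

## Evaluation

Original test contigs are located in a result assembly by exact, unique
matching (both strands), after excluding contigs that are duplicated
within the test assembly itself (cropped by 300 bp per flank for that
check; the search needle is cropped by `--crop-alignment`, default 0, and
`--recover-imperfect-contigs` enables a ≤ 1.5%-mismatch full-length
unique rescue). Each gap is then *closed* (flanks on one result contig,
consistent orientation and order; the inserted sequence between the
placements is compared to the truth), *unclosed* (different but adjacent
contigs of one scaffold, separated only by an N-run), *unknown* (a flank
missing or ambiguous), or *broken* (flanks found but no longer adjacent —
a misassembly). Identity = matches / global-alignment length, so indels
count as errors (19 correct bases of 20 → 95%); summaries report the mean,
the truth-length-weighted mean, and a six-bin histogram
([0,.7), [.7,.9), [.9,.95), [.95,.99), [.99,1), {1}). Contiguity is NG(x)
against the fixed ground-truth genome size (A/C/G/T bases only).

## Numerical / degenerate-input choices

Coordinates are 0-based half-open throughout (AGP output 1-based, BED
0-based, both standard). Terminal N-runs in input scaffolds are preserved
but never closable. Chain scores compare with a 10⁻⁹ tolerance; all other
tie-breaks are lexicographic and deterministic. Empty-vs-empty identity
is 1.0, empty-vs-nonempty 0.0. Pile-ups whose flanks cannot reach half
the anchor length fail anchoring rather than guessing. All randomness
flows from explicit integer seeds; the pipeline itself is deterministic
given its inputs.

## Known limitations

Single-threaded, desk-scale (≤ ~5 Mb genomes with the built-in aligner;
larger inputs require external PAF). Consensus below ~8× local depth is
weaker than a de Bruijn approach. Diploid variation is not separated —
heterozygous loci may validate poorly. Circular chromosomes and global
scaffolding optimisation are out of scope.
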