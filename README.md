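# spanweld

Close assembly gaps with uncorrected long reads — accurately.

Draft genome assemblies are scaffolds: contigs interleaved with runs of
`N` where the sequence is unknown, usually because of repeats. spanweld
fills these gaps from PacBio-CLR-class long reads (~13% error, indel
dominated) without any prior read correction, for people who have a draft
assembly plus auxiliary long-read data and care that inserted sequence is
*right*: every candidate insertion must survive repeat-aware alignment
filtering, conflict resolution in a scaffold graph, a pile-up consensus,
and a final re-mapping validation, or the gap stays `N`.

The pipeline:

1. **Repeat annotation** — low-complexity (DUST-like), tandem
   (period-bounded self-match), self-alignment depth ≥ 4, and
   read-coverage masks. Read depth at a unique locus is Poisson(C) for
   global coverage C, so positions deeper than the smallest m with
   P(Poisson(C) > m) < 10⁻³ are collapsed repeats; improper alignments
   (clipped reads not explained by contig ends) deeper than C/2 mark the
   rest. Masks are homogenized through the read alignments so every
   repeat copy is masked.
2. **Filtering** — keep alignments that are proper, anchored by ≥ 500
   non-repetitive bp, unambiguous within their read, and touching a
   contig end.
3. **Scaffold graph** — four nodes per contig; read-supported span edges
   between contig ends; small skipped-contig cycles repaired by
   re-alignment; conflicts resolved by a ≥ 3× support-dominance rule with
   a 6× bonus for edges matching the input scaffolding; edges with < 3
   reads dropped.
4. **Consensus** — pile-up reads cropped to common flank positions;
   read-to-read local alignments chained by a shortest path on a DAG with
   node weight −(mean covered bp) and edge weight
   gapSizeDiff + 0.1·max(|gap_A|, |gap_B|); a reference read picked by
   intrinsic quality (fewest windows in the worst 8%); a windowed,
   anchor-segmented majority vote (with a small partial-order alignment
   for contested segments) polished over several re-alignment rounds; the
   result anchored into the flanks at ≥ 24 bp exact matches.
5. **Validation** — reads re-mapped to the closed assembly; a closed gap
   passes only with ≥ 3 alignments spanning the ±1 kb region and minimum
   continuous 500 bp-window coverage above half the haploid read
   coverage. Failures revert to the original `N`-run.

It also ships the benchmark machinery: a synthetic genome/read simulator
with planted repeats, ground-truth gap introduction, closability flags,
and an evaluator that classifies every gap (closed / unclosed / unknown /
broken) and reports sequence identity and NG50.

## Worked example

```python
from spanweld import PipelineConfig, close_gaps
from spanweld.evaluate import evaluate_closure
from spanweld.simulate import (RepeatFamily, simulate_genome, plan_gaps,
                               make_test_assembly, simulate_reads,
                               find_closable_gaps)

genome, repeats = simulate_genome(120_000, [RepeatFamily(6, 1500, 0.05)], seed=7)
spec = plan_gaps(genome, repeats, 4, (50, 1500), seed=8)
test, truths, _ = make_test_assembly(genome, gap_spec=spec)
reads, origins = simulate_reads(genome, coverage=20, mean_len=12_000,
                                len_param=60_000, seed=9)

result = close_gaps(test, reads, PipelineConfig(read_coverage=20))
records, summary, ng = evaluate_closure(test, result.assembly, truths,
                                        genome.total_bases())
for r in records:
    print(r.gap_id, r.state, r.identity)
```

prints

```
chr1.1:21097-21249 closed 1.0
chr1.1:38012-38742 closed 1.0
chr1.1:48066-48255 closed 1.0
chr1.1:102570-102824 closed 1.0
```

— all four introduced gaps (152–730 bp, planted near repeat copies)
closed, each inserted sequence identical to the ground truth that was
replaced by `N`s.

The same flow from the shell:

```bash
spanweld sim-genome --length 120000 --seed 7 --out ref.fa
spanweld build-partial-assembly ref.fa --gap-bed gaps.bed \
    --out test.fa --truth-out truth.tsv
spanweld sim-reads ref.fa --coverage 20 --seed 9 --out reads.fa
spanweld close test.fa reads.fa --read-coverage 20 --out closed.fa
spanweld check-results test.fa closed.fa truth.tsv --genome-size 120000
```

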