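"""Gap classification, sequence identity, summaries, and NG statistics."""

import numpy as np
import pytest

from spanweld.assembly import Assembly, reverse_complement, scaffold_from_sequence
from spanweld.evaluate import (
    GapRecord,
    classify_gaps,
    evaluate_closure,
    gap_identity,
    locate_contigs,
    ng_stats,
    summarize,
)
from spanweld.simulate import GapTruth, make_test_assembly, plan_gaps, simulate_genome
from tests.conftest import random_dna


class TestIdentity:
    def test_worked_example_19_of_20(self):
        truth = "ACGTACGTACGTACGTACGT"
        inserted = truth[:10] + ("C" if truth[10] != "C" else "G") + truth[11:]
        assert gap_identity(inserted, truth) == pytest.approx(0.95)

    def test_identical(self):
        assert gap_identity("ACGT", "ACGT") == 1.0

    def test_empty_vs_truth(self):
        assert gap_identity("", "A" * 100) == 0.0
        assert gap_identity("", "") == 1.0

    def test_symmetric(self):
        a, b = "ACGTACGTAA", "ACTTACGA"
        assert gap_identity(a, b) == pytest.approx(gap_identity(b, a))

    def test_indels_count_as_errors(self):
        truth = "A" * 50
        assert gap_identity("A" * 45, truth) == pytest.approx(45 / 50)


def _benchmark(seed=41, n_gaps=2):
    genome, track = simulate_genome(40_000, seed=seed)
    spec = plan_gaps(genome, track, n_gaps, (100, 400), seed=seed + 1)
    test, truths, _ = make_test_assembly(genome, gap_spec=spec)
    return genome, test, truths


class TestClassify:
    def test_ground_truth_result_all_closed_identity_one(self):
        genome, test, truths = _benchmark()
        # "result" = the ground truth itself, re-scaffolded per test scaffold
        result = Assembly(
            [
                scaffold_from_sequence(s.id + "_t", t)
                for s, t in zip(
                    test.scaffolds,
                    [genome.scaffolds[0].sequence],
                )
            ]
        )
        records, summary, stats = evaluate_closure(
            test, result, truths, genome.total_bases()
        )
        assert summary.n_closed == len(truths)
        assert all(r.identity == 1.0 for r in records)

    def test_unclosed_when_gap_remains(self):
        genome, test, truths = _benchmark()
        records, summary, _ = evaluate_closure(
            test, test, truths, genome.total_bases()
        )
        assert summary.n_unclosed == len(truths)
        assert summary.n_broken == 0

    def test_broken_when_flanks_separated(self):
        genome, test, truths = _benchmark(seed=43, n_gaps=1)
        (t,) = truths
        (s,) = test.scaffolds
        seq = s.sequence
        # split the assembly at the gap into two far-apart scaffolds, and
        # attach the right flank to unrelated sequence
        rng = np.random.default_rng(44)
        left_part = seq[: t.test_begin]
        right_part = seq[t.test_end :]
        result = Assembly(
            [
                scaffold_from_sequence("a", left_part + random_dna(rng, 5000)),
                scaffold_from_sequence("b", right_part),
            ]
        )
        records = evaluate_closure(test, result, truths, genome.total_bases())[0]
        assert records[0].state == "broken"

    def test_unknown_when_flank_missing(self):
        genome, test, truths = _benchmark(seed=45, n_gaps=1)
        (t,) = truths
        (s,) = test.scaffolds
        rng = np.random.default_rng(46)
        result = Assembly(
            [scaffold_from_sequence("junk", random_dna(rng, 10_000))]
        )
        records = evaluate_closure(test, result, truths, genome.total_bases())[0]
        assert records[0].state == "unknown"

    def test_reverse_complemented_result_still_closed(self):
        genome, test, truths = _benchmark(seed=47, n_gaps=1)
        result = Assembly(
            [
                scaffold_from_sequence(
                    "rc", reverse_complement(genome.scaffolds[0].sequence)
                )
            ]
        )
        records = evaluate_closure(test, result, truths, genome.total_bases())[0]
        assert records[0].state == "closed"
        assert records[0].identity == 1.0


class TestLocate:
    def test_duplicated_contig_excluded(self):
        rng = np.random.default_rng(48)
        dup = random_dna(rng, 2000)
        uniq = random_dna(rng, 2000)
        test = Assembly(
            [
                scaffold_from_sequence("s1", dup),
                scaffold_from_sequence("s2", dup),
                scaffold_from_sequence("s3", uniq),
            ]
        )
        result = Assembly([scaffold_from_sequence("r", dup + uniq)])
        placements = locate_contigs(test, result, crop_ambiguous=100)
        assert placements["s1.1"] is None and placements["s2.1"] is None
        assert placements["s3.1"] is not None

    def test_modified_flanks_found_with_crop(self):
        rng = np.random.default_rng(49)
        contig = random_dna(rng, 3000)
        test = Assembly([scaffold_from_sequence("s", contig)])
        mangled = random_dna(rng, 50) + contig[50:-50] + random_dna(rng, 50)
        result = Assembly([scaffold_from_sequence("r", mangled)])
        assert locate_contigs(test, result, crop_alignment=0)["s.1"] is None
        assert locate_contigs(test, result, crop_alignment=50)["s.1"] is not None

    def test_recover_imperfect_contigs(self):
        rng = np.random.default_rng(50)
        contig = random_dna(rng, 3000)
        test = Assembly([scaffold_from_sequence("s", contig)])
        # ~0.5% scattered substitutions
        mut = list(contig)
        for pos in rng.choice(3000, 15, replace=False):
            mut[pos] = "ACGT"[("ACGT".index(mut[pos]) + 1) % 4]
        result = Assembly([scaffold_from_sequence("r", "".join(mut))])
        assert locate_contigs(test, result)["s.1"] is None
        assert (
            locate_contigs(test, result, recover_imperfect=True)["s.1"]
            is not None
        )


class TestSummarize:
    def test_mean_and_weighted_mean(self):
        records = [
            GapRecord("a", "closed", identity=1.0, truth_len=100),
            GapRecord("b", "closed", identity=0.9, truth_len=900),
        ]
        s = summarize(records)
        assert s.mean_id == pytest.approx(0.95)
        assert s.weighted_id == pytest.approx(0.91)

    def test_bin_edges(self):
        records = [
            GapRecord("a", "closed", identity=0.99, truth_len=10),
            GapRecord("b", "closed", identity=1.0, truth_len=10),
            GapRecord("c", "closed", identity=0.7, truth_len=10),
        ]
        s = summarize(records)
        assert s.bins[-1] == 1  # exactly 1.0
        assert s.bins[-2] == 1  # [0.99, 1.0)
        assert s.bins[1] == 1  # [0.7, 0.9)
        assert sum(s.bins) == s.n_closed == 3

    def test_zero_closed_gives_na(self):
        s = summarize([GapRecord("a", "unclosed", truth_len=5)])
        assert s.mean_id is None and s.weighted_id is None


class TestNg:
    def test_hand_example(self):
        asm = Assembly(
            [
                scaffold_from_sequence("a", "A" * 50),
                scaffold_from_sequence("b", "C" * 30),
                scaffold_from_sequence("c", "G" * 20),
            ]
        )
        stats = ng_stats(asm, 100)
        assert stats.ng50 == 50

    def test_single_contig(self):
        asm = Assembly([scaffold_from_sequence("a", "A" * 1000)])
        stats = ng_stats(asm, 1000, xs=(10, 50, 100))
        assert all(v == 1000 for _, v in stats.curve)

    def test_short_assembly_gives_zero(self):
        asm = Assembly([scaffold_from_sequence("a", "A" * 100)])
        assert ng_stats(asm, 1000).ng50 == 0

    def test_against_sorted_prefix_oracle(self):
        rng = np.random.default_rng(51)
        lengths = [int(x) for x in rng.integers(10, 500, 12)]
        asm = Assembly(
            [
                scaffold_from_sequence(f"c{i}", "A" * n)
                for i, n in enumerate(lengths)
            ]
        )
        G = sum(lengths)
        stats = ng_stats(asm, G)
        ordered = sorted(lengths, reverse=True)
        for x, val in stats.curve:
            total = 0
            oracle = 0
            for L in ordered:
                total += L
                if total >= x / 100 * G:
                    oracle = L
                    break
            assert val == oracle

    def test_curve_nonincreasing(self):
        rng = np.random.default_rng(52)
        asm = Assembly(
            [
                scaffold_from_sequence(f"c{i}", "A" * int(n))
                for i, n in enumerate(rng.integers(50, 400, 8))
            ]
        )
        vals = [v for _, v in ng_stats(asm, 1500).curve]
        assert vals == sorted(vals, reverse=True)
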