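"""Insertion application modes, continuous coverage, validation."""

import numpy as np
import pytest

from spanweld.align import LocalAlignment
from spanweld.assembly import Assembly, scaffold_from_sequence, write_fasta
from spanweld.closer import apply_insertions, continuous_coverage, validate_gaps
from spanweld.config import PipelineConfig
from spanweld.consensus import Insertion
from spanweld.intervals import Interval
from tests.conftest import random_dna


def _aln(tid, tb, te, qid="r", tlen=100_000):
    span = te - tb
    return LocalAlignment(
        query_id=qid, query_len=span, q_begin=0, q_end=span,
        target_id=tid, target_len=tlen, t_begin=tb, t_end=te,
        strand="+", n_match=span,
    )


@pytest.fixture()
def gapped_assembly():
    rng = np.random.default_rng(31)
    left, right = random_dna(rng, 2000), random_dna(rng, 2000)
    asm = Assembly([scaffold_from_sequence("s", left + "N" * 100 + right)])
    return asm, left, right


def _insertion(core, cut_left=1990, cut_right=10, **kw):
    return Insertion(
        gap_id="g1", left_contig="s.1", left_side="end",
        right_contig="s.2", right_side="begin",
        cut_left=cut_left, cut_right=cut_right, core=core,
        is_input_gap=True, input_gap_length=100, **kw,
    )


class TestApply:
    def test_inserted_sequence_construction(self, gapped_assembly):
        asm, left, right = gapped_assembly
        ins = _insertion("TTTT")
        closed, records = apply_insertions(asm, [ins], "intra_only")
        (s,) = closed.scaffolds
        assert s.sequence == left[:1990] + "TTTT" + right[10:]
        (rec,) = records
        assert s.sequence[rec.core_begin : rec.core_end] == "TTTT"

    def test_no_insertions_byte_identical(self, gapped_assembly, tmp_path):
        asm, *_ = gapped_assembly
        closed, records = apply_insertions(asm, [], "intra_only")
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(asm, p1)
        write_fasta(closed, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert records == []

    def test_inter_join_ignored_under_intra_only(self):
        rng = np.random.default_rng(32)
        a, b = random_dna(rng, 2000), random_dna(rng, 2000)
        asm = Assembly(
            [scaffold_from_sequence("x", a), scaffold_from_sequence("y", b)]
        )
        ins = Insertion(
            gap_id="j", left_contig="x.1", left_side="end",
            right_contig="y.1", right_side="begin",
            cut_left=1995, cut_right=5, core="ACGT", is_input_gap=False,
        )
        closed, _ = apply_insertions(asm, [ins], "intra_only")
        assert len(closed.scaffolds) == 2
        closed2, recs = apply_insertions(asm, [ins], "intra_and_inter")
        assert len(closed2.scaffolds) == 1
        (s,) = closed2.scaffolds
        assert s.sequence == a[:1995] + "ACGT" + b[5:]
        assert recs and recs[0].scaffold_id == s.id

    def test_free_scaffolding_joins_contigs(self):
        rng = np.random.default_rng(33)
        a, b = random_dna(rng, 2000), random_dna(rng, 2000)
        asm = Assembly(
            [scaffold_from_sequence("x", a), scaffold_from_sequence("y", b)]
        )
        ins = Insertion(
            gap_id="j", left_contig="x.1", left_side="end",
            right_contig="y.1", right_side="begin",
            cut_left=2000, cut_right=0, core="", is_input_gap=False,
        )
        closed, _ = apply_insertions(asm, [ins], "free_scaffolding")
        assert len(closed.scaffolds) == 1
        assert closed.scaffolds[0].sequence == a + b

    def test_unapplied_gap_keeps_n_run(self, gapped_assembly):
        asm, left, right = gapped_assembly
        closed, _ = apply_insertions(asm, [], "intra_only")
        assert "N" * 100 in closed.scaffolds[0].sequence


class TestContinuousCoverage:
    def test_single_covering_alignment(self):
        alns = [_aln("c", 0, 2000)]
        assert continuous_coverage(alns, Interval("c", 0, 2000), w=500) == 1

    def test_abutting_alignments_leave_uncovered_window(self):
        # two alignments overlapping by 400 < w=500 mid-region
        alns = [_aln("c", 0, 1200), _aln("c", 800, 2000)]
        assert continuous_coverage(alns, Interval("c", 0, 2000), w=500) == 0

    def test_region_shorter_than_window(self):
        alns = [_aln("c", 0, 300)]
        assert continuous_coverage(alns, Interval("c", 50, 250), w=500) == 1

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(34)
        for _ in range(25):
            alns = []
            for _ in range(rng.integers(1, 15)):
                b = int(rng.integers(0, 3000))
                e = b + int(rng.integers(200, 1500))
                alns.append(_aln("c", b, e))
            region = Interval("c", 500, 3000)
            w = 400
            got = continuous_coverage(alns, region, w)
            oracle = min(
                sum(1 for a in alns if a.t_begin <= x and a.t_end >= x + w)
                for x in range(region.begin, region.end - w + 1)
            )
            assert got == oracle


class TestValidate:
    def _setup(self, gapped_assembly, n_spanning):
        asm, left, right = gapped_assembly
        ins = _insertion("TTTT")
        closed, records = apply_insertions(asm, [ins], "intra_only")
        contig = closed.contigs[0]
        rec = records[0]
        rb = max(0, rec.core_begin - 1000)
        re_ = min(len(contig), rec.core_end + 1000)
        alns = [
            _aln(contig.id, max(0, rb - 50), min(len(contig), re_ + 50),
                 qid=f"v{i}", tlen=len(contig))
            for i in range(n_spanning)
        ]
        return closed, records, [ins], alns

    def test_well_covered_insertion_passes(self, gapped_assembly):
        cfg = PipelineConfig(read_coverage=10, ploidy=1)  # threshold 5
        closed, records, inss, alns = self._setup(gapped_assembly, 8)
        (out,) = validate_gaps(closed, records, inss, alns, cfg)
        assert out.validated == "pass"

    def test_thin_coverage_fails(self, gapped_assembly):
        cfg = PipelineConfig(read_coverage=10, ploidy=1)
        closed, records, inss, alns = self._setup(gapped_assembly, 2)
        (out,) = validate_gaps(closed, records, inss, alns, cfg)
        assert out.validated == "fail"

    def test_monotone_in_spanning_reads(self, gapped_assembly):
        cfg = PipelineConfig(read_coverage=10, ploidy=1)
        closed, records, inss, alns = self._setup(gapped_assembly, 6)
        (r1,) = validate_gaps(closed, records, inss, alns, cfg)
        (r2,) = validate_gaps(closed, records, inss, alns + alns[:3], cfg)
        assert not (r1.validated == "pass" and r2.validated == "fail")

    def test_reverting_restores_input(self, gapped_assembly, tmp_path):
        asm, *_ = gapped_assembly
        ins = _insertion("TTTT")
        # validation fails (no alignments) -> re-apply without it
        closed, records = apply_insertions(asm, [ins], "intra_only")
        cfg = PipelineConfig(read_coverage=10)
        (out,) = validate_gaps(closed, records, [ins], [], cfg)
        assert out.validated == "fail"
        reverted, _ = apply_insertions(asm, [], "intra_only")
        p1, p2 = tmp_path / "in.fa", tmp_path / "out.fa"
        write_fasta(asm, p1)
        write_fasta(reverted, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_default_validation_threshold():
    cfg = PipelineConfig(read_coverage=40, ploidy=2)
    assert cfg.validation_min_coverage == 10.0
    cfg2 = PipelineConfig(read_coverage=40, ploidy=2, min_coverage_reads=7)
    assert cfg2.validation_min_coverage == 7.0
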