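"""Cropping, intrinsic QVs, reference selection, consensus, anchoring."""

import numpy as np
import pytest

from spanweld.align import LocalAlignment, align_pair
from spanweld.assembly import Assembly, scaffold_from_sequence
from spanweld.config import PipelineConfig
from spanweld.consensus import (
    AlignmentChain,
    CroppedPileUp,
    CroppedRead,
    _swap_alignment,
    anchor_insertion,
    build_insertion,
    chain_alignments,
    consensus,
    crop_pileup,
    intrinsic_qv,
    select_reference_read,
)
from spanweld.evaluate import gap_identity
from spanweld.graph import PileUp, SpanSupport
from spanweld.simulate import _corrupt
from tests.conftest import random_dna


def _aln(qid, qb, qe, tid, tb, te, qlen, tlen, strand="+"):
    return LocalAlignment(
        query_id=qid, query_len=qlen, q_begin=qb, q_end=qe,
        target_id=tid, target_len=tlen, t_begin=tb, t_end=te,
        strand=strand, n_match=min(qe - qb, te - tb),
    )


@pytest.fixture()
def gap_fixture():
    rng = np.random.default_rng(21)
    left = random_dna(rng, 3000)
    gap = random_dna(rng, 400)
    right = random_dna(rng, 3000)
    seq = left + "N" * 400 + right
    asm = Assembly([scaffold_from_sequence("s", seq)])
    return asm, left, gap, right


def _error_free_pileup(asm, left, gap, right, starts=(500, 800, 1100)):
    """Spanning reads with staggered starts, no errors."""
    reads = {}
    supports = []
    genome = left + gap + right
    for i, s in enumerate(starts):
        rid = f"r{i}"
        end = len(genome) - 500 - 150 * i
        reads[rid] = genome[s:end]
        qlen = end - s
        a1 = _aln(rid, 0, 3000 - s, "s.1", s, 3000, qlen, 3000)
        a2 = _aln(rid, 3000 + 400 - s, qlen, "s.2", 0, end - 3400, qlen, 3000)
        supports.append(SpanSupport(rid, a1, a2))
    pileup = PileUp(
        left=("s.1", "end"), right=("s.2", "begin"), spanning=supports,
        is_input_gap=True, input_gap_length=400,
    )
    return pileup, reads


class TestCrop:
    def test_error_free_cropped_reads_identical(self, gap_fixture):
        asm, left, gap, right = gap_fixture
        pileup, reads = _error_free_pileup(asm, left, gap, right)
        cfg = PipelineConfig(read_coverage=10)
        cropped = crop_pileup(pileup, asm, reads, cfg)
        seqs = {r.seq for r in cropped.spanning_reads}
        assert len(seqs) == 1  # all reads share the crop window exactly
        (s,) = seqs
        assert gap in s and s.startswith(cropped.left_flank[:50])

    def test_crop_positions_inside_flank_contigs(self, gap_fixture):
        asm, left, gap, right = gap_fixture
        pileup, reads = _error_free_pileup(asm, left, gap, right)
        cropped = crop_pileup(pileup, asm, reads, PipelineConfig(read_coverage=10))
        assert 0 < cropped.pos_left < 3000
        assert 0 < cropped.pos_right < 3000

    def test_read_missing_crop_point_dropped(self, gap_fixture):
        asm, left, gap, right = gap_fixture
        pileup, reads = _error_free_pileup(
            asm, left, gap, right, starts=(500, 800, 1100, 2900)
        )
        # the late-starting read reaches only 100 bp of the left flank;
        # with min_spanning_reads=3 it is sacrificed for a usable flank
        cropped = crop_pileup(pileup, asm, reads, PipelineConfig(read_coverage=10))
        assert len(cropped.spanning_reads) == 3
        assert {r.read_id for r in cropped.spanning_reads} == {"r0", "r1", "r2"}


class TestQv:
    def _chains(self, seqs):
        chains = {}
        ids = sorted(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                alns = [
                    x
                    for x in align_pair(
                        seqs[a], seqs[b], max_err=0.5, query_id=a, target_id=b,
                        min_seeds=2,
                    )
                    if x.strand == "+"
                ]
                best = chain_alignments(alns)
                if best:
                    chains[(a, b)] = best[0]
        return chains

    def test_identical_reads_zero_qv(self):
        rng = np.random.default_rng(22)
        seq = random_dna(rng, 1000)
        seqs = {f"r{i}": seq for i in range(3)}
        qvs = intrinsic_qv({r: 1000 for r in seqs}, self._chains(seqs))
        for r in seqs:
            assert np.all(qvs[r] == 0.0)

    def test_window_count(self):
        qvs = intrinsic_qv({"r": 950}, {}, window=100)
        assert len(qvs["r"]) == 10  # ceil(950 / 100)

    def test_corrupted_block_has_worse_qv(self):
        rng = np.random.default_rng(23)
        seq = random_dna(rng, 1200)
        bad = seq[:600] + random_dna(rng, 100) + seq[700:]
        seqs = {"bad": bad, "r1": seq, "r2": seq, "r3": seq}
        qvs = intrinsic_qv({r: len(s) for r, s in seqs.items()}, self._chains(seqs))
        assert qvs["bad"][6] > max(qvs["bad"][i] for i in (0, 1, 2, 3, 4))

    def test_lone_read_worst_qv(self):
        qvs = intrinsic_qv({"r": 500}, {})
        assert np.all(qvs["r"] == 1.0)

    def test_pristine_read_selected(self):
        # every noisy read carries one scrambled block of its own; the
        # clean read is the only one without a bad window
        rng = np.random.default_rng(24)
        truth = random_dna(rng, 1500)
        seqs = {"clean": truth}
        for i in range(4):
            lo = 200 + i * 250
            seqs[f"n{i}"] = truth[:lo] + random_dna(rng, 120) + truth[lo + 120 :]
        qvs = intrinsic_qv({r: len(s) for r, s in seqs.items()}, self._chains(seqs))
        ref = select_reference_read(qvs, {r: len(s) for r, s in seqs.items()})
        assert ref == "clean"

    def test_tie_breaks_by_length_then_id(self):
        qvs = {"a": np.zeros(3), "bb": np.zeros(3)}
        assert select_reference_read(qvs, {"a": 300, "bb": 310}) == "bb"
        assert select_reference_read(qvs, {"a": 300, "bb": 300}) == "a"


class TestConsensus:
    def test_error_free_reads_reproduce_reference(self):
        rng = np.random.default_rng(25)
        seq = random_dna(rng, 1500)
        seqs = {f"r{i}": seq for i in range(3)}
        chains = {}
        for a in ("r0", "r1"):
            (chain,) = chain_alignments(
                [x for x in align_pair(seq, seq, query_id=a, target_id="r2")
                 if x.strand == "+"]
            )
            chains[(a, "r2")] = chain
        assert consensus(seq, "r2", seqs, chains) == seq

    def test_noisy_pileup_high_identity(self):
        rng = np.random.default_rng(26)
        truth = random_dna(rng, 2000)
        arr = np.frombuffer(truth.encode(), dtype=np.uint8)
        seqs = {
            f"r{i}": _corrupt(rng, arr, 0.13).tobytes().decode()
            for i in range(15)
        }
        chains = {}
        ids = sorted(seqs)
        for i, a in enumerate(ids[:-1]):
            alns = [
                x
                for x in align_pair(
                    seqs[a], seqs[ids[-1]], max_err=0.5, query_id=a,
                    target_id=ids[-1], min_seeds=2,
                )
                if x.strand == "+"
            ]
            best = chain_alignments(alns)
            if best:
                chains[(a, ids[-1])] = best[0]
        cons = consensus(seqs[ids[-1]], ids[-1], seqs, chains)
        assert gap_identity(cons, truth) >= 0.99

    def test_identity_improves_with_depth(self):
        rng = np.random.default_rng(27)
        truth = random_dna(rng, 1500)
        arr = np.frombuffer(truth.encode(), dtype=np.uint8)

        def run(depth):
            seqs = {
                f"r{i}": _corrupt(rng, arr, 0.13).tobytes().decode()
                for i in range(depth)
            }
            ids = sorted(seqs)
            ref = ids[0]
            chains = {}
            for other in ids[1:]:
                alns = [
                    x
                    for x in align_pair(
                        seqs[other], seqs[ref], max_err=0.5, query_id=other,
                        target_id=ref, min_seeds=2,
                    )
                    if x.strand == "+"
                ]
                best = chain_alignments(alns)
                if best:
                    chains[(other, ref)] = best[0]
            return gap_identity(consensus(seqs[ref], ref, seqs, chains), truth)

        lo = np.mean([run(3) for _ in range(2)])
        hi = np.mean([run(20) for _ in range(2)])
        assert hi > lo

    def test_homopolymer_deletion_outvoted(self):
        base = "ACGTAGGTACCCCCCGTATGCACA" * 4
        dropped = base.replace("CCCCCC", "CCCCC", 1)
        seqs = {"r0": base, "r1": base, "r2": dropped}
        chains = {}
        for a in ("r1", "r2"):
            (chain,) = chain_alignments(
                [x for x in align_pair(seqs[a], base, query_id=a, target_id="r0",
                                       min_seeds=2, min_length=50)
                 if x.strand == "+"]
            )
            chains[(a, "r0")] = chain
        assert consensus(base, "r0", seqs, chains) == base


class TestAnchoring:
    def test_error_free_anchor_positions(self):
        rng = np.random.default_rng(28)
        left = random_dna(rng, 600)
        core = random_dna(rng, 300)
        right = random_dna(rng, 600)
        cons = left + core + right
        res = anchor_insertion(cons, left, right, k=24, min_anchor=500)
        assert res is not None
        cut_l, cons_b, cons_e, cut_r = res
        assert cut_l == 600 and cut_r == 600
        assert cons[cons_b:cons_e] == core

    def test_missing_right_flank_fails(self):
        rng = np.random.default_rng(29)
        left = random_dna(rng, 600)
        cons = left + random_dna(rng, 300)
        assert anchor_insertion(cons, left, random_dna(rng, 600)) is None


def test_build_insertion_end_to_end(gap_fixture):
    asm, left, gap, right = gap_fixture
    pileup, reads = _error_free_pileup(asm, left, gap, right)
    cfg = PipelineConfig(read_coverage=10)
    cropped = crop_pileup(pileup, asm, reads, cfg)
    ins = build_insertion(cropped, cfg)
    assert ins.validated == "pending"
    # reconstruct: kept left contig + core + kept right contig = truth
    rebuilt = left[: ins.cut_left] + ins.core + right[ins.cut_right :]
    assert rebuilt == left + gap + right
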