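"""Scaffold-graph construction, conflict resolution, and pile-up
collection on hand-built alignment sets."""

import numpy as np
import pytest

from spanweld.align import LocalAlignment
from spanweld.assembly import Assembly, scaffold_from_sequence
from spanweld.config import PipelineConfig
from spanweld.graph import (
    SpanSupport,
    build_graph,
    prune_and_collect,
    resolve_conflicts,
    resolve_small_cycles,
    span_edges,
)
from tests.conftest import random_dna


def _aln(qid, qb, qe, tid, tb, te, qlen, tlen, strand="+"):
    return LocalAlignment(
        query_id=qid, query_len=qlen, q_begin=qb, q_end=qe,
        target_id=tid, target_len=tlen, t_begin=tb, t_end=te,
        strand=strand, n_match=min(qe - qb, te - tb),
    )


@pytest.fixture()
def two_contig_assembly():
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 5000) + "N" * 100 + random_dna(rng, 5000)
    return Assembly([scaffold_from_sequence("s", seq)])


def _spanning_read(rid, gap_pad=300):
    # read: 2 kb of c1's end + gap + 2 kb of c2's start
    a1 = _aln(rid, 0, 2000, "s.1", 3000, 5000, qlen=4000 + gap_pad, tlen=5000)
    a2 = _aln(rid, 2000 + gap_pad, 4000 + gap_pad, "s.2", 0, 2000,
              qlen=4000 + gap_pad, tlen=5000)
    return [a1, a2]


def test_three_spanning_reads_one_span_edge(two_contig_assembly):
    alns = [a for i in range(3) for a in _spanning_read(f"r{i}")]
    g = build_graph(two_contig_assembly, alns)
    edges = span_edges(g)
    assert len(edges) == 1
    (u, v, data) = edges[0]
    assert {u, v} == {("s.1", "end"), ("s.2", "begin")}
    assert len(data["reads"]) == 3
    assert "input_gap" in data["kinds"]  # coincides with the input gap
    # contig edges untouched
    assert g.has_edge(("s.1", "begin"), ("s.1", "end"))


def test_no_transitive_edges():
    rng = np.random.default_rng(12)
    seq = "N".join([random_dna(rng, 3000)] * 3).replace("N", "N" * 50, 2)
    asm = Assembly([scaffold_from_sequence("s", seq)])
    # one read touching all three contigs consecutively
    alns = [
        _aln("r", 0, 1000, "s.1", 2000, 3000, qlen=7000, tlen=3000),
        _aln("r", 1100, 4100, "s.2", 0, 3000, qlen=7000, tlen=3000),
        _aln("r", 4200, 5200, "s.3", 0, 1000, qlen=7000, tlen=3000),
    ]
    g = build_graph(asm, alns)
    pairs = {frozenset((u[0], v[0])) for u, v, _ in span_edges(g)}
    assert frozenset(("s.1", "s.2")) in pairs
    assert frozenset(("s.2", "s.3")) in pairs
    assert frozenset(("s.1", "s.3")) not in pairs


def test_extension_edge_for_overhanging_read(two_contig_assembly):
    # read extends 1.5 kb past the end of the scaffold
    a = _aln("r", 0, 2000, "s.2", 3000, 5000, qlen=3500, tlen=5000)
    g = build_graph(two_contig_assembly, [a])
    assert g.has_edge(("s.2", "end"), ("s.2", "post"))
    assert len(g[("s.2", "end")][("s.2", "post")]["reads"]) == 1


class TestConflicts:
    def _graph_with_competitors(self, supports):
        """One begin node contested by several span edges."""
        rng = np.random.default_rng(13)
        pieces = [random_dna(rng, 3000) for _ in range(len(supports) + 1)]
        scaffolds = [
            scaffold_from_sequence(f"s{i}", p) for i, p in enumerate(pieces)
        ]
        asm = Assembly(scaffolds)
        alns = []
        rid = 0
        for ci, n in enumerate(supports):
            for _ in range(n):
                rid += 1
                alns.append(
                    _aln(f"r{rid}", 0, 1000, f"s{ci + 1}.1", 2000, 3000,
                         qlen=2100, tlen=3000)
                )
                alns.append(
                    _aln(f"r{rid}", 1100, 2100, "s0.1", 0, 1000,
                         qlen=2100, tlen=3000)
                )
        return asm, build_graph(asm, alns)

    def test_dominant_edge_kept(self):
        asm, g = self._graph_with_competitors([9, 3])
        g = resolve_conflicts(g, margin=3, gap_bonus=6)
        edges = span_edges(g)
        assert len(edges) == 1 and len(edges[0][2]["reads"]) == 9

    def test_close_call_deletes_all(self):
        asm, g = self._graph_with_competitors([8, 3])
        g = resolve_conflicts(g, margin=3, gap_bonus=6)
        assert span_edges(g) == []

    def test_input_gap_bonus(self):
        asm, g = self._graph_with_competitors([2, 4])
        # mark the 2-read edge as coinciding with an input gap
        for u, v, data in span_edges(g):
            if len(data["reads"]) == 2:
                data["kinds"].add("input_gap")
        g = resolve_conflicts(g, margin=3, gap_bonus=6)
        edges = span_edges(g)
        assert len(edges) == 1 and len(edges[0][2]["reads"]) == 2

    def test_at_most_one_span_edge_per_contig_end(self):
        asm, g = self._graph_with_competitors([9, 3, 1])
        g = resolve_conflicts(g)
        for node in g.nodes:
            if node[1] in ("begin", "end"):
                n_span = sum(
                    1 for nbr in g.neighbors(node)
                    if "span" in g[node][nbr]["kinds"] and g[node][nbr]["reads"]
                )
                assert n_span <= 1


class TestPileUps:
    def test_weak_edge_removed(self, two_contig_assembly):
        alns = [a for i in range(2) for a in _spanning_read(f"r{i}")]
        g = build_graph(two_contig_assembly, alns)
        assert prune_and_collect(g, min_spanning_reads=3) == []

    def test_extension_reads_merged(self, two_contig_assembly):
        alns = [a for i in range(4) for a in _spanning_read(f"r{i}")]
        # two extension reads on each flank of the gap
        for i in range(2):
            alns.append(
                _aln(f"el{i}", 0, 2000, "s.1", 3000, 5000, qlen=2400, tlen=5000)
            )
            alns.append(
                _aln(f"er{i}", 400, 2400, "s.2", 0, 2000, qlen=2400, tlen=5000)
            )
        g = build_graph(two_contig_assembly, alns)
        (pileup,) = prune_and_collect(g, min_spanning_reads=3)
        assert pileup.n_reads == 8
        assert len(pileup.spanning) == 4
        assert len(pileup.ext_left) == 2 and len(pileup.ext_right) == 2
        assert pileup.is_input_gap and pileup.input_gap_length == 100

    def test_no_surviving_edges(self, two_contig_assembly):
        g = build_graph(two_contig_assembly, [])
        assert prune_and_collect(g, 3) == []


def test_small_cycle_repair():
    rng = np.random.default_rng(14)
    a_seq, b_seq, c_seq = (random_dna(rng, n) for n in (3000, 800, 3000))
    seq = a_seq + "N" * 50 + b_seq + "N" * 50 + c_seq
    asm = Assembly([scaffold_from_sequence("s", seq)])
    reads = {}
    alns = []
    # three well-behaved reads touching A->B and B->C stepwise
    for i in range(3):
        rid = f"good{i}"
        reads[rid] = a_seq[-1500:] + b_seq + c_seq[:1500]
        alns += [
            _aln(rid, 0, 1500, "s.1", 1500, 3000, qlen=3800, tlen=3000),
            _aln(rid, 1500, 2300, "s.2", 0, 800, qlen=3800, tlen=800),
            _aln(rid, 2300, 3800, "s.3", 0, 1500, qlen=3800, tlen=3000),
        ]
    # one read whose alignment to the small contig B was missed
    reads["skip"] = a_seq[-1500:] + b_seq + c_seq[:1500]
    alns += [
        _aln("skip", 0, 1500, "s.1", 1500, 3000, qlen=3800, tlen=3000),
        _aln("skip", 2300, 3800, "s.3", 0, 1500, qlen=3800, tlen=3000),
    ]
    cfg = PipelineConfig(read_coverage=10)
    g = build_graph(asm, alns, cfg)
    skip_edge = (("s.1", "end"), ("s.3", "begin"))
    assert g.has_edge(*skip_edge) and len(g[skip_edge[0]][skip_edge[1]]["reads"]) == 1
    g = resolve_small_cycles(g, reads, asm, cfg)
    # the skipping edge is gone; the read was re-aligned to B and its
    # support rewritten onto the stepwise edges
    assert not (
        g.has_edge(*skip_edge) and "span" in g[skip_edge[0]][skip_edge[1]]["kinds"]
    )
    ab = g[("s.1", "end")][("s.2", "begin")]
    bc = g[("s.2", "end")][("s.3", "begin")]
    assert "skip" in {s.read_id for s in ab["reads"]}
    assert "skip" in {s.read_id for s in bc["reads"]}


def test_cycle_free_graph_unchanged(two_contig_assembly):
    alns = [a for i in range(3) for a in _spanning_read(f"r{i}")]
    reads = {f"r{i}": "ACGT" * 100 for i in range(3)}
    g = build_graph(two_contig_assembly, alns)
    before = {(u, v): len(d["reads"]) for u, v, d in span_edges(g)}
    g = resolve_small_cycles(g, reads, two_contig_assembly)
    after = {(u, v): len(d["reads"]) for u, v, d in span_edges(g)}
    assert before == after
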