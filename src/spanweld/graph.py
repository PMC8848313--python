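"""Scaffold graph: four nodes per contig, read-supported edges.

Nodes are ``(contig_id, part)`` with part in {pre, begin, end, post}.
Edge kinds:

* ``contig`` — {begin, end} of one contig (structural, never modified);
* ``input_gap`` — {end_i, begin_j} for adjacent contigs of an input
  scaffold (records the existing scaffolding);
* ``span`` — reads aligning to two contig ends across a gap;
* ``extension`` — {pre, begin} or {end, post}, reads running past a
  contig end.

A read contributes one span edge per *consecutive* pair of its filtered
alignments — transitive edges (contig i to i+2) are never added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .align import Aligner, LocalAlignment
from .assembly import Assembly
from .config import PipelineConfig

__all__ = [
    "Node",
    "SpanSupport",
    "PileUp",
    "build_graph",
    "resolve_small_cycles",
    "resolve_conflicts",
    "prune_and_collect",
    "span_edges",
    "dump_edges",
]

Node = Tuple[str, str]  # (contig_id, 'pre'|'begin'|'end'|'post')


@dataclass
class SpanSupport:
    """One read's evidence for a span edge: its alignments to both flanks,
    in read-coordinate order."""

    read_id: str
    aln_first: LocalAlignment
    aln_second: LocalAlignment


@dataclass
class PileUp:
    """Reads assigned to one candidate gap (ordered contig-end pair)."""

    left: Node  # (contig_id, 'begin'|'end') — side facing the gap
    right: Node
    spanning: List[SpanSupport]
    ext_left: List[Tuple[str, LocalAlignment]] = field(default_factory=list)
    ext_right: List[Tuple[str, LocalAlignment]] = field(default_factory=list)
    is_input_gap: bool = False
    input_gap_length: Optional[int] = None

    @property
    def gap_id(self) -> str:
        return f"{self.left[0]}({self.left[1]})--{self.right[0]}({self.right[1]})"

    @property
    def n_reads(self) -> int:
        return len(self.spanning) + len(self.ext_left) + len(self.ext_right)


def _exit_node(a: LocalAlignment) -> Node:
    """Node through which the read leaves the contig (read orientation)."""
    return (a.target_id, "end" if a.strand == "+" else "begin")


def _entry_node(a: LocalAlignment) -> Node:
    return (a.target_id, "begin" if a.strand == "+" else "end")


def _edge_key(u: Node, v: Node) -> Tuple[Node, Node]:
    return (u, v) if u <= v else (v, u)


def build_graph(
    assembly: Assembly,
    filtered_alns: Sequence[LocalAlignment],
    config: Optional[PipelineConfig] = None,
) -> nx.Graph:
    cfg = config or PipelineConfig()
    allowance = cfg.proper_alignment_allowance
    g = nx.Graph()

    # structural edges first
    for scaffold in assembly:
        prev_contig = None
        pending_gap = None
        for comp in scaffold.components:
            if hasattr(comp, "seq"):  # Contig
                for part in ("pre", "begin", "end", "post"):
                    g.add_node((comp.id, part))
                g.add_edge(
                    (comp.id, "begin"), (comp.id, "end"), kinds={"contig"}, reads=[]
                )
                if prev_contig is not None and pending_gap is not None:
                    g.add_edge(
                        (prev_contig.id, "end"),
                        (comp.id, "begin"),
                        kinds={"input_gap"},
                        reads=[],
                        gap_length=pending_gap,
                    )
                prev_contig = comp
                pending_gap = None
            else:  # Gap
                pending_gap = comp.length if prev_contig is not None else None

    # read-derived edges
    by_read: Dict[str, List[LocalAlignment]] = {}
    for a in filtered_alns:
        by_read.setdefault(a.query_id, []).append(a)
    for rid in sorted(by_read):
        alns = sorted(by_read[rid], key=lambda a: (a.q_begin, a.q_end))
        for a, b in zip(alns, alns[1:]):
            u, v = _exit_node(a), _entry_node(b)
            if u[0] == v[0]:
                continue  # same contig twice in a row: no self-span
            _add_read_edge(g, u, v, "span", SpanSupport(rid, a, b))
        first, last = alns[0], alns[-1]
        if first.q_begin > allowance:
            n = _entry_node(first)
            outer = (n[0], "pre" if n[1] == "begin" else "post")
            _add_read_edge(g, outer, n, "extension", SpanSupport(rid, first, first))
        if last.query_len - last.q_end > allowance:
            n = _exit_node(last)
            outer = (n[0], "post" if n[1] == "end" else "pre")
            _add_read_edge(g, n, outer, "extension", SpanSupport(rid, last, last))
    return g


def _add_read_edge(g: nx.Graph, u: Node, v: Node, kind: str, support: SpanSupport):
    if g.has_edge(u, v):
        g[u][v]["kinds"].add(kind)
        g[u][v]["reads"].append(support)
    else:
        g.add_edge(u, v, kinds={kind}, reads=[support])


def span_edges(g: nx.Graph) -> List[Tuple[Node, Node, dict]]:
    return [
        (u, v, data)
        for u, v, data in g.edges(data=True)
        if "span" in data["kinds"]
    ]


def _support(data: dict) -> int:
    return len({s.read_id for s in data["reads"]})


# ---------------------------------------------------------------------------
# small-cycle repair
# ---------------------------------------------------------------------------

def _stepwise_paths(
    g: nx.Graph, u: Node, v: Node, max_skipped: int
) -> List[List[Node]]:
    """Paths u -> v alternating span and contig edges with <= max_skipped
    intermediate contigs, not using the direct edge {u, v}."""
    results = []

    def walk(node: Node, path: List[Node], skipped: int):
        if skipped > max_skipped:
            return
        for nbr in g.neighbors(node):
            data = g[node][nbr]
            if "span" not in data["kinds"] and "input_gap" not in data["kinds"]:
                continue
            if {node, nbr} == {u, v} and len(path) == 1:
                continue  # the skipping edge itself
            if nbr == v:
                results.append(path + [nbr])
                continue
            if nbr[0] in {p[0] for p in path}:
                continue
            # traverse the intermediate contig to its other side
            other = (nbr[0], "end" if nbr[1] == "begin" else "begin")
            walk(other, path + [nbr, other], skipped + 1)

    walk(u, [u], 0)
    return results


def resolve_small_cycles(
    g: nx.Graph,
    reads: Dict[str, str],
    assembly: Assembly,
    config: Optional[PipelineConfig] = None,
    max_skipped: int = 3,
) -> nx.Graph:
    """Repair edges that skip small contigs.

    For each span edge parallel to a stepwise path through <= max_skipped
    intermediate contigs, every skipping read is re-aligned to the skipped
    contigs at increased sensitivity (error ceiling +5 points, halved
    seeds).  On success its support is rewritten onto the stepwise edges;
    on failure the read is dropped from the skipping edge.
    """
    cfg = config or PipelineConfig()
    for u, v, data in list(span_edges(g)):
        if not g.has_edge(u, v) or "span" not in g[u][v]["kinds"]:
            continue
        if "input_gap" in g[u][v]["kinds"]:
            # the input scaffolding asserts these contigs are adjacent;
            # such an edge cannot be skipping intermediate contigs
            continue
        paths = _stepwise_paths(g, u, v, max_skipped)
        paths = [p for p in paths if len(p) > 2]
        if not paths:
            continue
        path = min(paths, key=len)
        intermediates = []
        for i in range(1, len(path) - 1, 2):
            intermediates.append(path[i][0])
        intermediates = list(dict.fromkeys(intermediates))
        if not intermediates:
            continue
        # a read can only have skipped contigs it could completely cover
        longest_read = max(
            (s.aln_first.query_len for s in g[u][v]["reads"]), default=0
        )
        if any(
            len(assembly.contig(cid)) > longest_read for cid in intermediates
        ):
            continue
        targets = {cid: assembly.contig(cid).seq for cid in intermediates}
        sensitive = Aligner(
            targets,
            k=max(8, cfg.seed_k - 4),
            max_err=min(0.95, cfg.max_alignment_error + 0.05),
            min_length=min(cfg.min_alignment_length, 200),
            min_seeds=3,
        )
        for sup in g[u][v]["reads"]:
            seq = reads.get(sup.read_id)
            new_alns: List[LocalAlignment] = []
            if seq is not None:
                # the skipped contigs must lie between the read's two
                # flanking alignments; only that segment is re-aligned
                lo = max(0, min(sup.aln_first.q_end, sup.aln_second.q_end) - 200)
                hi = min(
                    len(seq),
                    max(sup.aln_first.q_begin, sup.aln_second.q_begin) + 200,
                )
                if hi > lo:
                    for a in sensitive.map_sequence(sup.read_id, seq[lo:hi]):
                        new_alns.append(
                            LocalAlignment(
                                query_id=a.query_id,
                                query_len=len(seq),
                                q_begin=a.q_begin + lo,
                                q_end=a.q_end + lo,
                                target_id=a.target_id,
                                target_len=a.target_len,
                                t_begin=a.t_begin,
                                t_end=a.t_end,
                                strand=a.strand,
                                n_match=a.n_match,
                                trace=a.trace,
                            )
                        )
            hit_ids = {a.target_id for a in new_alns}
            if seq is not None and all(c in hit_ids for c in intermediates):
                # rewrite the read's evidence onto the stepwise edges
                chain = sorted(
                    [sup.aln_first, sup.aln_second] + new_alns,
                    key=lambda a: (a.q_begin, a.q_end),
                )
                for a, b in zip(chain, chain[1:]):
                    nu, nv = _exit_node(a), _entry_node(b)
                    if nu[0] == nv[0]:
                        continue
                    _add_read_edge(g, nu, nv, "span", SpanSupport(sup.read_id, a, b))
            # on re-alignment failure the read is discarded entirely
        g[u][v]["reads"] = []
        g[u][v]["kinds"].discard("span")
        if not g[u][v]["kinds"]:
            g.remove_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# conflict resolution
# ---------------------------------------------------------------------------

def resolve_conflicts(
    g: nx.Graph,
    margin: float = 3.0,
    gap_bonus: float = 6.0,
) -> nx.Graph:
    """Keep, at every contig end with competing span edges, the dominant
    edge — effective support (read count, times ``gap_bonus`` for edges
    coinciding with an input gap) at least ``margin`` times every
    competitor's — or delete them all."""
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if node[1] not in ("begin", "end"):
                continue
            incident = [
                (nbr, g[node][nbr])
                for nbr in g.neighbors(node)
                if "span" in g[node][nbr]["kinds"] and _support(g[node][nbr]) > 0
            ]
            if len(incident) < 2:
                continue
            scored = [
                (
                    _support(data) * (gap_bonus if "input_gap" in data["kinds"] else 1.0),
                    nbr,
                    data,
                )
                for nbr, data in incident
            ]
            scored.sort(key=lambda x: -x[0])
            best, runner = scored[0][0], scored[1][0]
            losers = scored[1:] if best >= margin * runner else scored
            for _, nbr, data in losers:
                data["reads"] = []
                data["kinds"].discard("span")
                if not data["kinds"]:
                    g.remove_edge(node, nbr)
            changed = True
    return g


# ---------------------------------------------------------------------------
# pile-up collection
# ---------------------------------------------------------------------------

def prune_and_collect(
    g: nx.Graph,
    min_spanning_reads: int = 3,
) -> List[PileUp]:
    """Drop weak span edges and collect one pile-up per survivor, merged
    with the extension reads of the two flanking contig ends."""
    pileups: List[PileUp] = []
    for u, v, data in span_edges(g):
        if _support(data) < min_spanning_reads:
            data["reads"] = []
            data["kinds"].discard("span")
            continue
        if u[1] == "end" and v[1] == "begin":
            left, right = u, v
        elif v[1] == "end" and u[1] == "begin":
            left, right = v, u
        else:
            left, right = (u, v) if u <= v else (v, u)
        # orient supports so aln_first maps the 'left' node's contig
        supports = []
        for s in data["reads"]:
            if _exit_node(s.aln_first) == left:
                supports.append(s)
            else:
                supports.append(SpanSupport(s.read_id, s.aln_second, s.aln_first))
        pileup = PileUp(
            left=left,
            right=right,
            spanning=supports,
            is_input_gap="input_gap" in data["kinds"],
            input_gap_length=data.get("gap_length"),
        )
        span_ids = {s.read_id for s in supports}
        for node, bucket in ((left, pileup.ext_left), (right, pileup.ext_right)):
            outer = (node[0], "post" if node[1] == "end" else "pre")
            if g.has_edge(node, outer) and "extension" in g[node][outer]["kinds"]:
                for s in g[node][outer]["reads"]:
                    if s.read_id not in span_ids:
                        bucket.append((s.read_id, s.aln_first))
        pileups.append(pileup)
    pileups.sort(key=lambda p: p.gap_id)
    return pileups


def dump_edges(g: nx.Graph, path) -> None:
    """Tabular edge list for debugging (TSV)."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\ttypes\tsupport\tread_ids\n")
        for u, v, data in sorted(g.edges(data=True)):
            rids = ",".join(sorted({s.read_id for s in data["reads"]}))
            fh.write(
                f"{u[0]}:{u[1]}\t{v[0]}:{v[1]}\t"
                f"{'+'.join(sorted(data['kinds']))}\t"
                f"{len({s.read_id for s in data['reads']})}\t{rids}\n"
            )
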