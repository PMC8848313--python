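"""From pile-up to insertion: cropping, chaining, QV, consensus, anchors.

Reads of a pile-up are cropped so that all alignments start and end at
common reference positions and co-oriented left-to-right across the gap.
Read-to-read local alignments are chained by solving a shortest-path
problem on a DAG: each local alignment is a node with negative weight
(mean bp covered on the two reads); compatible pairs are joined by edges
weighted gapSizeDiff + 0.1 * max(|gap_A|, |gap_B|).  Per-window intrinsic
quality values pick the reference read; a windowed majority vote over the
chained reads (column-wise plurality when no window string has a
majority) yields the consensus, which is finally anchored into the
flanking contigs at exact-match runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .align import LocalAlignment, align_pair, parse_cigar
from .assembly import Assembly, reverse_complement
from .config import PipelineConfig
from .graph import Node, PileUp, SpanSupport, _entry_node, _exit_node

__all__ = [
    "CroppedRead",
    "CroppedPileUp",
    "AlignmentChain",
    "Insertion",
    "crop_pileup",
    "chain_alignments",
    "intrinsic_qv",
    "select_reference_read",
    "consensus",
    "anchor_insertion",
    "build_insertion",
]


@dataclass
class CroppedRead:
    read_id: str
    seq: str  # pile-up orientation (left flank -> gap -> right flank)
    kind: str  # 'span' | 'ext_left' | 'ext_right'


@dataclass
class CroppedPileUp:
    gap_id: str
    left: Node
    right: Node
    pos_left: int  # crop position, left contig coordinates
    pos_right: int
    left_len: int  # flanking contig lengths
    right_len: int
    left_flank: str  # pile-up orientation
    right_flank: str
    reads: List[CroppedRead]
    is_input_gap: bool = False
    input_gap_length: Optional[int] = None

    @property
    def spanning_reads(self) -> List[CroppedRead]:
        return [r for r in self.reads if r.kind == "span"]


@dataclass
class AlignmentChain:
    alignments: List[LocalAlignment]
    score: float

    @property
    def aligned_bp(self) -> int:
        return sum(
            (a.query_span + a.target_span) // 2 for a in self.alignments
        )


@dataclass
class Insertion:
    """A consensus sequence anchored into two contig ends."""

    gap_id: str
    left_contig: str
    left_side: str  # 'end' | 'begin' — side of the left contig facing the gap
    right_contig: str
    right_side: str
    cut_left: int  # cut position in the left contig's gap-facing orientation
    cut_right: int
    core: str  # inserted bases, pile-up orientation
    is_input_gap: bool = False
    input_gap_length: Optional[int] = None
    n_reads: int = 0
    validated: str = "pending"  # 'pending' | 'pass' | 'fail'
    fail_reason: str = ""


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def _read_direction(sup: SpanSupport, left: Node) -> str:
    """'+' if the read traverses the pile-up left-to-right."""
    return "+" if _exit_node(sup.aln_first) == left else "-"


def crop_pileup(
    pileup: PileUp,
    assembly: Assembly,
    reads: Dict[str, str],
    config: Optional[PipelineConfig] = None,
    max_flank: int = 800,
) -> Optional[CroppedPileUp]:
    """Crop all pile-up reads to common reference positions on each flank.

    The crop positions keep as much flank overlap as possible while being
    reachable by every spanning read; reads preventing a minimal usable
    flank are dropped (down to min_spanning_reads), and any read whose
    alignment does not reach the final positions is dropped.
    """
    cfg = config or PipelineConfig()
    min_flank = max(cfg.anchor_exact_run * 2, cfg.min_anchor_length // 2)
    left_contig = assembly.contig(pileup.left[0])
    right_contig = assembly.contig(pileup.right[0])
    lside, rside = pileup.left[1], pileup.right[1]

    spans = list(pileup.spanning)

    def left_reach(a: LocalAlignment) -> int:
        # flank overlap available on the left contig, in U_L orientation
        return len(left_contig) - a.t_begin if lside == "end" else a.t_end

    def right_reach(a: LocalAlignment) -> int:
        return a.t_end if rside == "begin" else len(right_contig) - a.t_begin

    # drop worst offenders while a usable flank is impossible
    while len(spans) > cfg.min_spanning_reads:
        lmin = min(left_reach(s.aln_first) for s in spans)
        rmin = min(right_reach(s.aln_second) for s in spans)
        if lmin >= min(min_flank, len(left_contig) - 1) and rmin >= min(
            min_flank, len(right_contig) - 1
        ):
            break
        worst = min(
            spans,
            key=lambda s: min(left_reach(s.aln_first), right_reach(s.aln_second)),
        )
        spans.remove(worst)
    if len(spans) < max(1, cfg.min_spanning_reads if not cfg.allow_single_reads else 1):
        return None

    flank_left = min(max_flank, min(left_reach(s.aln_first) for s in spans))
    flank_right = min(max_flank, min(right_reach(s.aln_second) for s in spans))
    if flank_left <= 0 or flank_right <= 0:
        return None

    # crop positions in contig coordinates
    pos_left = (
        len(left_contig) - flank_left if lside == "end" else flank_left
    )
    pos_right = flank_right if rside == "begin" else len(right_contig) - flank_right

    left_flank = (
        left_contig.seq[pos_left:]
        if lside == "end"
        else reverse_complement(left_contig.seq[:pos_left])
    )
    right_flank = (
        right_contig.seq[:pos_right]
        if rside == "begin"
        else reverse_complement(right_contig.seq[pos_right:])
    )

    cropped: List[CroppedRead] = []
    for s in spans:
        seq = reads[s.read_id]
        if not _covers(s.aln_first, pos_left) or not _covers(s.aln_second, pos_right):
            continue
        q1 = s.aln_first.project_target_to_query(pos_left)
        q2 = s.aln_second.project_target_to_query(pos_right)
        lo, hi = (q1, q2) if q1 <= q2 else (q2, q1)
        if hi <= lo:
            continue
        piece = seq[lo:hi]
        if _read_direction(s, pileup.left) == "-":
            piece = reverse_complement(piece)
        cropped.append(CroppedRead(s.read_id, piece, "span"))

    for rid, aln in pileup.ext_left:
        seq = reads.get(rid)
        if seq is None or not _covers(aln, pos_left):
            continue
        q = aln.project_target_to_query(pos_left)
        fwd = _exit_node(aln) == pileup.left
        piece = seq[q:] if fwd else reverse_complement(seq[:q])
        if len(piece) > 0:
            cropped.append(CroppedRead(rid, piece, "ext_left"))
    for rid, aln in pileup.ext_right:
        seq = reads.get(rid)
        if seq is None or not _covers(aln, pos_right):
            continue
        q = aln.project_target_to_query(pos_right)
        fwd = _entry_node(aln) == pileup.right
        piece = seq[:q] if fwd else reverse_complement(seq[q:])
        if len(piece) > 0:
            cropped.append(CroppedRead(rid, piece, "ext_right"))

    if not any(r.kind == "span" for r in cropped):
        return None
    gap_id = f"{pileup.left[0]}({lside})--{pileup.right[0]}({rside})"
    return CroppedPileUp(
        gap_id=gap_id,
        left=pileup.left,
        right=pileup.right,
        pos_left=pos_left,
        pos_right=pos_right,
        left_len=len(left_contig),
        right_len=len(right_contig),
        left_flank=left_flank,
        right_flank=right_flank,
        reads=cropped,
        is_input_gap=pileup.is_input_gap,
        input_gap_length=pileup.input_gap_length,
    )


def _covers(aln: LocalAlignment, pos: int) -> bool:
    return aln.t_begin <= pos <= aln.t_end


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _gaps(x: LocalAlignment, y: LocalAlignment) -> Tuple[int, int]:
    gap_a = y.q_begin - x.q_end
    gap_b = y.t_begin - x.t_end
    return gap_a, gap_b


def chainable(
    x: LocalAlignment,
    y: LocalAlignment,
    max_indel: int = 1000,
    max_chain_gap: int = 10000,
    max_relative_overlap: float = 0.3,
) -> bool:
    """The four chainability rules for ordered local alignments x, y."""
    if x.strand != y.strand:
        return False
    if not (x.q_begin < y.q_begin and x.t_begin < y.t_begin):
        return False
    gap_a, gap_b = _gaps(x, y)
    if abs(gap_a - gap_b) >= max_indel:
        return False
    if gap_a >= max_chain_gap or gap_b >= max_chain_gap:
        return False
    ov_a = max(0, -gap_a) / max(1, min(x.query_span, y.query_span))
    ov_b = max(0, -gap_b) / max(1, min(x.target_span, y.target_span))
    if max(ov_a, ov_b) > max_relative_overlap:
        return False
    return True


def node_weight(a: LocalAlignment) -> float:
    """Negative (beneficial) weight: mean bp covered on the two reads."""
    return -(a.query_span + a.target_span) / 2.0


def edge_weight(x: LocalAlignment, y: LocalAlignment) -> float:
    gap_a, gap_b = _gaps(x, y)
    return abs(gap_a - gap_b) + 0.1 * max(abs(gap_a), abs(gap_b))


def chain_alignments(
    local_alns: Sequence[LocalAlignment],
    max_indel: int = 1000,
    max_chain_gap: int = 10000,
    max_relative_overlap: float = 0.3,
) -> List[AlignmentChain]:
    """Best chain(s) of the local alignments between one read pair.

    Minimum-total-weight paths in the chainability DAG; the single best
    chain after tie-breaking (smaller score, then more aligned bp, then
    leftmost start) is returned (empty input -> empty list).
    """
    alns = sorted(local_alns, key=lambda a: (a.q_begin, a.q_end, a.t_begin))
    n = len(alns)
    if n == 0:
        return []
    dp = [node_weight(a) for a in alns]
    back: List[Optional[int]] = [None] * n
    for j in range(n):
        for i in range(j):
            if chainable(
                alns[i], alns[j], max_indel, max_chain_gap, max_relative_overlap
            ):
                cand = dp[i] + edge_weight(alns[i], alns[j]) + node_weight(alns[j])
                if cand < dp[j] - 1e-12:
                    dp[j] = cand
                    back[j] = i

    def trace(j: int) -> List[LocalAlignment]:
        path = []
        k: Optional[int] = j
        while k is not None:
            path.append(alns[k])
            k = back[k]
        return path[::-1]

    candidates = [AlignmentChain(trace(j), dp[j]) for j in range(n)]
    best = min(
        candidates,
        key=lambda c: (
            round(c.score, 9),
            -c.aligned_bp,
            c.alignments[0].q_begin,
            c.alignments[0].t_begin,
        ),
    )
    return [best]


# ---------------------------------------------------------------------------
# intrinsic quality values
# ---------------------------------------------------------------------------

WORST_QV = 1.0


def intrinsic_qv(
    read_lens: Dict[str, int],
    chains: Dict[Tuple[str, str], AlignmentChain],
    window: int = 100,
) -> Dict[str, np.ndarray]:
    """Per-read, per-window difference rates from the chained alignments.

    The QV of a window is the mean per-base difference rate of all chained
    alignments covering it; windows covered by no alignment get the worst
    QV (1.0).  Chains map (query read, target read) -> best chain.
    """
    err = {
        rid: np.zeros((len(range(0, max(1, n), window)),), dtype=np.float64)
        for rid, n in read_lens.items()
    }
    cov = {rid: np.zeros_like(e) for rid, e in err.items()}

    def add(rid: str, pos: int, n_bases: int, n_err: int) -> None:
        # distribute a run over the read's windows
        e, c = err[rid], cov[rid]
        while n_bases > 0 or n_err > 0:
            w = min(pos // window, len(e) - 1)
            room = (w + 1) * window - pos
            take = min(n_bases, room) if n_bases else 0
            frac = take / n_bases if n_bases else 1.0
            e[w] += n_err * frac
            c[w] += take
            n_err -= round(n_err * frac)
            n_bases -= take
            pos += take
            if take == 0:
                break

    for (qid, tid), chain in chains.items():
        for a in chain.alignments:
            qpos, tpos = a.q_begin, a.t_begin
            for n, op in parse_cigar(a.trace):
                if op == "=":
                    add(qid, qpos, n, 0)
                    add(tid, tpos, n, 0)
                    qpos += n
                    tpos += n
                elif op == "X":
                    add(qid, qpos, n, n)
                    add(tid, tpos, n, n)
                    qpos += n
                    tpos += n
                elif op == "I":
                    add(qid, qpos, n, n)
                    add(tid, tpos, 0, n)
                    qpos += n
                elif op == "D":
                    add(qid, qpos, 0, n)
                    add(tid, tpos, n, n)
                    tpos += n

    qvs: Dict[str, np.ndarray] = {}
    for rid in read_lens:
        with np.errstate(invalid="ignore", divide="ignore"):
            q = err[rid] / cov[rid]
        q[~np.isfinite(q)] = WORST_QV
        qvs[rid] = np.minimum(q, WORST_QV)
    return qvs


def select_reference_read(
    qvs: Dict[str, np.ndarray],
    read_lens: Dict[str, int],
    bad_fraction: float = 0.08,
    candidates: Optional[Sequence[str]] = None,
) -> str:
    """Read with the fewest bad QV windows.

    A window QV is bad if it is among the worst ``bad_fraction`` of all
    window QVs pooled over the pile-up.  Ties prefer the longer read,
    then the lexicographically smaller id.
    """
    pool = np.concatenate([qvs[r] for r in sorted(qvs)])
    threshold = float(np.quantile(pool, 1.0 - bad_fraction))
    cands = sorted(candidates) if candidates is not None else sorted(qvs)
    if not cands:
        raise ValueError("no candidate reads")
    return min(
        cands,
        key=lambda r: (int(np.sum(qvs[r] > threshold)), -read_lens[r], r),
    )


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _expand_columns(
    aln: LocalAlignment, read_seq: str, ref_seq: Optional[str] = None
) -> Tuple[List[str], List[int]]:
    """Alignment as per-column (query char | '', ref position | -1)."""
    qcol: List[str] = []
    tpos_col: List[int] = []
    qpos, tpos = aln.q_begin, aln.t_begin
    for n, op in parse_cigar(aln.trace):
        if op in "=X":
            for i in range(n):
                qcol.append(read_seq[qpos + i])
                tpos_col.append(tpos + i)
            qpos += n
            tpos += n
        elif op == "D":
            for i in range(n):
                qcol.append("")
                tpos_col.append(tpos + i)
            tpos += n
        elif op == "I":
            for i in range(n):
                qcol.append(read_seq[qpos + i])
                tpos_col.append(-1)
            qpos += n
    return qcol, tpos_col


def _left_normalize(qcol: List[str], tpos_col: List[int], ref_seq: str) -> None:
    """Shift indels leftwards (homopolymer-normalize) in place.

    Without this, equivalent alignments place the same indel at
    different columns in different reads, splitting the vote."""
    n = len(qcol)
    for i in range(1, n):
        j = i
        if qcol[j] == "" and tpos_col[j] >= 0:
            # deletion: shift left while adjacent reference chars repeat
            while (
                j > 0
                and qcol[j - 1] != ""
                and tpos_col[j - 1] >= 0
                and ref_seq[tpos_col[j - 1]] == ref_seq[tpos_col[j]]
            ):
                # swap the gap with the (match) column to its left
                qcol[j] = qcol[j - 1]
                qcol[j - 1] = ""
                j -= 1
        elif qcol[j] != "" and tpos_col[j] == -1:
            # insertion: shift left while adjacent query chars repeat
            while (
                j > 0
                and tpos_col[j - 1] >= 0
                and qcol[j - 1] != ""
                and qcol[j - 1] == qcol[j]
            ):
                tpos_col[j] = tpos_col[j - 1]
                tpos_col[j - 1] = -1
                j -= 1


def _replacement_strings(
    ref_len: int, aln: LocalAlignment, read_seq: str, ref_seq: Optional[str] = None
) -> Dict[int, str]:
    """Per-reference-position realization of one read under a chained
    alignment (query = read, target = reference read).  Insertions attach
    to the preceding reference position; indels are left-normalized when
    the reference sequence is available."""
    qcol, tpos_col = _expand_columns(aln, read_seq)
    if ref_seq is not None:
        _left_normalize(qcol, tpos_col, ref_seq)
    repl: Dict[int, str] = {}
    last_t = aln.t_begin
    for q, t in zip(qcol, tpos_col):
        if t >= 0:
            repl[t] = repl.get(t, "") + q
            last_t = t
        else:  # insertion: attach to the preceding reference position
            repl[last_t] = repl.get(last_t, "") + q
    return repl


class _POA:
    """Minimal partial-order alignment graph for short window strings.

    Strings are aligned one by one to the growing DAG (match +2,
    mismatch -2, gap -2); matching characters fuse into existing nodes
    and traversed edges gain weight.  The consensus is the heaviest edge
    path.  This resolves indel evidence that per-column voting splits
    between alignment forms: however a read's aligner phrased an extra
    or missing base, its path through the graph supports the same edges.
    """

    def __init__(self) -> None:
        self.chars: List[str] = []
        self.out: List[Dict[int, int]] = []
        self.inn: List[Dict[int, int]] = []
        self.starts: Dict[int, int] = {}  # start node -> weight
        self.n_seqs = 0  # weighted sequences added

    def _new_node(self, ch: str) -> int:
        self.chars.append(ch)
        self.out.append({})
        self.inn.append({})
        return len(self.chars) - 1

    def _topo(self) -> List[int]:
        n = len(self.chars)
        indeg = [len(self.inn[v]) for v in range(n)]
        stack = [v for v in range(n) if indeg[v] == 0]
        order: List[int] = []
        while stack:
            v = stack.pop()
            order.append(v)
            for w in self.out[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        return order

    def add(self, s: str, weight: int = 1) -> None:
        if not s:
            return
        self.n_seqs += weight
        if not self.chars:
            prev = None
            for ch in s:
                v = self._new_node(ch)
                if prev is None:
                    self.starts[v] = self.starts.get(v, 0) + weight
                else:
                    self.out[prev][v] = self.out[prev].get(v, 0) + weight
                    self.inn[v][prev] = self.out[prev][v]
                prev = v
            return
        path = self._align(s)
        prev = None
        for j, node in enumerate(path):
            if node is None:
                node = self._new_node(s[j])
                path[j] = node
            if prev is None:
                self.starts[node] = self.starts.get(node, 0) + weight
            else:
                self.out[prev][node] = self.out[prev].get(node, 0) + weight
                self.inn[node][prev] = self.out[prev][node]
            prev = node

    def _align(self, s: str) -> List[Optional[int]]:
        """Align s to the graph; returns, per char of s, the node id to
        fuse into (None where a new node is needed).

        DP over (topo-ordered node rows + a virtual source row) x string
        positions; match +2, mismatch/gap -2; the graph end is free (all
        window strings share anchored boundaries, so real paths end
        together and the slack is harmless).
        """
        MATCH, MIS, GAP = 2, -2, -2
        m = len(s)
        order = self._topo()
        pos_of = {v: i for i, v in enumerate(order)}
        NEG = float("-inf")
        src = [GAP * j for j in range(m + 1)]  # virtual source row
        dp = [[NEG] * (m + 1) for _ in order]
        # bt entries: (pred_row (-1 = source), pred_j, kind) kind: 1 diag,
        # 0 node-skip, 2 char-insert
        bt: List[List[Tuple[int, int, int]]] = [
            [(-1, 0, -1)] * (m + 1) for _ in order
        ]
        for i, v in enumerate(order):
            ch = self.chars[v]
            pred_rows = [pos_of[p] for p in self.inn[v]]
            rows = pred_rows + ([-1] if v in self.starts or not self.inn[v] else [])
            for j in range(m + 1):
                best, arg = NEG, (-1, 0, -1)
                if j > 0:
                    sc = MATCH if s[j - 1] == ch else MIS
                    for pi in rows:
                        base = src[j - 1] if pi == -1 else dp[pi][j - 1]
                        if base != NEG and base + sc > best:
                            best, arg = base + sc, (pi, j - 1, 1)
                for pi in rows:  # node consumed without a char
                    base = src[j] if pi == -1 else dp[pi][j]
                    if base != NEG and base + GAP > best:
                        best, arg = base + GAP, (pi, j, 0)
                if j > 0 and dp[i][j - 1] != NEG:  # char consumed, no node
                    if dp[i][j - 1] + GAP > best:
                        best, arg = dp[i][j - 1] + GAP, (i, j - 1, 2)
                dp[i][j] = best
                bt[i][j] = arg
        path: List[Optional[int]] = [None] * m
        if not order:
            return path
        end_i = max(range(len(order)), key=lambda i: dp[i][m])
        if dp[end_i][m] == NEG:
            return path
        i, j = end_i, m
        while i != -1:
            pi, pj, kind = bt[i][j]
            if kind == 1 and s[j - 1] == self.chars[order[i]]:
                path[j - 1] = order[i]
            i, j = pi, pj
        return path

    def consensus(self) -> str:
        """Heaviest start-to-sink edge path.

        Each traversed edge pays a depth-scaled toll, so a detour through
        spurious extra nodes (each edge supported by few reads) cannot
        out-score the direct, well-supported edge — plain weight sums
        would favour longer paths.
        """
        if not self.chars:
            return ""
        toll = 0.55 * self.n_seqs
        order = self._topo()
        NEG = float("-inf")
        best: Dict[int, float] = {}
        prev: Dict[int, Optional[int]] = {}
        for v in order:
            w = float(self.starts[v]) - toll if v in self.starts else NEG
            p: Optional[int] = None
            for u, ew in self.inn[v].items():
                if best.get(u, NEG) != NEG and best[u] + ew - toll > w:
                    w = best[u] + ew - toll
                    p = u
            best[v] = w
            prev[v] = p
        sinks = [v for v in order if not self.out[v] and best[v] != NEG]
        if not sinks:
            sinks = [v for v in order if best[v] != NEG]
        if not sinks:
            return ""
        end = max(sinks, key=lambda v: best[v])
        chars = []
        node: Optional[int] = end
        while node is not None:
            chars.append(self.chars[node])
            node = prev[node]
        return "".join(chars[::-1])


def _poa_window(strings: List[str], backbone: str) -> Optional[str]:
    if len(strings) < 3:
        return None
    poa = _POA()
    poa.add(backbone, weight=0)
    for s in sorted(strings):
        if s:
            poa.add(s, weight=1)
    cons = poa.consensus()
    return cons or None


def _vote(
    reference_seq: str,
    projections: List[Tuple[Dict[int, str], Tuple[int, int]]],
    window: int = 100,
    max_segment: int = 150,
    clean_frac: float = 0.7,
    poa_frac: float = 0.35,
) -> str:
    """Anchor-segmented consensus vote.

    Columns where a single base holds >= 80% of the votes are *clean*
    anchors and emitted directly.  Runs of unclean columns — where read
    errors make aligners phrase the same variant differently, splitting
    per-column votes — are voted as whole anchored segment strings,
    which captures indels atomically; segments whose strings are all
    distinct fall back to a small partial-order alignment.  ``window``
    caps nothing here and is kept for interface stability; segments
    longer than ``max_segment`` keep their column-plurality result.
    """
    ref_len = len(reference_seq)
    if ref_len == 0:
        return ""
    col_votes: List[Dict[str, int]] = [dict() for _ in range(ref_len)]
    cover = [0] * ref_len
    for repl, (lo, hi) in projections:
        for p in range(max(0, lo), min(ref_len, hi)):
            s = repl.get(p, "")
            cv = col_votes[p]
            cv[s] = cv.get(s, 0) + 1
            cover[p] += 1

    winner: List[str] = [""] * ref_len
    clean = [False] * ref_len
    for p in range(ref_len):
        ref_s = reference_seq[p]
        cv = col_votes[p]
        cv[ref_s] = cv.get(ref_s, 0) + 1  # the reference read's own vote
        win, win_n = max(cv.items(), key=lambda kv: (kv[1], kv[0] == ref_s, kv[0]))
        total = cover[p] + 1
        winner[p] = win
        clean[p] = len(win) == 1 and win_n >= clean_frac * total and win_n >= 3

    out: List[str] = []
    p = 0
    while p < ref_len:
        if clean[p]:
            out.append(winner[p])
            p += 1
            continue
        # dirty run [p, b); the clean column p-1 (if any) joins as the
        # left anchor — insertions attach leftwards, so it carries the
        # run's insertion evidence
        b = p
        while b < ref_len and not clean[b]:
            b += 1
        a = p - 1 if p > 0 else p
        seg_cols = range(a, b)
        ref_seg = reference_seq[a:b]
        if a < p:
            out.pop()  # that anchor was emitted as a single clean char
        strings = [ref_seg]
        for repl, (lo, hi) in projections:
            if lo <= a and hi >= b:
                strings.append("".join(repl.get(q, "") for q in seg_cols))
        counts: Dict[str, int] = {}
        for s in strings:
            counts[s] = counts.get(s, 0) + 1
        best, best_n = max(
            counts.items(), key=lambda kv: (kv[1], kv[0] == ref_seg, kv[0])
        )
        if best_n < poa_frac * len(strings) and len(ref_seg) <= max_segment:
            column_fallback = "".join(winner[q] for q in seg_cols)
            if len(strings) >= 4:
                poa = _poa_window(strings[1:15], column_fallback)
                best = poa if poa is not None else column_fallback
            elif best_n == 1:
                best = column_fallback
        elif best_n == 1:
            best = "".join(winner[q] for q in seg_cols)
        out.append(best)
        p = b
    return "".join(out)


def consensus(
    reference_seq: str,
    reference_id: str,
    read_seqs: Dict[str, str],
    chains: Dict[Tuple[str, str], AlignmentChain],
    window: int = 100,
    refine_rounds: int = 3,
    read_kinds: Optional[Dict[str, str]] = None,
    max_vote_error: float = 0.45,
) -> str:
    """Reference-guided windowed majority consensus.

    Every read is projected onto reference coordinates through its best
    chain; per reference window the majority window string wins, and
    without a strict majority column-wise plurality decides.  The
    reference read votes with its own sequence, and windows covered by
    no other read use the reference verbatim.

    Because votes are conditioned on alignments against the error-laden
    reference, indel placement jitters and caps the attainable accuracy;
    ``refine_rounds`` additional rounds re-align every read directly to
    the current consensus (globally for spanning reads, end-anchored for
    extension reads) and vote again, which removes most of that jitter.
    """
    projections: List[Tuple[Dict[int, str], Tuple[int, int]]] = []
    ref_len = len(reference_seq)
    for (qid, tid), chain in chains.items():
        if tid != reference_id or qid == reference_id:
            continue
        repl: Dict[int, str] = {}
        lo, hi = ref_len, 0
        for a in chain.alignments:
            repl.update(
                _replacement_strings(ref_len, a, read_seqs[qid], reference_seq)
            )
            lo = min(lo, a.t_begin)
            hi = max(hi, a.t_end)
        if hi > lo:
            projections.append((repl, (lo, hi)))
    current = _vote(reference_seq, projections, window)

    kinds = read_kinds or {}
    for _ in range(refine_rounds):
        projections = []
        for rid, seq in read_seqs.items():
            if rid == reference_id and seq == current:
                continue
            proj = _project_onto(seq, current, kinds.get(rid, "span"), max_vote_error)
            if proj is not None:
                projections.append(proj)
        refined = _vote(current, projections, window)
        if refined == current:
            break
        current = refined
    return current


def _project_onto(
    read: str, target: str, kind: str, max_err: float
) -> Optional[Tuple[Dict[int, str], Tuple[int, int]]]:
    """Replacement strings of one read aligned directly to ``target``.

    Spanning reads cover the whole target (global alignment); extension
    reads anchor at the target start (ext_left) or end (ext_right)."""
    if not read or not target:
        return None
    if kind == "span":
        res = edlib.align(read, target, mode="NW", task="path")
        t_begin, t_end = 0, len(target)
        cigar = res["cigar"]
        q_begin = 0
    elif kind == "ext_left":
        res = edlib.align(read, target, mode="SHW", task="path")
        if not res["locations"]:
            return None
        t_begin, t_end = 0, res["locations"][0][1] + 1
        cigar = res["cigar"]
        q_begin = 0
    else:  # ext_right: anchor at the target's end via reversal
        res = edlib.align(read[::-1], target[::-1], mode="SHW", task="path")
        if not res["locations"]:
            return None
        consumed = res["locations"][0][1] + 1
        t_begin, t_end = len(target) - consumed, len(target)
        ops = parse_cigar(res["cigar"])[::-1]
        cigar = "".join(f"{n}{op}" for n, op in ops)
        q_begin = 0
    ops = parse_cigar(cigar)
    total = sum(n for n, _ in ops)
    dist = sum(n for n, op in ops if op != "=")
    if total == 0 or dist / total > max_err:
        return None
    aln = LocalAlignment(
        query_id="r",
        query_len=len(read),
        q_begin=q_begin,
        q_end=q_begin + sum(n for n, op in ops if op in "=XI"),
        target_id="t",
        target_len=len(target),
        t_begin=t_begin,
        t_end=t_end,
        strand="+",
        n_match=sum(n for n, op in ops if op == "="),
        trace=cigar,
    )
    repl = _replacement_strings(len(target), aln, read, target)
    return repl, (t_begin, t_end)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _anchor_one_side(
    flank: str,
    cons_window: str,
    k: int,
    min_span: int,
    max_err: float = 0.05,
    near_end: int = 100,
) -> Optional[int]:
    """Anchor a flank at the start of a consensus window.

    The insert site is the *contig end*: the flank is never trimmed, so
    contig sequence stays byte-identical.  The flank must align into the
    consensus at >= 95% identity with an exact run of >= k bp ending
    within ``near_end`` bp of the flank's gap-facing end — that run pins
    the junction unambiguously.  Returns the consensus position at which
    the flank ends (the insertion point), or None on failure.
    """
    if len(flank) < min_span or not cons_window:
        return None
    res = edlib.align(flank, cons_window, mode="SHW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    ops = parse_cigar(res["cigar"])
    total = sum(n for n, _ in ops)
    if total == 0 or res["editDistance"] / total > max_err:
        return None
    qpos = 0
    last_run_end = -1
    for n, op in ops:
        if op == "=" and n >= k:
            last_run_end = qpos + n
        if op in "=XI":
            qpos += n
    if last_run_end < len(flank) - near_end:
        return None
    return res["locations"][0][1] + 1


def anchor_insertion(
    cons: str,
    left_flank: str,
    right_flank: str,
    k: int = 24,
    min_anchor: int = 500,
) -> Optional[Tuple[int, int, int, int]]:
    """Locate insert sites at the flanking contig ends.

    Returns (flank_cut_left, cons_begin, cons_end, flank_cut_right);
    the flank cuts always equal the full flank lengths — contigs are not
    modified when closing a gap.  None if either consensus end fails to
    align to its flank (below 95% identity over at least min_anchor/2 bp,
    or no >= k bp exact run near the junction).
    """
    min_span = min(min_anchor // 2, len(left_flank), len(right_flank))
    margin = 200
    cons_b = _anchor_one_side(
        left_flank, cons[: len(left_flank) + margin], k, min_span
    )
    if cons_b is None:
        return None
    cons_e_rev = _anchor_one_side(
        right_flank[::-1],
        cons[::-1][: len(right_flank) + margin],
        k,
        min_span,
    )
    if cons_e_rev is None:
        return None
    cons_e = len(cons) - cons_e_rev
    if cons_e < cons_b:
        return None
    return len(left_flank), cons_b, cons_e, len(right_flank)


# ---------------------------------------------------------------------------
# full per-pile-up processing
# ---------------------------------------------------------------------------

def build_insertion(
    cropped: CroppedPileUp,
    config: Optional[PipelineConfig] = None,
) -> Optional[Insertion]:
    """Chain, vote, and anchor one cropped pile-up into an Insertion."""
    cfg = config or PipelineConfig()
    seqs = {r.read_id: r.seq for r in cropped.reads}
    lens = {rid: len(s) for rid, s in seqs.items()}
    ids = sorted(seqs)

    # pairwise alignment + chaining
    chains: Dict[Tuple[str, str], AlignmentChain] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            alns = align_pair(
                seqs[a],
                seqs[b],
                mode="local",
                max_err=min(0.95, 2 * cfg.max_alignment_error),
                query_id=a,
                target_id=b,
                k=cfg.seed_k,
                min_length=min(100, cfg.min_alignment_length),
                min_seeds=2,
            )
            alns = [x for x in alns if x.strand == "+"]
            best = chain_alignments(
                alns, cfg.max_indel, cfg.max_chain_gap, cfg.max_relative_overlap
            )
            if best:
                chains[(a, b)] = best[0]

    qvs = intrinsic_qv(lens, chains, window=cfg.qv_window)
    span_ids = [r.read_id for r in cropped.spanning_reads]
    ref_id = select_reference_read(
        qvs, lens, bad_fraction=cfg.bad_fraction, candidates=span_ids
    )

    # re-key chains so the reference read is always the target
    ref_chains: Dict[Tuple[str, str], AlignmentChain] = {}
    for (a, b), chain in chains.items():
        if b == ref_id:
            ref_chains[(a, b)] = chain
        elif a == ref_id:
            flipped = [_swap_alignment(x) for x in chain.alignments]
            ref_chains[(b, a)] = AlignmentChain(flipped, chain.score)
    cons = consensus(
        seqs[ref_id],
        ref_id,
        seqs,
        ref_chains,
        window=cfg.consensus_window,
        read_kinds={r.read_id: r.kind for r in cropped.reads},
    )

    anchors = anchor_insertion(
        cons,
        cropped.left_flank,
        cropped.right_flank,
        k=cfg.anchor_exact_run,
        min_anchor=cfg.min_anchor_length,
    )
    n_reads = len(cropped.reads)
    base = dict(
        gap_id=cropped.gap_id,
        left_contig=cropped.left[0],
        left_side=cropped.left[1],
        right_contig=cropped.right[0],
        right_side=cropped.right[1],
        is_input_gap=cropped.is_input_gap,
        input_gap_length=cropped.input_gap_length,
        n_reads=n_reads,
    )
    if anchors is None:
        return Insertion(
            cut_left=0, cut_right=0, core="", validated="fail",
            fail_reason="anchoring failed", **base
        )
    cut_l, cons_b, cons_e, cut_r = anchors
    # Convert flank cuts to gap-facing-orientation (U) contig coordinates.
    # U_L is the left contig oriented so the gap is on its right; its
    # flank is the suffix of U_L, so the cut (end of kept sequence) is
    # flank start + cut_l.  U_R has the gap on its left; kept is U_R[cut:].
    cut_left = cropped.left_len - len(cropped.left_flank) + cut_l
    cut_right = len(cropped.right_flank) - cut_r
    if not (0 < cut_left <= cropped.left_len) or not (
        0 <= cut_right < cropped.right_len
    ):
        return Insertion(
            cut_left=0, cut_right=0, core="", validated="fail",
            fail_reason="anchor outside contig", **base
        )
    return Insertion(
        cut_left=cut_left,
        cut_right=cut_right,
        core=cons[cons_b:cons_e],
        validated="pending",
        **base,
    )


def _swap_alignment(a: LocalAlignment) -> LocalAlignment:
    """Swap query and target of a '+'-strand traced alignment."""
    swapped_ops = [
        (n, {"I": "D", "D": "I"}.get(op, op)) for n, op in parse_cigar(a.trace)
    ]
    from .align import _ops_to_cigar

    return LocalAlignment(
        query_id=a.target_id,
        query_len=a.target_len,
        q_begin=a.t_begin,
        q_end=a.t_end,
        target_id=a.query_id,
        target_len=a.query_len,
        t_begin=a.q_begin,
        t_end=a.q_end,
        strand=a.strand,
        n_match=a.n_match,
        trace=_ops_to_cigar(swapped_ops),
    )
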