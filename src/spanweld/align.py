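"""Local alignments, CIGAR traces, PAF I/O, and the built-in aligner.

The aligner is a contract: anything producing traced local alignments at a
stated error ceiling will do.  The implementation here is a deterministic
seed-and-extend scheme — exact k-mer seeds clustered by diagonal, gap-free
anchors bridged with banded edit distance (edlib), forced extensions
trimmed back to the locally maximal alignment — adequate for genomes up to
a few megabases.

Conventions (PAF-compatible):

* query coordinates are always on the query's forward strand;
* target coordinates are always on the target's forward strand;
* the trace (extended CIGAR, ``= X I D``) is stored in alignment
  orientation: it consumes the target forward and, for ``-`` strand
  alignments, the reverse complement of the query.  ``I`` consumes query
  only, ``D`` target only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .assembly import reverse_complement
from .intervals import Interval

__all__ = [
    "LocalAlignment",
    "parse_cigar",
    "cigar_stats",
    "read_paf",
    "write_paf",
    "align_pair",
    "KmerIndex",
    "Aligner",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_CONSUMES_QUERY = frozenset("=XIM")
_CONSUMES_TARGET = frozenset("=XDM")


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if sum(len(str(n)) + 1 for n, _ in ops) != len(cigar):
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def cigar_stats(ops: Sequence[Tuple[int, str]]) -> Tuple[int, int, int, int]:
    """Return (query bases, target bases, matches, edit distance)."""
    q = t = match = dist = 0
    for n, op in ops:
        if op in _CONSUMES_QUERY:
            q += n
        if op in _CONSUMES_TARGET:
            t += n
        if op == "=":
            match += n
        elif op in "XID":
            dist += n
    return q, t, match, dist


def _ops_to_cigar(ops: Sequence[Tuple[int, str]]) -> str:
    merged: List[Tuple[int, str]] = []
    for n, op in ops:
        if n == 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged)


@dataclass
class LocalAlignment:
    """One local alignment between a query and a target sequence."""

    query_id: str
    query_len: int
    q_begin: int
    q_end: int
    target_id: str
    target_len: int
    t_begin: int
    t_end: int
    strand: str  # '+' or '-'
    n_match: int
    trace: str = ""  # extended CIGAR in alignment orientation
    tags: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.trace:
            q, t, match, _ = cigar_stats(parse_cigar(self.trace))
            if q != self.q_end - self.q_begin or t != self.t_end - self.t_begin:
                raise ValueError(
                    f"trace inconsistent with intervals for {self.query_id}->"
                    f"{self.target_id}: cigar ({q},{t}) vs "
                    f"({self.q_end - self.q_begin},{self.t_end - self.t_begin})"
                )

    # -- basic views ---------------------------------------------------
    @property
    def query_iv(self) -> Interval:
        return Interval(self.query_id, self.q_begin, self.q_end)

    @property
    def target_iv(self) -> Interval:
        return Interval(self.target_id, self.t_begin, self.t_end)

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_begin

    @property
    def target_span(self) -> int:
        return self.t_end - self.t_begin

    def alignment_length(self) -> int:
        if not self.trace:
            return max(self.query_span, self.target_span)
        return self._aln_len()

    def _aln_len(self) -> int:
        return sum(n for n, _ in parse_cigar(self.trace))

    def error_rate(self) -> float:
        if not self.trace:
            span = max(self.query_span, self.target_span)
            return 1.0 - self.n_match / span if span else 0.0
        ops = parse_cigar(self.trace)
        _, _, _, dist = cigar_stats(ops)
        total = sum(n for n, _ in ops)
        return dist / total if total else 0.0

    # -- coordinate projection ----------------------------------------
    def _cum(self) -> Tuple[np.ndarray, np.ndarray]:
        cached = getattr(self, "_cum_cache", None)
        if cached is not None:
            return cached
        ops = parse_cigar(self.trace)
        qadv = np.fromiter(
            (n if op in _CONSUMES_QUERY else 0 for n, op in ops), dtype=np.int64
        )
        tadv = np.fromiter(
            (n if op in _CONSUMES_TARGET else 0 for n, op in ops), dtype=np.int64
        )
        cum = (np.concatenate(([0], np.cumsum(qadv))), np.concatenate(([0], np.cumsum(tadv))))
        self._cum_cache = cum
        return cum

    def _aln_q_begin(self) -> int:
        """Alignment-orientation query start (on revcomp for '-' strand)."""
        if self.strand == "+":
            return self.q_begin
        return self.query_len - self.q_end

    def project_target_to_query(self, t_pos: int) -> int:
        """Map a target position inside the alignment to a forward-strand
        query position (nearest aligned boundary; clips to the alignment)."""
        if not self.trace:
            # linear interpolation fallback
            frac = (min(max(t_pos, self.t_begin), self.t_end) - self.t_begin) / max(
                1, self.target_span
            )
            q_aln = self._aln_q_begin() + round(frac * self.query_span)
        else:
            qcum, tcum = self._cum()
            off = min(max(t_pos, self.t_begin), self.t_end) - self.t_begin
            i = int(np.searchsorted(tcum, off, side="left"))
            if i > 0 and tcum[i] != off:
                i -= 1
                # inside run i: advance query proportionally within the run
                run_t = tcum[i + 1] - tcum[i]
                run_q = qcum[i + 1] - qcum[i]
                extra = off - tcum[i]
                q_off = qcum[i] + (extra if run_q == run_t else min(extra, run_q))
            else:
                q_off = qcum[i]
            q_aln = self._aln_q_begin() + int(q_off)
        if self.strand == "+":
            return q_aln
        return self.query_len - q_aln

    def project_query_to_target(self, q_pos: int) -> int:
        """Map a forward-strand query position to a target position."""
        if self.strand == "+":
            q_aln = min(max(q_pos, self.q_begin), self.q_end) - self.q_begin
        else:
            q_aln = (self.query_len - min(max(q_pos, self.q_begin), self.q_end)) - (
                self.query_len - self.q_end
            )
        if not self.trace:
            frac = q_aln / max(1, self.query_span)
            return self.t_begin + round(frac * self.target_span)
        qcum, tcum = self._cum()
        i = int(np.searchsorted(qcum, q_aln, side="left"))
        if i > 0 and qcum[i] != q_aln:
            i -= 1
            run_q = qcum[i + 1] - qcum[i]
            run_t = tcum[i + 1] - tcum[i]
            extra = q_aln - qcum[i]
            t_off = tcum[i] + (extra if run_q == run_t else min(extra, run_t))
        else:
            t_off = tcum[i]
        return self.t_begin + int(t_off)


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------

def read_paf(path) -> List[LocalAlignment]:
    alns: List[LocalAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 PAF columns")
            try:
                tags = {}
                cigar = ""
                for tag in cols[12:]:
                    key, typ, val = tag.split(":", 2)
                    if key == "cg":
                        cigar = val
                    else:
                        tags[key] = val
                alns.append(
                    LocalAlignment(
                        query_id=cols[0],
                        query_len=int(cols[1]),
                        q_begin=int(cols[2]),
                        q_end=int(cols[3]),
                        strand=cols[4],
                        target_id=cols[5],
                        target_len=int(cols[6]),
                        t_begin=int(cols[7]),
                        t_end=int(cols[8]),
                        n_match=int(cols[9]),
                        trace=cigar,
                        tags=tags,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line: {exc}") from exc
    return alns


def write_paf(alignments: Iterable[LocalAlignment], path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            block = a._aln_len() if a.trace else max(a.query_span, a.target_span)
            cols = [
                a.query_id,
                str(a.query_len),
                str(a.q_begin),
                str(a.q_end),
                a.strand,
                a.target_id,
                str(a.target_len),
                str(a.t_begin),
                str(a.t_end),
                str(a.n_match),
                str(block),
                "255",
            ]
            for key, val in a.tags.items():
                typ = "i" if val.lstrip("-").isdigit() else "Z"
                cols.append(f"{key}:{typ}:{val}")
            if a.trace:
                cols.append(f"cg:Z:{a.trace}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Built-in aligner
# ---------------------------------------------------------------------------

def _edlib_ops(
    query: str, target: str, mode: str, max_err: Optional[float] = None
) -> Tuple[List[Tuple[int, str]], int]:
    """Run edlib; return (ops, consumed target length).

    With ``max_err`` given, the search is banded at a distance bound
    derived from it and falls back to an unbounded run if exceeded.
    """
    if not query and not target:
        return [], 0
    if not query:
        return ([(len(target), "D")], len(target)) if mode == "NW" else ([], 0)
    if not target:
        return [(len(query), "I")], 0
    if max_err is not None:
        k = int((max_err + 0.1) * max(len(query), len(target))) + 50
        res = edlib.align(query, target, mode=mode, task="path", k=k)
        if res["editDistance"] < 0:
            res = edlib.align(query, target, mode=mode, task="path")
    else:
        res = edlib.align(query, target, mode=mode, task="path")
    ops = parse_cigar(res["cigar"])
    t_end = res["locations"][0][1] + 1 if res["locations"] else 0
    return ops, t_end


_MATCH_SCORE = 1
_ERROR_SCORE = -3


def _trim_ends(ops: List[Tuple[int, str]]) -> Tuple[List[Tuple[int, str]], int, int, int, int]:
    """Trim an alignment to its maximal-scoring contiguous segment.

    Forced extensions may run into unrelated sequence; the optimal local
    alignment under a match/+1 error/-3 score is the maximal-scoring
    sub-segment of the op sequence (Kadane), whose boundaries always fall
    on '=' run boundaries.  Returns (ops, dq_left, dt_left, dq_right,
    dt_right) — query/target bases trimmed at each end.
    """
    if not ops:
        return ops, 0, 0, 0, 0
    best_score = -1.0
    best_lo = best_hi = 0
    score = 0.0
    lo = 0
    for i, (n, op) in enumerate(ops):
        if score <= 0:
            score = 0.0
            lo = i
        score += (_MATCH_SCORE if op == "=" else _ERROR_SCORE) * n
        if score > best_score:
            best_score = score
            best_lo, best_hi = lo, i + 1
    kept = ops[best_lo:best_hi]
    # strip residual terminal non-match runs
    while kept and kept[0][1] != "=":
        kept.pop(0)
        best_lo += 1
    while kept and kept[-1][1] != "=":
        kept.pop()
        best_hi -= 1

    def consumed(seq: List[Tuple[int, str]]) -> Tuple[int, int]:
        q = t = 0
        for n, op in seq:
            if op in _CONSUMES_QUERY:
                q += n
            if op in _CONSUMES_TARGET:
                t += n
        return q, t

    dq_l, dt_l = consumed(ops[:best_lo])
    dq_r, dt_r = consumed(ops[best_hi:])
    return kept, dq_l, dt_l, dq_r, dt_r


def _split_ops(
    ops: List[Tuple[int, str]], xdrop: int = 60
) -> List[Tuple[int, int, List[Tuple[int, str]]]]:
    """Split an alignment wherever the running score falls ``xdrop``
    below its maximum (an unrelated stretch sewn between two genuinely
    matching regions), as a local aligner would report two alignments.

    Returns (query offset, target offset, ops) per segment.
    """
    segments: List[Tuple[int, int, List[Tuple[int, str]]]] = []
    q = t = 0  # consumed so far
    seg_start_q = seg_start_t = 0
    seg: List[Tuple[int, str]] = []
    score = best = 0.0
    best_len = 0  # ops in seg at the running maximum
    for n, op in ops:
        if op == "=":
            score += _MATCH_SCORE * n
        else:
            score += _ERROR_SCORE * n
        seg.append((n, op))
        if op in _CONSUMES_QUERY:
            q += n
        if op in _CONSUMES_TARGET:
            t += n
        if score >= best:
            best = score
            best_len = len(seg)
        elif best - score > xdrop:
            # cut at the maximum (always the end of a match run)
            segments.append((seg_start_q, seg_start_t, seg[:best_len]))
            seg = seg[best_len:]
            while seg and seg[0][1] != "=":  # a segment cannot open on an error
                seg.pop(0)
            dq, dt = 0, 0
            for m, o in seg:
                if o in _CONSUMES_QUERY:
                    dq += m
                if o in _CONSUMES_TARGET:
                    dt += m
            seg_start_q, seg_start_t = q - dq, t - dt
            score, best, best_len = 0.0, 0.0, 0
            for i, (m, o) in enumerate(seg):  # rescore the carried tail
                score += (_MATCH_SCORE if o == "=" else _ERROR_SCORE) * m
                if score >= best:
                    best = score
                    best_len = i + 1
    segments.append((seg_start_q, seg_start_t, seg))
    return [s for s in segments if s[2]]


class KmerIndex:
    """Exact k-mer index over a set of named sequences."""

    def __init__(self, seqs: Dict[str, str], k: int = 12, max_occ: int = 200):
        self.k = k
        self.max_occ = max_occ
        self.seqs = seqs
        index: Dict[str, List[Tuple[str, int]]] = {}
        for sid, seq in seqs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                hits = index.setdefault(kmer, [])
                hits.append((sid, i))
        # drop hyper-repetitive k-mers to bound seed counts
        self.index = {
            kmer: hits for kmer, hits in index.items() if len(hits) <= max_occ
        }

    def seeds(self, query: str) -> Dict[str, List[Tuple[int, int]]]:
        """All (qpos, tpos) exact k-mer matches, grouped by target id."""
        k = self.k
        out: Dict[str, List[Tuple[int, int]]] = {}
        idx = self.index
        for qpos in range(len(query) - k + 1):
            hits = idx.get(query[qpos : qpos + k])
            if hits:
                for sid, tpos in hits:
                    out.setdefault(sid, []).append((qpos, tpos))
        return out


def _cluster_seeds(
    seeds: List[Tuple[int, int]], max_seed_gap: int = 500
) -> List[List[Tuple[int, int]]]:
    """Greedy colinear clustering of (qpos, tpos) seeds sorted by qpos."""
    seeds = sorted(seeds)
    clusters: List[List[Tuple[int, int]]] = []
    tails: List[Tuple[int, int]] = []  # last seed of each open cluster
    active: List[int] = []  # cluster indices whose tail can still extend
    for q, t in seeds:
        placed = False
        # seeds come in qpos order, so clusters whose tail fell more than
        # max_seed_gap behind are closed for good
        live: List[int] = []
        for ci in reversed(active):
            lq, lt = tails[ci]
            if q - lq > max_seed_gap:
                continue
            live.append(ci)
            if placed:
                continue
            dq, dt = q - lq, t - lt
            if dq < 0 or dt < 0:
                continue
            # indel drift grows with distance travelled along the
            # alignment (~min(dq, dt)); a max-based band would chain
            # seeds straight across tandem periods
            if abs(dt - dq) <= 0.25 * min(dq, dt) + 12:
                clusters[ci].append((q, t))
                tails[ci] = (q, t)
                placed = True
        active = live[::-1]
        if not placed:
            clusters.append([(q, t)])
            tails.append((q, t))
            active.append(len(clusters) - 1)
    return clusters


def _extend_and_stitch(
    query: str,
    target: str,
    qs: int,
    qe: int,
    ts: int,
    te: int,
    max_err: float,
    max_ext: int = 800,
) -> Optional[Tuple[int, int, int, int, List[Tuple[int, str]]]]:
    """Align query[qs:qe] to target[ts:te] plus extensions to the ends.

    Extensions are capped at ``max_ext`` bp: seeds are dense enough that
    a genuine alignment never continues for that long without any seed,
    so anything longer is unrelated sequence that end trimming would
    discard anyway.  Returns (q_begin, q_end, t_begin, t_end, ops) or
    None.
    """
    slack = 1.0 + 2.0 * max_err
    core_ops, _ = _edlib_ops(query[qs:qe], target[ts:te], "NW", max_err=max_err)

    # left extension (aligned on reversed prefixes)
    lq, lt = min(qs, max_ext), min(ts, max_ext)
    wq = min(lq, int(lt * slack) + 50)
    wt = min(lt, int(lq * slack) + 50)
    left_ops: List[Tuple[int, str]] = []
    lq_used = lt_used = 0
    if wq > 0 and wt > 0:
        a_rev = query[qs - wq : qs][::-1]
        b_rev = target[ts - wt : ts][::-1]
        if wq <= wt:
            ops, t_used = _edlib_ops(a_rev, b_rev, "SHW", max_err=max_err)
            lq_used, lt_used = wq, t_used
        else:
            ops, t_used = _edlib_ops(b_rev, a_rev, "SHW", max_err=max_err)
            ops = [(n, {"I": "D", "D": "I"}.get(op, op)) for n, op in ops]
            lq_used, lt_used = t_used, wt
        left_ops = ops[::-1]

    # right extension
    rq = min(len(query) - qe, max_ext)
    rt = min(len(target) - te, max_ext)
    wq = min(rq, int(rt * slack) + 50)
    wt = min(rt, int(rq * slack) + 50)
    right_ops: List[Tuple[int, str]] = []
    rq_used = rt_used = 0
    if wq > 0 and wt > 0:
        a_fwd = query[qe : qe + wq]
        b_fwd = target[te : te + wt]
        if wq <= wt:
            ops, t_used = _edlib_ops(a_fwd, b_fwd, "SHW", max_err=max_err)
            rq_used, rt_used = wq, t_used
        else:
            ops, t_used = _edlib_ops(b_fwd, a_fwd, "SHW", max_err=max_err)
            ops = [(n, {"I": "D", "D": "I"}.get(op, op)) for n, op in ops]
            rq_used, rt_used = t_used, wt
        right_ops = ops

    ops = left_ops + core_ops + right_ops
    q_begin, t_begin = qs - lq_used, ts - lt_used
    q_end, t_end = qe + rq_used, te + rt_used

    ops, dq_l, dt_l, dq_r, dt_r = _trim_ends(ops)
    q_begin += dq_l
    t_begin += dt_l
    q_end -= dq_r
    t_end -= dt_r
    if not ops or q_end <= q_begin or t_end <= t_begin:
        return None
    return q_begin, q_end, t_begin, t_end, ops


class Aligner:
    """Seed-and-extend local aligner over an indexed target set."""

    def __init__(
        self,
        targets: Dict[str, str],
        k: int = 12,
        max_err: float = 0.25,
        min_length: int = 200,
        min_seeds: int = 3,
        max_seed_gap: int = 500,
        max_occ: int = 200,
    ):
        self.targets = targets
        self.max_err = max_err
        self.min_length = min_length
        self.min_seeds = min_seeds
        self.max_seed_gap = max_seed_gap
        self.index = KmerIndex(targets, k=k, max_occ=max_occ)

    def map_sequence(
        self, query_id: str, seq: str, exclude_self_diagonal: bool = False
    ) -> List[LocalAlignment]:
        """All local alignments of ``seq`` against the indexed targets,
        both strands, error rate <= max_err, length >= min_length."""
        results: List[LocalAlignment] = []
        qlen = len(seq)
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            seed_map = self.index.seeds(oriented)
            for tid, seeds in seed_map.items():
                target = self.targets[tid]
                if exclude_self_diagonal and tid == query_id and strand == "+":
                    seeds = [(q, t) for q, t in seeds if q != t]
                for cluster in _cluster_seeds(seeds, self.max_seed_gap):
                    if len(cluster) < self.min_seeds:
                        continue
                    qs = cluster[0][0]
                    qe = cluster[-1][0] + self.index.k
                    ts = min(t for _, t in cluster)
                    te = max(t for _, t in cluster) + self.index.k
                    if qe - qs < self.index.k * 2:
                        continue
                    hit = _extend_and_stitch(
                        oriented, target, qs, qe, ts, te, self.max_err
                    )
                    if hit is None:
                        continue
                    hq_begin, _hq_end, ht_begin, _ht_end, ops = hit
                    for dq, dt, seg in _split_ops(ops):
                        sq, st, _, _ = cigar_stats(seg)
                        _, _, n_match, dist = cigar_stats(seg)
                        total = sum(n for n, _ in seg)
                        if total < self.min_length or dist / total > self.max_err:
                            continue
                        q_begin, t_begin = hq_begin + dq, ht_begin + dt
                        q_end, t_end = q_begin + sq, t_begin + st
                        if strand == "+":
                            fq_begin, fq_end = q_begin, q_end
                        else:
                            fq_begin, fq_end = qlen - q_end, qlen - q_begin
                        if (
                            exclude_self_diagonal
                            and tid == query_id
                            and strand == "+"
                            and fq_begin == t_begin
                            and fq_end == t_end
                        ):
                            continue
                        results.append(
                            LocalAlignment(
                                query_id=query_id,
                                query_len=qlen,
                                q_begin=fq_begin,
                                q_end=fq_end,
                                target_id=tid,
                                target_len=len(target),
                                t_begin=t_begin,
                                t_end=t_end,
                                strand=strand,
                                n_match=n_match,
                                trace=_ops_to_cigar(seg),
                            )
                        )
        return _dedupe(results)


def _dedupe(alns: List[LocalAlignment]) -> List[LocalAlignment]:
    """Drop alignments nearly identical to a better one (same pair/strand,
    >=90% mutual overlap on both sequences)."""
    alns = sorted(alns, key=lambda a: -a.n_match)
    kept: List[LocalAlignment] = []
    for a in alns:
        dup = False
        for b in kept:
            if (
                a.target_id == b.target_id
                and a.strand == b.strand
                and _overlap_frac(a.q_begin, a.q_end, b.q_begin, b.q_end) >= 0.9
                and _overlap_frac(a.t_begin, a.t_end, b.t_begin, b.t_end) >= 0.9
            ):
                dup = True
                break
        if not dup:
            kept.append(a)
    kept.sort(key=lambda a: (a.target_id, a.t_begin, a.q_begin))
    return kept


def _overlap_frac(b1: int, e1: int, b2: int, e2: int) -> float:
    inter = max(0, min(e1, e2) - max(b1, b2))
    small = max(1, min(e1 - b1, e2 - b2))
    return inter / small


def align_pair(
    seq_a: str,
    seq_b: str,
    mode: str = "local",
    max_err: float = 0.25,
    query_id: str = "a",
    target_id: str = "b",
    k: int = 12,
    min_length: int = 100,
    min_seeds: int = 2,
) -> List[LocalAlignment]:
    """Align two sequences; query is ``seq_a``, target ``seq_b``.

    mode='local': all local alignments with error rate <= max_err.
    mode='semi_global': the whole of ``seq_a`` aligned as an infix of
    ``seq_b`` (best hit per strand, filtered by max_err).
    """
    if mode == "semi_global":
        results = []
        for strand, oriented in (("+", seq_a), ("-", reverse_complement(seq_a))):
            if not oriented or not seq_b:
                continue
            res = edlib.align(oriented, seq_b, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            loc = res["locations"][0]
            t_begin = loc[0] if loc[0] is not None else 0
            t_end = loc[1] + 1
            ops = parse_cigar(res["cigar"])
            _, _, n_match, dist = cigar_stats(ops)
            total = sum(n for n, _ in ops)
            if total == 0 or dist / total > max_err:
                continue
            results.append(
                LocalAlignment(
                    query_id=query_id,
                    query_len=len(seq_a),
                    q_begin=0,
                    q_end=len(seq_a),
                    target_id=target_id,
                    target_len=len(seq_b),
                    t_begin=t_begin,
                    t_end=t_end,
                    strand=strand,
                    n_match=n_match,
                    trace=_ops_to_cigar(ops),
                )
            )
        results.sort(key=lambda a: a.error_rate())
        return results
    if mode != "local":
        raise ValueError(f"unknown mode {mode!r}")
    aligner = Aligner(
        {target_id: seq_b},
        k=k,
        max_err=max_err,
        min_length=min_length,
        min_seeds=min_seeds,
    )
    return aligner.map_sequence(query_id, seq_a, exclude_self_diagonal=False)
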