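"""Repeat annotation: the four masks and their homogenization.

Four annotations are produced on assembly (contig) coordinates:

1. low-complexity regions (symmetric-DUST-style triplet scoring);
2. tandem repeats (period-bounded self-comparison);
3. regions covered by many assembly self-alignments;
4. regions with excessive read-alignment depth, in two parts — total
   depth above a Poisson-derived ceiling ``C_max``, and improper-alignment
   depth above half the global read coverage.

The union is then *homogenized*: masked intervals are projected through
the read alignments onto the reads and back onto the assembly through all
alignments of each read, so that every copy of an annotated repeat becomes
masked even if only one copy was detected.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.stats import poisson

from .align import LocalAlignment
from .intervals import Interval, MaskTrack

__all__ = [
    "dust_mask",
    "tandem_mask",
    "self_alignment_mask",
    "compute_cmax",
    "read_coverage_mask",
    "is_proper",
    "improper_coverage_mask",
    "homogenize",
    "depth_profile",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# 1. low-complexity (DUST-style)
# ---------------------------------------------------------------------------

def dust_mask(
    contigs: Dict[str, str], window: int = 64, threshold: float = 2.0
) -> MaskTrack:
    """Mask windows whose triplet score exceeds ``threshold``.

    Score of a window with triplet counts c_t is
    sum(c_t * (c_t - 1) / 2) / (n_triplets - 1), the SDUST statistic.
    Windows slide by window/2; flagged windows are merged.
    """
    step = max(1, window // 2)
    intervals: List[Interval] = []
    for cid, seq in contigs.items():
        n = len(seq)
        if n < 3:
            continue
        codes = _encode(seq)
        trip = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
        starts = list(range(0, max(1, n - window + 1), step))
        if starts[-1] != max(0, n - window):
            starts.append(max(0, n - window))
        for s in starts:
            w = trip[s : s + window - 2]
            if len(w) < 2:
                continue
            counts = np.bincount(w, minlength=64)
            score = float(np.sum(counts * (counts - 1)) / 2) / (len(w) - 1)
            if score > threshold:
                intervals.append(Interval(cid, s, min(n, s + window)))
    return MaskTrack(intervals)


# ---------------------------------------------------------------------------
# 2. tandem repeats
# ---------------------------------------------------------------------------

def tandem_mask(
    contigs: Dict[str, str],
    max_period: int = 100,
    min_len: int = 60,
    max_gap: int = 3,
) -> MaskTrack:
    """Mask regions self-matching at a diagonal offset <= max_period.

    For each period p, positions where seq[i] == seq[i+p] are computed;
    runs of matches (tolerating gaps <= max_gap, overall match density
    >= 0.8) of length >= max(min_len - p, p) mask [run_start, run_end + p).
    """
    intervals: List[Interval] = []
    for cid, seq in contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(arr)
        for p in range(1, min(max_period, n - 1) + 1):
            eq = arr[:-p] == arr[p:]
            if not eq.any():
                continue
            eq_cum = np.concatenate(([0], np.cumsum(eq)))
            # run-length encode; merge runs separated by <= max_gap mismatches
            edges = np.flatnonzero(np.diff(eq.astype(np.int8)))
            bounds = np.concatenate(([0], edges + 1, [len(eq)]))
            runs = [
                (int(bounds[i]), int(bounds[i + 1]))
                for i in range(len(bounds) - 1)
                if eq[bounds[i]]
            ]
            merged: List[Tuple[int, int]] = []
            for b, e in runs:
                if merged and b - merged[-1][1] <= max_gap:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((b, e))
            for b, e in merged:
                if e - b >= max(min_len - p, p, 8) and (
                    eq_cum[e] - eq_cum[b]
                ) >= 0.8 * (e - b):
                    intervals.append(Interval(cid, b, min(n, e + p)))
    return MaskTrack(intervals)


# ---------------------------------------------------------------------------
# depth counting (shared by masks 3 and 4)
# ---------------------------------------------------------------------------

def depth_profile(
    intervals: Iterable[Tuple[str, int, int]], seq_lens: Dict[str, int]
) -> Dict[str, np.ndarray]:
    """Per-base alignment depth for each sequence."""
    diffs = {sid: np.zeros(n + 1, dtype=np.int64) for sid, n in seq_lens.items()}
    for sid, b, e in intervals:
        d = diffs.get(sid)
        if d is None:
            continue
        b = max(0, b)
        e = min(seq_lens[sid], e)
        if e > b:
            d[b] += 1
            d[e] -= 1
    return {sid: np.cumsum(d[:-1]) for sid, d in diffs.items()}


def _mask_from_depth(
    depth: Dict[str, np.ndarray], threshold: float, strict: bool
) -> MaskTrack:
    intervals = []
    for sid, prof in depth.items():
        flag = prof > threshold if strict else prof >= threshold
        if not flag.any():
            continue
        edges = np.flatnonzero(np.diff(flag.astype(np.int8)))
        bounds = np.concatenate(([0], edges + 1, [len(flag)]))
        for i in range(len(bounds) - 1):
            if flag[bounds[i]]:
                intervals.append(Interval(sid, int(bounds[i]), int(bounds[i + 1])))
    return MaskTrack(intervals)


# ---------------------------------------------------------------------------
# 3. self-alignment repeats
# ---------------------------------------------------------------------------

def self_alignment_mask(
    self_alns: Sequence[LocalAlignment],
    seq_lens: Dict[str, int],
    max_coverage_self: int = 4,
) -> MaskTrack:
    """Mask positions covered by >= max_coverage_self self-alignments.

    Callers must already have excluded the trivial full-length alignment
    of each contig to itself.
    """
    depth = depth_profile(
        ((a.target_id, a.t_begin, a.t_end) for a in self_alns), seq_lens
    )
    return _mask_from_depth(depth, max_coverage_self, strict=False)


# ---------------------------------------------------------------------------
# 4. read-coverage repeats
# ---------------------------------------------------------------------------

def compute_cmax(C: float, tail_prob: float = 1e-3) -> int:
    """Smallest integer m with P(Poisson(C) > m) < tail_prob.

    Read sampling is uniform, so the depth at any position is Poisson(C);
    depth beyond the upper tail indicates a collapsed repeat.
    """
    if C <= 0:
        raise ValueError("read coverage C must be > 0")
    m = int(poisson.isf(tail_prob, C))  # first guess near the quantile
    while poisson.sf(m, C) >= tail_prob:
        m += 1
    while m > 0 and poisson.sf(m - 1, C) < tail_prob:
        m -= 1
    return m


def read_coverage_mask(
    read_alns: Sequence[LocalAlignment], seq_lens: Dict[str, int], c_max: int
) -> MaskTrack:
    """Mask positions with read-alignment depth strictly above C_max."""
    depth = depth_profile(
        ((a.target_id, a.t_begin, a.t_end) for a in read_alns), seq_lens
    )
    return _mask_from_depth(depth, c_max, strict=True)


def is_proper(
    aln: LocalAlignment, allowance: int = 100, at_target_ends: bool = False
) -> bool:
    """True if <= allowance bp of the read is unaligned at either end.

    With ``at_target_ends=True`` an unaligned read tail is also tolerated
    when the alignment reaches within ``allowance`` of the corresponding
    target (contig) boundary — the tail then hangs off the contig end, as
    for reads spanning a gap, and is no repeat signal.
    """
    left_tail = aln.q_begin
    right_tail = aln.query_len - aln.q_end
    if not at_target_ends:
        return left_tail <= allowance and right_tail <= allowance
    at_t_begin = aln.t_begin <= allowance
    at_t_end = aln.target_len - aln.t_end <= allowance
    # the read's left tail abuts the target's low side on '+', high side on '-'
    left_ok = left_tail <= allowance or (at_t_begin if aln.strand == "+" else at_t_end)
    right_ok = right_tail <= allowance or (at_t_end if aln.strand == "+" else at_t_begin)
    return left_ok and right_ok


def improper_coverage_mask(
    read_alns: Sequence[LocalAlignment],
    seq_lens: Dict[str, int],
    threshold: float,
    allowance: int = 100,
) -> MaskTrack:
    """Mask positions where improper-alignment depth exceeds ``threshold``
    (default C/2).  Alignments whose unaligned tails are explained by
    contig boundaries do not count as improper."""
    improper = (
        a
        for a in read_alns
        if not is_proper(a, allowance, at_target_ends=True)
    )
    depth = depth_profile(((a.target_id, a.t_begin, a.t_end) for a in improper), seq_lens)
    return _mask_from_depth(depth, threshold, strict=True)


# ---------------------------------------------------------------------------
# homogenization
# ---------------------------------------------------------------------------

def homogenize(
    masks: Sequence[MaskTrack],
    read_alns: Sequence[LocalAlignment],
    max_rounds: int = 5,
) -> MaskTrack:
    """Transfer masks through read alignments and back, to a fixpoint.

    Output is a superset of the union of the inputs and idempotent by
    construction (iterated until no further growth).
    """
    current = MaskTrack()
    for m in masks:
        current = current.union(m)
    by_read: Dict[str, List[LocalAlignment]] = {}
    for a in read_alns:
        by_read.setdefault(a.query_id, []).append(a)

    for _ in range(max_rounds):
        # assembly -> read space
        read_ivs: Dict[str, List[Tuple[int, int]]] = {}
        for alns in by_read.values():
            for a in alns:
                for mb, me in current.intervals(a.target_id):
                    b = max(mb, a.t_begin)
                    e = min(me, a.t_end)
                    if e <= b:
                        continue
                    q1 = a.project_target_to_query(b)
                    q2 = a.project_target_to_query(e)
                    lo, hi = (q1, q2) if q1 <= q2 else (q2, q1)
                    if hi > lo:
                        read_ivs.setdefault(a.query_id, []).append((lo, hi))
        # read space -> assembly, through *all* alignments of the read
        new_ivs: List[Interval] = []
        for rid, ivs in read_ivs.items():
            for a in by_read[rid]:
                for lo, hi in ivs:
                    b = max(lo, a.q_begin)
                    e = min(hi, a.q_end)
                    if e <= b:
                        continue
                    t1 = a.project_query_to_target(b)
                    t2 = a.project_query_to_target(e)
                    tlo, thi = (t1, t2) if t1 <= t2 else (t2, t1)
                    if thi > tlo:
                        new_ivs.append(Interval(a.target_id, tlo, thi))
        updated = current.union(MaskTrack(new_ivs))
        if updated == current:
            break
        current = updated
    return current
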