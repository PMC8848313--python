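"""Score a gap-closer's output against the ground truth.

The original test-assembly contigs are located in the result assembly by
exact (optionally near-exact) unique matching; each introduced gap is
then classified:

* ``closed`` — both flanking contigs map to one result contig; the
  inserted sequence between them is compared to the truth;
* ``unclosed`` — flanks map to different but adjacent contigs of one
  result scaffold (separated only by an N-run);
* ``unknown`` — a flank is missing or cannot be located uniquely;
* ``broken`` — both flanks located but no longer adjacent (misassembly).

Sequence identity is matches / alignment-length of a global alignment,
so indels count as errors.  Contiguity is summarized as NG(x) against
the fixed ground-truth genome size G (real A/C/G/T bases only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .assembly import Assembly, reverse_complement
from .simulate import GapTruth

__all__ = [
    "Placement",
    "GapRecord",
    "IdentitySummary",
    "ContiguityStats",
    "locate_contigs",
    "classify_gaps",
    "gap_identity",
    "summarize",
    "ng_stats",
    "evaluate_closure",
]

IDENTITY_BINS = [0.0, 0.7, 0.9, 0.95, 0.99, 1.0]  # plus the exact-1.0 bin


@dataclass
class Placement:
    contig_id: str  # result contig
    begin: int  # match coordinates of the (cropped) test contig
    end: int
    strand: str
    crop: int  # bp cropped from each flank before searching


@dataclass
class GapRecord:
    gap_id: str
    state: str  # 'closed' | 'unclosed' | 'unknown' | 'broken'
    identity: Optional[float] = None  # defined iff closed
    truth_len: int = 0
    inserted_len: int = 0


@dataclass
class IdentitySummary:
    n_closed: int
    n_unclosed: int
    n_unknown: int
    n_broken: int
    mean_id: Optional[float]
    weighted_id: Optional[float]
    bins: List[int] = field(default_factory=list)


@dataclass
class ContiguityStats:
    genome_size: int
    ng50: int
    curve: List[Tuple[int, int]] = field(default_factory=list)  # (x, NG(x))


def _occurrences(needle: str, hay: str) -> List[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def locate_contigs(
    test_assembly: Assembly,
    result_assembly: Assembly,
    crop_ambiguous: int = 300,
    crop_alignment: int = 0,
    recover_imperfect: bool = False,
    max_mismatch: float = 0.015,
) -> Dict[str, Optional[Placement]]:
    """Locate each test contig in the result by exact unique match.

    Contigs with more than one exact match within the *test* assembly
    (after cropping ``crop_ambiguous`` bp per flank) are excluded.
    Search needles are cropped by ``crop_alignment`` per flank, so a
    closer may modify contig flanks without losing the match.  With
    ``recover_imperfect``, unfound contigs are accepted if they align
    fully and uniquely with at most ``max_mismatch`` errors.

    Returns contig id -> Placement, or None for ambiguous/missing.
    """
    test_seqs = [s.sequence for s in test_assembly]
    result_contigs = [(c.id, c.seq) for c in result_assembly.contigs]

    out: Dict[str, Optional[Placement]] = {}
    for contig in test_assembly.contigs:
        core = contig.seq[crop_ambiguous : len(contig.seq) - crop_ambiguous]
        if not core:
            out[contig.id] = None
            continue
        n_self = sum(
            len(_occurrences(core, hay)) + len(_occurrences(reverse_complement(core), hay))
            for hay in test_seqs
        )
        if n_self > 1:
            out[contig.id] = None  # duplicated in the test assembly
            continue
        needle = contig.seq[crop_alignment : len(contig.seq) - crop_alignment]
        hits: List[Placement] = []
        for rid, rseq in result_contigs:
            for pos in _occurrences(needle, rseq):
                hits.append(
                    Placement(rid, pos, pos + len(needle), "+", crop_alignment)
                )
            rc = reverse_complement(needle)
            for pos in _occurrences(rc, rseq):
                hits.append(
                    Placement(rid, pos, pos + len(needle), "-", crop_alignment)
                )
        if not hits and recover_imperfect:
            hits = _imperfect_hits(needle, result_contigs, max_mismatch, crop_alignment)
        out[contig.id] = hits[0] if len(hits) == 1 else None
    return out


def _imperfect_hits(
    needle: str,
    result_contigs: List[Tuple[str, str]],
    max_mismatch: float,
    crop: int,
) -> List["Placement"]:
    k = int(max_mismatch * len(needle))
    hits: List[Placement] = []
    for rid, rseq in result_contigs:
        for strand, query in (("+", needle), ("-", reverse_complement(needle))):
            res = edlib.align(query, rseq, mode="HW", task="locations", k=k)
            if res["editDistance"] < 0:
                continue
            # collapse overlapping locations into one hit
            locs = res["locations"]
            kept = []
            last_end = -(10**9)
            for b, e in locs:
                if (b or 0) > last_end:
                    kept.append((b or 0, e + 1))
                    last_end = e + 1
            for b, e in kept:
                hits.append(Placement(rid, b, e, strand, crop))
    return hits


def classify_gaps(
    placements: Dict[str, Optional[Placement]],
    gaps: Sequence[GapTruth],
    test_assembly: Assembly,
    result_assembly: Assembly,
) -> List[GapRecord]:
    """Classify each introduced gap and extract inserted sequences."""
    flanks = _gap_flanks(gaps, test_assembly)
    contig_seq = {c.id: c.seq for c in result_assembly.contigs}
    # adjacency: consecutive contigs of one result scaffold
    order: Dict[str, Tuple[str, int]] = {}
    for s in result_assembly:
        for i, c in enumerate(s.contigs):
            order[c.id] = (s.id, i)

    records: List[GapRecord] = []
    for gap in gaps:
        left_id, right_id = flanks[gap.gap_id]
        pl, pr = placements.get(left_id), placements.get(right_id)
        if pl is None or pr is None:
            records.append(GapRecord(gap.gap_id, "unknown", truth_len=gap.length))
            continue
        if pl.contig_id == pr.contig_id and pl.strand == pr.strand:
            seq = contig_seq[pl.contig_id]
            if pl.strand == "+":
                lo, hi = pl.end + pl.crop, pr.begin - pr.crop
            else:
                lo, hi = pr.end + pr.crop, pl.begin - pl.crop
            if lo <= hi:
                inserted = seq[lo:hi]
                if pl.strand == "-":
                    inserted = reverse_complement(inserted)
                ident = gap_identity(inserted, gap.truth_seq)
                records.append(
                    GapRecord(
                        gap.gap_id,
                        "closed",
                        identity=ident,
                        truth_len=gap.length,
                        inserted_len=len(inserted),
                    )
                )
                continue
            records.append(GapRecord(gap.gap_id, "broken", truth_len=gap.length))
            continue
        sl, il = order[pl.contig_id]
        sr, ir = order[pr.contig_id]
        if sl == sr and abs(il - ir) == 1:
            records.append(GapRecord(gap.gap_id, "unclosed", truth_len=gap.length))
        else:
            records.append(GapRecord(gap.gap_id, "broken", truth_len=gap.length))
    return records


def _gap_flanks(
    gaps: Sequence[GapTruth], test_assembly: Assembly
) -> Dict[str, Tuple[str, str]]:
    """Flanking test-contig ids for each introduced gap, by position."""
    out: Dict[str, Tuple[str, str]] = {}
    for gap in gaps:
        scaffold = next(s for s in test_assembly if s.id == gap.test_scaffold)
        left = right = None
        for c in scaffold.contigs:
            if c.scaffold_offset + len(c) == gap.test_begin:
                left = c.id
            if c.scaffold_offset == gap.test_end:
                right = c.id
        if left is None or right is None:
            raise ValueError(f"gap {gap.gap_id} has no flanking contigs")
        out[gap.gap_id] = (left, right)
    return out


def gap_identity(inserted_seq: str, truth_seq: str) -> float:
    """Global-alignment identity: matches / (matches + mismatches + indels)."""
    if not inserted_seq and not truth_seq:
        return 1.0
    if not inserted_seq or not truth_seq:
        return 0.0
    res = edlib.align(inserted_seq, truth_seq, mode="NW", task="path")
    from .align import parse_cigar

    total = sum(n for n, _ in parse_cigar(res["cigar"]))
    return (total - res["editDistance"]) / total


def summarize(records: Sequence[GapRecord]) -> IdentitySummary:
    closed = [r for r in records if r.state == "closed"]
    counts = {s: sum(1 for r in records if r.state == s) for s in
              ("closed", "unclosed", "unknown", "broken")}
    bins = [0] * (len(IDENTITY_BINS))
    for r in closed:
        x = r.identity
        if x == 1.0:
            bins[-1] += 1
        else:
            for bi in range(len(IDENTITY_BINS) - 1):
                if IDENTITY_BINS[bi] <= x < IDENTITY_BINS[bi + 1]:
                    bins[bi] += 1
                    break
    if closed:
        mean_id = float(np.mean([r.identity for r in closed]))
        w = np.array([r.truth_len for r in closed], dtype=np.float64)
        weighted = float(
            np.average([r.identity for r in closed], weights=w)
            if w.sum() > 0
            else mean_id
        )
    else:
        mean_id = weighted = None
    return IdentitySummary(
        n_closed=counts["closed"],
        n_unclosed=counts["unclosed"],
        n_unknown=counts["unknown"],
        n_broken=counts["broken"],
        mean_id=mean_id,
        weighted_id=weighted,
        bins=bins,
    )


def ng_stats(
    assembly: Assembly, genome_size: int, xs: Sequence[int] = tuple(range(10, 101, 10))
) -> ContiguityStats:
    """NG(x): largest L such that contigs >= L sum to >= x% of G."""
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    lengths = sorted((len(c) for c in assembly.contigs), reverse=True)
    cums = np.cumsum(lengths) if lengths else np.array([0])

    def ng(x: int) -> int:
        need = x / 100.0 * genome_size
        for length, cum in zip(lengths, cums):
            if cum >= need:
                return length
        return 0

    curve = [(x, ng(x)) for x in xs]
    return ContiguityStats(genome_size=genome_size, ng50=ng(50), curve=curve)


def evaluate_closure(
    test_assembly: Assembly,
    result_assembly: Assembly,
    gaps: Sequence[GapTruth],
    genome_size: int,
    crop_ambiguous: int = 300,
    crop_alignment: int = 0,
    recover_imperfect: bool = False,
) -> Tuple[List[GapRecord], IdentitySummary, ContiguityStats]:
    """Full evaluation: locate, classify, summarize, NG stats."""
    placements = locate_contigs(
        test_assembly,
        result_assembly,
        crop_ambiguous=crop_ambiguous,
        crop_alignment=crop_alignment,
        recover_imperfect=recover_imperfect,
    )
    records = classify_gaps(placements, gaps, test_assembly, result_assembly)
    return records, summarize(records), ng_stats(result_assembly, genome_size)
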