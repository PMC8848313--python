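"""Synthetic benchmarks: genomes with planted repeats, CLR-like reads,
test assemblies with ground-truth gaps, and closability flags.

The read simulator emulates PacBio continuous long reads: start positions
uniform over the genome, long-tailed (log-normal) lengths truncated at
sequence ends, and i.i.d. per-base errors at a 13% default rate split
55% insertion / 25% deletion / 20% substitution, matching the indel
dominance of CLR chemistry.  Each read's true source interval and strand
are recorded so that gap closability can be decided exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assembly import (
    Assembly,
    reverse_complement,
    scaffold_from_sequence,
)
from .intervals import Interval, MaskTrack

__all__ = [
    "RepeatFamily",
    "TandemArray",
    "ReadOrigin",
    "GapTruth",
    "simulate_genome",
    "simulate_reads",
    "plan_gaps",
    "make_test_assembly",
    "find_closable_gaps",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class RepeatFamily:
    """Interspersed repeat family: ``count`` diverged copies of one
    ``length``-bp master sequence."""

    count: int
    length: int
    divergence: float = 0.05  # per-base substitution rate between copies


@dataclass
class TandemArray:
    unit_length: int
    copies: int


@dataclass
class ReadOrigin:
    read_id: str
    seq_id: str
    begin: int
    end: int
    strand: str


@dataclass
class GapTruth:
    gap_id: str
    seq_id: str  # reference scaffold id
    begin: int  # reference scaffold coordinates (for read-truth queries)
    end: int
    truth_seq: str
    test_scaffold: str = ""  # scaffold of the test assembly holding the gap
    test_begin: int = 0  # coordinates within that test scaffold
    test_end: int = 0

    @property
    def length(self) -> int:
        return self.end - self.begin


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _mutate_subs(
    rng: np.random.Generator, arr: np.ndarray, rate: float
) -> np.ndarray:
    out = arr.copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit):
        codes = _CODE[out[hit]]
        out[hit] = _BASES[(codes + rng.integers(1, 4, len(hit))) % 4]
    return out


def simulate_genome(
    length: int,
    repeat_families: Sequence[RepeatFamily] = (),
    tandem_arrays: Sequence[TandemArray] = (),
    seed: int = 0,
    seq_id: str = "chr1",
    min_separation: int = 2000,
) -> Tuple[Assembly, MaskTrack]:
    """Random uniform-base genome with planted repeats.

    Returns the assembly (one gap-free scaffold) and the ground-truth
    repeat annotation.
    """
    rng = np.random.default_rng(seed)
    arr = _random_seq(rng, length)
    placed: List[Tuple[int, int]] = []

    def place(seg_len: int) -> Optional[int]:
        for _ in range(200):
            pos = int(rng.integers(min_separation, max(min_separation + 1, length - seg_len - min_separation)))
            if all(
                pos + seg_len + min_separation <= b or pos >= e + min_separation
                for b, e in placed
            ):
                placed.append((pos, pos + seg_len))
                return pos
        return None

    for fam in repeat_families:
        master = _random_seq(rng, fam.length)
        for _ in range(fam.count):
            pos = place(fam.length)
            if pos is None:
                continue
            arr[pos : pos + fam.length] = _mutate_subs(rng, master, fam.divergence)
    for tan in tandem_arrays:
        unit = _random_seq(rng, tan.unit_length)
        seg = np.tile(unit, tan.copies)
        pos = place(len(seg))
        if pos is not None:
            arr[pos : pos + len(seg)] = seg

    seq = arr.tobytes().decode()
    mask = MaskTrack(Interval(seq_id, b, e) for b, e in placed)
    return Assembly([scaffold_from_sequence(seq_id, seq)]), mask


def _corrupt(
    rng: np.random.Generator, arr: np.ndarray, error: float
) -> np.ndarray:
    """Apply CLR-like errors: 55% insertion / 25% deletion / 20% sub."""
    n = len(arr)
    u = rng.random(n)
    err = u < error
    kind = rng.random(n)
    ins = err & (kind < 0.55)
    dele = err & (kind >= 0.55) & (kind < 0.80)
    sub = err & (kind >= 0.80)

    work = arr.copy()
    sub_idx = np.flatnonzero(sub)
    if len(sub_idx):
        codes = _CODE[work[sub_idx]]
        work[sub_idx] = _BASES[(codes + rng.integers(1, 4, len(sub_idx))) % 4]

    out_count = ins.astype(np.int64) + (~dele).astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(out_count)[:-1]))
    out = np.empty(int(out_count.sum()), dtype=np.uint8)
    ins_idx = np.flatnonzero(ins)
    if len(ins_idx):
        out[starts[ins_idx]] = _BASES[rng.integers(0, 4, len(ins_idx))]
    keep = ~dele
    out[(starts + ins.astype(np.int64))[keep]] = work[keep]
    return out


def simulate_reads(
    genome: Assembly,
    coverage: float,
    mean_len: int = 25000,
    len_param: int = 125000,
    error: float = 0.13,
    seed: int = 0,
    min_len: int = 200,
) -> Tuple[Dict[str, str], List[ReadOrigin]]:
    """Simulate reads to the requested coverage.

    Lengths are log-normal with mean ``mean_len`` and standard deviation
    ``len_param / 5``, truncated at sequence ends.  Returns the reads and
    their true origins.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    scaffolds = [(s.id, s.sequence) for s in genome]
    arrs = {
        sid: np.frombuffer(seq.encode(), dtype=np.uint8) for sid, seq in scaffolds
    }
    sizes = np.array([len(seq) for _, seq in scaffolds], dtype=np.float64)
    total_target = coverage * sizes.sum()
    probs = sizes / sizes.sum()

    sd = len_param / 5.0
    sigma2 = np.log(1.0 + (sd / mean_len) ** 2)
    mu = np.log(mean_len) - sigma2 / 2.0
    sigma = float(np.sqrt(sigma2))

    reads: Dict[str, str] = {}
    origins: List[ReadOrigin] = []
    total = 0
    i = 0
    while total < total_target:
        si = int(rng.choice(len(scaffolds), p=probs))
        sid, _ = scaffolds[si]
        arr = arrs[sid]
        start = int(rng.integers(0, len(arr)))
        raw_len = int(np.exp(rng.normal(mu, sigma)))
        end = min(len(arr), start + raw_len)
        if end - start < min_len:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        template = arr[start:end]
        if strand == "-":
            template = np.frombuffer(
                reverse_complement(template.tobytes().decode()).encode(),
                dtype=np.uint8,
            )
        read = _corrupt(rng, template, error).tobytes().decode()
        i += 1
        rid = f"read_{i:06d}"
        reads[rid] = read
        origins.append(ReadOrigin(rid, sid, start, end, strand))
        total += end - start
    return reads, origins


def plan_gaps(
    genome: Assembly,
    repeat_track: MaskTrack,
    n_gaps: int,
    length_range: Tuple[int, int] = (50, 5000),
    seed: int = 0,
    exclusion: int = 3000,
    flank: int = 500,
    repeat_bias: float = 0.7,
) -> List[Tuple[str, int, int]]:
    """Choose gap intervals, biased toward planted repeat loci.

    With probability ``repeat_bias`` a gap is placed overlapping a repeat
    interval boundary (the realistic case: repeats cause gaps); otherwise
    uniformly.  Gaps keep ``exclusion`` + 2*flank distance from each
    other and from sequence ends.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    chosen: List[Tuple[str, int, int]] = []
    repeats = list(repeat_track)
    seq_lens = {s.id: len(s.sequence) for s in genome}
    min_dist = exclusion + 2 * flank

    def ok(sid: str, b: int, e: int) -> bool:
        if b < min_dist or e > seq_lens[sid] - min_dist:
            return False
        return all(
            s != sid or e + min_dist <= cb or b >= ce + min_dist
            for s, cb, ce in chosen
        )

    attempts = 0
    while len(chosen) < n_gaps and attempts < 200 * n_gaps:
        attempts += 1
        glen = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if repeats and rng.random() < repeat_bias:
            r = repeats[int(rng.integers(0, len(repeats)))]
            # straddle a repeat boundary so flanks stay mostly unique
            anchor = r.begin if rng.random() < 0.5 else r.end
            b = int(anchor - rng.integers(0, max(1, glen)))
            sid = r.seq_id
        else:
            sid = genome.scaffolds[int(rng.integers(0, len(genome.scaffolds)))].id
            b = int(rng.integers(0, max(1, seq_lens[sid] - glen)))
        e = b + glen
        if ok(sid, b, e):
            chosen.append((sid, b, e))
    chosen.sort()
    return chosen


def make_test_assembly(
    reference: Assembly,
    gap_spec: Optional[Sequence[Tuple[str, int, int]]] = None,
    fragmented: Optional[Assembly] = None,
    min_gap: int = 10,
    exclusion: int = 3000,
    flank: int = 500,
) -> Tuple[Assembly, List[GapTruth], Dict[str, int]]:
    """Introduce gaps of known truth sequence into a reference assembly.

    Either an explicit ``gap_spec`` (list of (seq_id, begin, end)) or a
    more ``fragmented`` assembly of the same genome provides the gap
    loci; for the latter, the 500 bp flanks of each fragmented-assembly
    gap are mapped uniquely (>= 80% matches) onto the reference and the
    enclosed sequence becomes the gap.  The reference is first
    disassembled into its contigs so every introduced gap has a known
    truth sequence.  Gaps shorter than ``min_gap`` or within
    ``exclusion`` bp of a pre-existing reference gap are skipped.

    Returns (test assembly, truth table, skip counters).
    """
    skipped = {"too_short": 0, "near_existing_gap": 0, "ambiguous_flank": 0}
    # disassemble: each reference contig becomes its own scaffold
    contigs = reference.contigs
    contig_seqs = {c.id: c.seq for c in contigs}

    if gap_spec is None:
        if fragmented is None:
            raise ValueError("either gap_spec or fragmented must be given")
        gap_spec = _gaps_from_fragmented(
            fragmented, contig_seqs, flank, skipped
        )

    # existing reference gaps, in original scaffold coordinates
    existing: Dict[str, List[Tuple[int, int]]] = {}
    for s in reference:
        pos = 0
        for comp in s.components:
            if not hasattr(comp, "seq"):
                existing.setdefault(s.id, []).append((pos, pos + len(comp)))
            pos += len(comp)

    # translate scaffold-coordinate specs onto contigs
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    truths: List[GapTruth] = []
    for sid, b, e in sorted(gap_spec):
        if e - b < min_gap:
            skipped["too_short"] += 1
            continue
        host = None
        if sid in contig_seqs:
            host, cb, ce = sid, b, e
        else:
            for s in reference:
                if s.id != sid:
                    continue
                for c in s.contigs:
                    if c.scaffold_offset <= b and e <= c.scaffold_offset + len(c):
                        host = c.id
                        cb, ce = b - c.scaffold_offset, e - c.scaffold_offset
                        break
        if host is None:
            skipped["ambiguous_flank"] += 1
            continue
        near = any(
            b < ge + exclusion and e > gb - exclusion
            for gb, ge in existing.get(sid, [])
        )
        if near:
            skipped["near_existing_gap"] += 1
            continue
        per_contig.setdefault(host, []).append((cb, ce))

    scaffolds = []
    for c in contigs:
        seq = c.seq
        cuts = sorted(per_contig.get(c.id, []))
        if cuts:
            parts = []
            prev = 0
            for gb, ge in cuts:
                parts.append(seq[prev:gb])
                parts.append("N" * (ge - gb))
                gap_id = f"{c.id}:{gb}-{ge}"
                truths.append(
                    GapTruth(
                        gap_id,
                        c.scaffold_id,
                        c.scaffold_offset + gb,
                        c.scaffold_offset + ge,
                        seq[gb:ge],
                        test_scaffold=c.id,
                        test_begin=gb,
                        test_end=ge,
                    )
                )
                prev = ge
            parts.append(seq[prev:])
            new_seq = "".join(parts)
        else:
            new_seq = seq
        scaffolds.append(scaffold_from_sequence(c.id, new_seq))
    return Assembly(scaffolds), truths, skipped


def _gaps_from_fragmented(
    fragmented: Assembly,
    contig_seqs: Dict[str, str],
    flank: int,
    skipped: Dict[str, int],
) -> List[Tuple[str, int, int]]:
    """Map fragmented-assembly gap flanks onto reference contigs."""
    from .align import Aligner

    aligner = Aligner(contig_seqs, k=16, max_err=0.1, min_length=flank // 2, min_seeds=3)

    def map_unique(seq: str) -> Optional[Tuple[str, int, int, str]]:
        hits = [
            a
            for a in aligner.map_sequence("flank", seq)
            if a.n_match >= 0.8 * len(seq)
        ]
        if len(hits) != 1:
            return None
        a = hits[0]
        return a.target_id, a.t_begin, a.t_end, a.strand

    specs: List[Tuple[str, int, int]] = []
    for scaffold in fragmented:
        for left_c, gap, right_c in scaffold.internal_gaps():
            lf = left_c.seq[-flank:]
            rf = right_c.seq[:flank]
            ml, mr = map_unique(lf), map_unique(rf)
            if ml is None or mr is None:
                skipped["ambiguous_flank"] += 1
                continue
            (tid_l, lb, le, st_l), (tid_r, rb, re_, st_r) = ml, mr
            if tid_l != tid_r or st_l != st_r:
                skipped["ambiguous_flank"] += 1
                continue
            if st_l == "+":
                if le <= rb:
                    specs.append((tid_l, le, rb))
                else:
                    skipped["ambiguous_flank"] += 1
            else:
                if re_ <= lb:
                    specs.append((tid_l, re_, lb))
                else:
                    skipped["ambiguous_flank"] += 1
    return specs


def find_closable_gaps(
    origins: Sequence[ReadOrigin],
    gaps: Sequence[GapTruth],
    min_reads: int = 3,
    flank: int = 500,
) -> Dict[str, bool]:
    """A gap is closable iff >= min_reads simulated reads span the gap
    plus ``flank`` bp on either side (decided from the read truth)."""
    by_seq: Dict[str, List[ReadOrigin]] = {}
    for o in origins:
        by_seq.setdefault(o.seq_id, []).append(o)
    out: Dict[str, bool] = {}
    for g in gaps:
        n = sum(
            1
            for o in by_seq.get(g.seq_id, [])
            if o.begin <= g.begin - flank and o.end >= g.end + flank
        )
        out[g.gap_id] = n >= min_reads
    return out
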