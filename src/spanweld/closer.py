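"""Apply insertions under the three closing modes and validate them.

Modes:

* ``intra_only`` (default): close only gaps already present inside input
  scaffolds;
* ``intra_and_inter``: additionally join different scaffolds end-to-end
  where spanned by sufficient read evidence;
* ``free_scaffolding``: ignore the input scaffold structure and scaffold
  the contigs purely from the read-supported joins.

Validation re-maps the reads to the gap-closed assembly and requires, in
a window of ``region_context`` around each former gap, at least
``min_spanning_reads`` alignments spanning the whole region and a minimum
continuous alignment coverage above threshold; failing insertions are
reverted to the original N-run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .align import LocalAlignment
from .assembly import (
    Assembly,
    Contig,
    Gap,
    Scaffold,
    reverse_complement,
    scaffold_from_sequence,
)
from .config import PipelineConfig
from .consensus import Insertion
from .intervals import Interval

__all__ = [
    "AppliedGap",
    "apply_insertions",
    "continuous_coverage",
    "validate_gaps",
]


@dataclass
class AppliedGap:
    """Where an insertion's core landed in the output assembly."""

    gap_id: str
    scaffold_id: str
    core_begin: int  # scaffold coordinates of the inserted bases
    core_end: int


class _Unit:
    """A scaffold-in-progress: sequence plus contig placements."""

    def __init__(
        self,
        uid: str,
        seq: str,
        contig_pos: Dict[str, Tuple[int, int]],
        records: List[AppliedGap],
    ):
        self.id = uid
        self.seq = seq
        self.contig_pos = contig_pos  # contig id -> (offset, length), '+' orient
        self.records = records
        self.first_contig, self.last_contig = self._terminals()

    def _terminals(self) -> Tuple[str, str]:
        items = sorted(self.contig_pos.items(), key=lambda kv: kv[1][0])
        return items[0][0], items[-1][0]

    def flipped(self) -> "_Unit":
        n = len(self.seq)
        pos = {
            cid: (n - off - ln, ln) for cid, (off, ln) in self.contig_pos.items()
        }
        recs = [
            AppliedGap(r.gap_id, self.id, n - r.core_end, n - r.core_begin)
            for r in self.records
        ]
        return _Unit(self.id, reverse_complement(self.seq), pos, recs)


def _intra_pass(
    scaffold: Scaffold, by_pair: Dict[Tuple[str, str], Insertion]
) -> _Unit:
    """Apply intra-scaffold insertions, returning one unit."""
    comps = scaffold.components
    # trims per contig from the insertions flanking it
    trim_right: Dict[str, int] = {}
    trim_left: Dict[str, int] = {}
    cores: Dict[int, Tuple[str, str]] = {}  # component index of gap -> (gap_id, core)
    for i, comp in enumerate(comps):
        if not isinstance(comp, Gap) or not (0 < i < len(comps) - 1):
            continue
        left, right = comps[i - 1], comps[i + 1]
        if not (isinstance(left, Contig) and isinstance(right, Contig)):
            continue
        ins = by_pair.get((left.id, right.id))
        if ins is None:
            continue
        trim_right[left.id] = ins.cut_left
        trim_left[right.id] = ins.cut_right
        cores[i] = (ins.gap_id, ins.core)

    chunks: List[str] = []
    contig_pos: Dict[str, Tuple[int, int]] = {}
    records: List[AppliedGap] = []
    pos = 0
    for i, comp in enumerate(comps):
        if isinstance(comp, Contig):
            lo = trim_left.get(comp.id, 0)
            hi = trim_right.get(comp.id, len(comp.seq))
            seq = comp.seq[lo:hi]
            # virtual placement of the *full* contig, so later joins can
            # use full-contig cut coordinates (interior trims never
            # interact with terminal joins)
            contig_pos[comp.id] = (pos - lo, len(comp.seq))
            chunks.append(seq)
            pos += len(seq)
        else:
            if i in cores:
                gap_id, core = cores[i]
                records.append(AppliedGap(gap_id, scaffold.id, pos, pos + len(core)))
                chunks.append(core)
                pos += len(core)
            else:
                chunks.append("N" * comp.length)
                pos += comp.length
    return _Unit(scaffold.id, "".join(chunks), contig_pos, records)


def _endpoint_orientation(
    unit: _Unit, contig: str, side: str, facing: str
) -> Optional[bool]:
    """Whether ``unit`` must be flipped so that (contig, side) faces
    ``facing`` ('right' for a join's left partner, 'left' for its right
    partner); None if the contig is not at a usable terminal."""
    if facing == "right":
        if side == "end" and contig == unit.last_contig:
            return False
        if side == "begin" and contig == unit.first_contig:
            return True
    else:
        if side == "begin" and contig == unit.first_contig:
            return False
        if side == "end" and contig == unit.last_contig:
            return True
    return None


def apply_insertions(
    assembly: Assembly,
    insertions: Sequence[Insertion],
    mode: str = "intra_only",
) -> Tuple[Assembly, List[AppliedGap]]:
    """Close gaps with the given insertions under ``mode``.

    Contig bases outside the insertion anchors are never modified;
    unapplied intra-scaffold gaps keep their original N-run length.
    Returns the new assembly and the positions of all inserted cores.
    """
    if mode not in ("intra_only", "intra_and_inter", "free_scaffolding"):
        raise ValueError(f"unknown mode {mode!r}")
    usable = [i for i in insertions if i.validated in ("pending", "pass")]

    intra = [
        i
        for i in usable
        if i.is_input_gap and i.left_side == "end" and i.right_side == "begin"
    ]
    by_pair = {(i.left_contig, i.right_contig): i for i in intra}
    if len(by_pair) < len(intra):
        raise ValueError("conflicting insertions on one contig pair")

    units: List[_Unit] = []
    if mode == "free_scaffolding":
        for contig in assembly.contigs:
            units.append(
                _Unit(contig.id, contig.seq, {contig.id: (0, len(contig.seq))}, [])
            )
        joins = usable
    else:
        for scaffold in assembly:
            units.append(
                _intra_pass(
                    scaffold, by_pair if mode != "free_scaffolding" else {}
                )
            )
        joins = (
            [i for i in usable if i not in intra]
            if mode == "intra_and_inter"
            else []
        )

    if not joins:
        return _finalize(units)

    # resolve inter-scaffold joins by chaining units end-to-end
    unit_of_contig = {
        cid: u for u in units for cid in u.contig_pos
    }
    edges = []  # (insertion, left unit, flip_left, right unit, flip_right)
    used_ports = set()
    for ins in joins:
        ul = unit_of_contig.get(ins.left_contig)
        ur = unit_of_contig.get(ins.right_contig)
        if ul is None or ur is None or ul is ur:
            continue
        fl = _endpoint_orientation(ul, ins.left_contig, ins.left_side, "right")
        fr = _endpoint_orientation(ur, ins.right_contig, ins.right_side, "left")
        if fl is None or fr is None:
            continue
        port_l = (ul.id, "L" if fl else "R")
        port_r = (ur.id, "R" if fr else "L")
        if port_l in used_ports or port_r in used_ports:
            continue
        used_ports.add(port_l)
        used_ports.add(port_r)
        edges.append((ins, ul, fl, ur, fr))

    in_edge = {e[3].id: e for e in edges}
    out_edge = {e[1].id: e for e in edges}
    # a unit entered and left must carry one consistent orientation
    for u in units:
        ein, eout = in_edge.get(u.id), out_edge.get(u.id)
        if ein is not None and eout is not None and ein[4] != eout[2]:
            del out_edge[u.id]
            in_edge.pop(eout[3].id, None)

    merged: List[_Unit] = []
    visited = set()
    starts = [u for u in units if u.id not in in_edge] + list(units)
    for start in starts:
        if start.id in visited:
            continue
        chain: List[Tuple[_Unit, bool, Optional[Insertion]]] = []
        cur = start
        while True:
            visited.add(cur.id)
            ein, eout = in_edge.get(cur.id), out_edge.get(cur.id)
            flip = ein[4] if ein is not None else (eout[2] if eout else False)
            if eout is not None and eout[3].id in visited:
                eout = None  # would close a cycle
            chain.append((cur, bool(flip), eout[0] if eout else None))
            if eout is None:
                break
            cur = eout[3]
        merged.append(_merge_chain(chain))
    return _finalize(merged)


def _merge_chain(
    chain: List[Tuple[_Unit, bool, Optional[Insertion]]]
) -> _Unit:
    if len(chain) == 1 and chain[0][2] is None:
        unit, flip, _ = chain[0]
        return unit.flipped() if flip else unit
    parts: List[str] = []
    contig_pos: Dict[str, Tuple[int, int]] = {}
    records: List[AppliedGap] = []
    pos = 0
    uid_parts = []
    pending: Optional[Insertion] = None  # insertion cutting into this unit
    for unit, flip, ins in chain:
        u = unit.flipped() if flip else unit
        uid_parts.append(u.id)
        start = (
            u.contig_pos[pending.right_contig][0] + pending.cut_right
            if pending is not None
            else 0
        )
        if ins is not None:
            off, _ln = u.contig_pos[ins.left_contig]
            end = off + ins.cut_left
        else:
            end = len(u.seq)
        for cid, (off, ln) in u.contig_pos.items():
            contig_pos[cid] = (pos + off - start, ln)
        for r in u.records:
            records.append(
                AppliedGap(
                    r.gap_id, "", pos + r.core_begin - start, pos + r.core_end - start
                )
            )
        parts.append(u.seq[start:end])
        pos += end - start
        if ins is not None:
            records.append(AppliedGap(ins.gap_id, "", pos, pos + len(ins.core)))
            parts.append(ins.core)
            pos += len(ins.core)
        pending = ins
    uid = "+".join(uid_parts)
    return _Unit(
        uid,
        "".join(parts),
        contig_pos,
        [AppliedGap(r.gap_id, uid, r.core_begin, r.core_end) for r in records],
    )


def _finalize(units: List[_Unit]) -> Tuple[Assembly, List[AppliedGap]]:
    scaffolds = []
    records: List[AppliedGap] = []
    for u in units:
        scaffolds.append(scaffold_from_sequence(u.id, u.seq))
        for r in u.records:
            records.append(AppliedGap(r.gap_id, u.id, r.core_begin, r.core_end))
    return Assembly(scaffolds), records


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def continuous_coverage(
    alns: Sequence[LocalAlignment], region: Interval, w: int = 500
) -> int:
    """Minimum, over window starts x in the region, of the number of
    alignments completely covering [x, x+w).

    Regions shorter than w are evaluated at the single window covering
    the whole region.
    """
    rb, re = region.begin, region.end
    if re - rb <= w:
        return sum(
            1
            for a in alns
            if a.target_id == region.seq_id and a.t_begin <= rb and a.t_end >= re
        )
    n_pos = re - w - rb + 1  # window starts rb .. re-w inclusive
    diff = [0] * (n_pos + 1)
    for a in alns:
        if a.target_id != region.seq_id:
            continue
        lo = max(rb, a.t_begin)
        hi = min(re - w, a.t_end - w)
        if hi < lo:
            continue
        diff[lo - rb] += 1
        diff[hi - rb + 1] -= 1
    depth = 0
    best = None
    for i in range(n_pos):
        depth += diff[i]
        best = depth if best is None else min(best, depth)
    return best or 0


def validate_gaps(
    closed: Assembly,
    records: Sequence[AppliedGap],
    insertions: Sequence[Insertion],
    read_alns: Sequence[LocalAlignment],
    config: Optional[PipelineConfig] = None,
) -> List[Insertion]:
    """Mark each applied insertion pass/fail from re-mapped reads.

    The genomic region region_context upstream and downstream of the
    former gap (clipped to its contig) must be fully spanned by at least
    min_spanning_reads alignments, and the minimum continuous alignment
    coverage must exceed the threshold (default: half the haploid read
    coverage).
    """
    cfg = config or PipelineConfig()
    by_gap = {r.gap_id: r for r in records}
    by_contig: Dict[str, List[LocalAlignment]] = {}
    for a in read_alns:
        by_contig.setdefault(a.target_id, []).append(a)

    out: List[Insertion] = []
    for ins in insertions:
        rec = by_gap.get(ins.gap_id)
        if rec is None:
            out.append(ins)
            continue
        scaffold = next(s for s in closed if s.id == rec.scaffold_id)
        host = None
        for c in scaffold.contigs:
            if (
                c.scaffold_offset <= rec.core_begin
                and c.scaffold_offset + len(c) >= rec.core_end
            ):
                host = c
                break
        if host is None:
            out.append(replace(ins, validated="fail", fail_reason="core split by N"))
            continue
        rb = max(0, rec.core_begin - host.scaffold_offset - cfg.region_context)
        re_ = min(len(host), rec.core_end - host.scaffold_offset + cfg.region_context)
        region = Interval(host.id, rb, re_)
        alns = by_contig.get(host.id, [])
        spanning = sum(1 for a in alns if a.t_begin <= rb and a.t_end >= re_)
        if spanning < cfg.min_spanning_reads:
            out.append(
                replace(ins, validated="fail", fail_reason="too few spanning reads")
            )
            continue
        cov = continuous_coverage(alns, region, cfg.weak_coverage_window)
        if cov <= cfg.validation_min_coverage:
            out.append(
                replace(ins, validated="fail", fail_reason="weak continuous coverage")
            )
            continue
        out.append(replace(ins, validated="pass"))
    return out
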