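"""Reduce read-to-assembly alignments to the reliable set for gap closing.

An alignment is kept when (i) it is proper — unaligned read tails are at
most the allowance or explained by a contig boundary; (ii) it is strongly
anchored — at least ``min_anchor`` bp of its reference interval fall
outside the homogenized repeat mask; (iii) no two retained alignments of
one read claim the same stretch of the read (ambiguous reads are dropped
entirely); and (iv) it touches a contig end — alignments buried inside a
contig cannot help close a gap.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

from .align import LocalAlignment
from .intervals import MaskTrack
from .repeats import is_proper

__all__ = ["filter_reliable"]


def _touches_contig_end(aln: LocalAlignment, allowance: int) -> bool:
    return aln.t_begin < allowance or aln.t_end > aln.target_len - allowance


def filter_reliable(
    read_alns: Sequence[LocalAlignment],
    final_mask: MaskTrack,
    min_anchor: int = 500,
    allowance: int = 100,
) -> List[LocalAlignment]:
    by_read: Dict[str, List[LocalAlignment]] = {}
    for a in read_alns:
        by_read.setdefault(a.query_id, []).append(a)

    out: List[LocalAlignment] = []
    for rid, alns in sorted(by_read.items()):
        proper = [a for a in alns if is_proper(a, allowance, at_target_ends=True)]
        # rule (iii): among proper alignments, read-coordinate overlap
        # beyond the allowance means the read maps ambiguously -> drop it
        proper.sort(key=lambda a: (a.q_begin, a.q_end))
        ambiguous = False
        max_end = -(10**9)
        for a in proper:
            if min(max_end, a.q_end) - a.q_begin > allowance:
                ambiguous = True
                break
            max_end = max(max_end, a.q_end)
        if ambiguous:
            continue
        for a in proper:
            unmasked = a.target_span - final_mask.masked_bases(
                a.target_id, a.t_begin, a.t_end
            )
            if unmasked < min_anchor:
                continue
            if not _touches_contig_end(a, allowance):
                continue
            out.append(a)
    return out
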