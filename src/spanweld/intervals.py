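"""Genomic intervals and per-sequence mask tracks.

All coordinates are 0-based, half-open.  A :class:`MaskTrack` keeps, for
each sequence id, a sorted list of disjoint merged intervals; this is the
common currency of every repeat-annotation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

__all__ = ["Interval", "MaskTrack", "read_bed", "write_bed"]


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval ``[begin, end)`` on sequence ``seq_id``."""

    seq_id: str
    begin: int
    end: int

    def __post_init__(self) -> None:
        if self.begin < 0 or self.end < self.begin:
            raise ValueError(f"invalid interval [{self.begin}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.begin

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.begin < other.end
            and other.begin < self.end
        )

    def intersection_length(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.begin, other.begin))


def _merge_pairs(pairs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping (begin, end) pairs; touching pairs merge."""
    out: List[Tuple[int, int]] = []
    for b, e in sorted(pairs):
        if e <= b:
            continue
        if out and b <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((b, e))
    return out


class MaskTrack:
    """Per-sequence set of sorted, disjoint, merged intervals."""

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        by_seq: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_seq.setdefault(iv.seq_id, []).append((iv.begin, iv.end))
        self._data: Dict[str, List[Tuple[int, int]]] = {
            seq: _merge_pairs(pairs) for seq, pairs in by_seq.items()
        }
        self._data = {seq: pairs for seq, pairs in self._data.items() if pairs}

    # -- construction -------------------------------------------------
    @classmethod
    def from_pairs(cls, data: Dict[str, Sequence[Tuple[int, int]]]) -> "MaskTrack":
        track = cls()
        track._data = {
            seq: _merge_pairs(pairs) for seq, pairs in data.items() if pairs
        }
        track._data = {s: p for s, p in track._data.items() if p}
        return track

    # -- container protocol -------------------------------------------
    def __iter__(self) -> Iterator[Interval]:
        for seq in sorted(self._data):
            for b, e in self._data[seq]:
                yield Interval(seq, b, e)

    def __len__(self) -> int:
        return sum(len(p) for p in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaskTrack):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        return f"MaskTrack({len(self)} intervals on {len(self._data)} seqs)"

    def sequences(self) -> List[str]:
        return sorted(self._data)

    def intervals(self, seq_id: str) -> List[Tuple[int, int]]:
        return list(self._data.get(seq_id, []))

    def total_masked(self, seq_id: str | None = None) -> int:
        if seq_id is not None:
            return sum(e - b for b, e in self._data.get(seq_id, []))
        return sum(e - b for p in self._data.values() for b, e in p)

    # -- set algebra ---------------------------------------------------
    def union(self, other: "MaskTrack") -> "MaskTrack":
        merged: Dict[str, List[Tuple[int, int]]] = {}
        for seq in set(self._data) | set(other._data):
            merged[seq] = self._data.get(seq, []) + other._data.get(seq, [])
        return MaskTrack.from_pairs(merged)

    def intersection(self, other: "MaskTrack") -> "MaskTrack":
        out: Dict[str, List[Tuple[int, int]]] = {}
        for seq in set(self._data) & set(other._data):
            a, b = self._data[seq], other._data[seq]
            res: List[Tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    res.append((lo, hi))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            out[seq] = res
        return MaskTrack.from_pairs(out)

    def subtract(self, other: "MaskTrack") -> "MaskTrack":
        out: Dict[str, List[Tuple[int, int]]] = {}
        for seq, pairs in self._data.items():
            cuts = other._data.get(seq, [])
            res: List[Tuple[int, int]] = []
            for b, e in pairs:
                cur = b
                for cb, ce in cuts:
                    if ce <= cur or cb >= e:
                        continue
                    if cb > cur:
                        res.append((cur, cb))
                    cur = max(cur, ce)
                    if cur >= e:
                        break
                if cur < e:
                    res.append((cur, e))
            out[seq] = res
        return MaskTrack.from_pairs(out)

    # -- queries --------------------------------------------------------
    def masked_bases(self, seq_id: str, begin: int, end: int) -> int:
        """Number of masked bases inside ``[begin, end)`` of ``seq_id``."""
        total = 0
        for b, e in self._data.get(seq_id, []):
            if e <= begin:
                continue
            if b >= end:
                break
            total += min(e, end) - max(b, begin)
        return total

    def contains(self, seq_id: str, pos: int) -> bool:
        for b, e in self._data.get(seq_id, []):
            if b <= pos < e:
                return True
            if b > pos:
                break
        return False


def read_bed(path) -> MaskTrack:
    """Read a BED3 file into a MaskTrack (extra columns ignored)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            intervals.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return MaskTrack(intervals)


def write_bed(track: MaskTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.seq_id}\t{iv.begin}\t{iv.end}\n")
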