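"""Assembly data model: contigs, gaps, scaffolds, and FASTA/AGP I/O.

A scaffold is an ordered list of :class:`Contig` and :class:`Gap`
components.  Runs of ``N`` in the input FASTA become gaps; the flanking
sequence becomes contigs named ``<scaffold>.<ordinal>`` (1-based ordinal).
Terminal N-runs are preserved on round trip but are never candidates for
gap closing — only gaps *between* two contigs are.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Union

from Bio import SeqIO

__all__ = [
    "Contig",
    "Gap",
    "Scaffold",
    "Assembly",
    "read_fasta",
    "write_fasta",
    "write_agp",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_N_RUN = re.compile(r"N+")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """Gap-free stretch of assembled sequence within a scaffold."""

    id: str
    scaffold_id: str
    scaffold_offset: int  # bp from scaffold start
    seq: str

    def __post_init__(self) -> None:
        if "N" in self.seq:
            raise ValueError(f"contig {self.id} contains N")
        if self.scaffold_offset < 0:
            raise ValueError("negative scaffold offset")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Gap:
    """Run of unknown sequence (N's) between contigs of one scaffold."""

    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("gap length must be >= 1")

    def __len__(self) -> int:
        return self.length


Component = Union[Contig, Gap]


@dataclass
class Scaffold:
    id: str
    components: List[Component] = field(default_factory=list)

    @property
    def contigs(self) -> List[Contig]:
        return [c for c in self.components if isinstance(c, Contig)]

    @property
    def sequence(self) -> str:
        parts = []
        for c in self.components:
            parts.append(c.seq if isinstance(c, Contig) else "N" * c.length)
        return "".join(parts)

    def __len__(self) -> int:
        return sum(len(c) for c in self.components)

    def internal_gaps(self) -> List[tuple]:
        """(left contig, gap, right contig) triples for closable gaps.

        Terminal N-runs (no contig on one side) are excluded.
        """
        out = []
        for i, comp in enumerate(self.components):
            if (
                isinstance(comp, Gap)
                and 0 < i < len(self.components) - 1
                and isinstance(self.components[i - 1], Contig)
                and isinstance(self.components[i + 1], Contig)
            ):
                out.append((self.components[i - 1], comp, self.components[i + 1]))
        return out


class Assembly:
    """Ordered collection of scaffolds with contig lookup."""

    def __init__(self, scaffolds: Iterable[Scaffold]):
        self.scaffolds: List[Scaffold] = list(scaffolds)
        seen = set()
        for s in self.scaffolds:
            if s.id in seen:
                raise ValueError(f"duplicate scaffold id {s.id!r}")
            seen.add(s.id)
        self._contig_index: Dict[str, Contig] = {}
        self._scaffold_of: Dict[str, Scaffold] = {}
        for s in self.scaffolds:
            for c in s.contigs:
                self._contig_index[c.id] = c
                self._scaffold_of[c.id] = s

    def __iter__(self):
        return iter(self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)

    @property
    def contigs(self) -> List[Contig]:
        return [c for s in self.scaffolds for c in s.contigs]

    def contig(self, contig_id: str) -> Contig:
        return self._contig_index[contig_id]

    def scaffold_of(self, contig_id: str) -> Scaffold:
        return self._scaffold_of[contig_id]

    def total_bases(self) -> int:
        """Real (non-N) bases across the assembly."""
        return sum(len(c) for c in self.contigs)


def scaffold_from_sequence(scaffold_id: str, seq: str) -> Scaffold:
    """Decompose an uppercased ACGTN string into contigs and gaps."""
    components: List[Component] = []
    pos = 0
    ordinal = 1
    for m in _N_RUN.finditer(seq):
        if m.start() > pos:
            components.append(
                Contig(f"{scaffold_id}.{ordinal}", scaffold_id, pos, seq[pos : m.start()])
            )
            ordinal += 1
        components.append(Gap(m.end() - m.start()))
        pos = m.end()
    if pos < len(seq):
        components.append(Contig(f"{scaffold_id}.{ordinal}", scaffold_id, pos, seq[pos:]))
    return Scaffold(scaffold_id, components)


def read_fasta(path) -> Assembly:
    """Read scaffolds from FASTA.

    Lowercase letters are uppercased (soft-masking ignored); IUPAC
    ambiguity codes other than ACGT become N.  Raises on an empty file or
    duplicate ids.
    """
    scaffolds = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _NON_ACGTN.sub("N", str(record.seq).upper())
        scaffolds.append(scaffold_from_sequence(record.id, seq))
    if not scaffolds:
        raise ValueError(f"no sequences in {path}")
    return Assembly(scaffolds)


def write_fasta(assembly: Assembly | Iterable[Scaffold], path, width: int = 60) -> None:
    scaffolds = assembly.scaffolds if isinstance(assembly, Assembly) else list(assembly)
    with open(path, "w") as fh:
        for s in scaffolds:
            fh.write(f">{s.id}\n")
            seq = s.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_agp(assembly: Assembly | Iterable[Scaffold], path) -> None:
    """Write AGP v2.1: W rows for contigs, N rows for gaps (type scaffold)."""
    scaffolds = assembly.scaffolds if isinstance(assembly, Assembly) else list(assembly)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for s in scaffolds:
            pos = 0
            part = 1
            for comp in s.components:
                begin1 = pos + 1  # AGP is 1-based inclusive
                end1 = pos + len(comp)
                if isinstance(comp, Contig):
                    fh.write(
                        f"{s.id}\t{begin1}\t{end1}\t{part}\tW\t"
                        f"{comp.id}\t1\t{len(comp)}\t+\n"
                    )
                else:
                    fh.write(
                        f"{s.id}\t{begin1}\t{end1}\t{part}\tN\t"
                        f"{len(comp)}\tscaffold\tyes\tpaired-ends\n"
                    )
                pos = end1
                part += 1


def read_reads_fasta(path) -> Dict[str, str]:
    """Read long reads as a plain id -> uppercase sequence mapping."""
    reads: Dict[str, str] = {}
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    for record in SeqIO.parse(str(path), fmt):
        if record.id in reads:
            raise ValueError(f"duplicate read id {record.id!r}")
        reads[record.id] = str(record.seq).upper()
    return reads


def write_reads_fasta(reads: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
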