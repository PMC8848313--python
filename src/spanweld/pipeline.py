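"""End-to-end gap closing: masks, mapping, graph, consensus, validation.

``close_gaps`` is the library entry point the CLI wraps: it takes an
assembly, a read set, and a configuration, and returns the gap-closed
assembly together with per-gap insertion outcomes and the intermediate
artefacts (masks, filtered alignments, pile-ups) for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from .align import Aligner, LocalAlignment
from .assembly import Assembly
from .closer import AppliedGap, apply_insertions, validate_gaps
from .config import PipelineConfig
from .consensus import Insertion, build_insertion, crop_pileup
from .filtering import filter_reliable
from .graph import (
    build_graph,
    prune_and_collect,
    resolve_conflicts,
    resolve_small_cycles,
)
from .intervals import MaskTrack
from .repeats import (
    compute_cmax,
    dust_mask,
    homogenize,
    improper_coverage_mask,
    read_coverage_mask,
    self_alignment_mask,
    tandem_mask,
)

__all__ = ["PipelineResult", "compute_masks", "close_gaps", "map_reads"]


@dataclass
class PipelineResult:
    assembly: Assembly
    insertions: List[Insertion]
    applied: List[AppliedGap]
    final_mask: MaskTrack
    n_reads_mapped: int
    n_filtered_alignments: int
    n_pileups: int

    @property
    def n_closed(self) -> int:
        return sum(1 for i in self.insertions if i.validated == "pass")


def map_reads(
    assembly: Assembly, reads: Dict[str, str], config: PipelineConfig
) -> List[LocalAlignment]:
    """Map all reads against the assembly contigs (local alignments)."""
    contigs = {c.id: c.seq for c in assembly.contigs}
    aligner = Aligner(
        contigs,
        k=config.seed_k,
        max_err=config.max_alignment_error,
        min_length=config.min_alignment_length,
    )
    alns: List[LocalAlignment] = []
    for rid in sorted(reads):
        alns.extend(aligner.map_sequence(rid, reads[rid]))
    return alns


def compute_masks(
    assembly: Assembly,
    read_alns: List[LocalAlignment],
    config: PipelineConfig,
) -> Dict[str, MaskTrack]:
    """The four repeat annotations plus their homogenized union."""
    contigs = {c.id: c.seq for c in assembly.contigs}
    seq_lens = {cid: len(s) for cid, s in contigs.items()}

    dust = dust_mask(contigs)
    tandem = tandem_mask(contigs)

    self_aligner = Aligner(
        contigs,
        k=config.seed_k,
        max_err=config.max_alignment_error,
        min_length=config.min_alignment_length,
    )
    self_alns: List[LocalAlignment] = []
    for cid in sorted(contigs):
        self_alns.extend(
            self_aligner.map_sequence(cid, contigs[cid], exclude_self_diagonal=True)
        )
    selfm = self_alignment_mask(self_alns, seq_lens, config.max_coverage_self)

    c_max = (
        config.max_coverage_reads
        if config.max_coverage_reads is not None
        else compute_cmax(config.read_coverage, config.cmax_tail_prob)
    )
    cov = read_coverage_mask(read_alns, seq_lens, c_max)
    improper = improper_coverage_mask(
        read_alns,
        seq_lens,
        config.improper_threshold,
        config.proper_alignment_allowance,
    )
    final = homogenize([dust, tandem, selfm, cov, improper], read_alns)
    return {
        "dust": dust,
        "tandem": tandem,
        "self": selfm,
        "reads": cov.union(improper),
        "final": final,
    }


def close_gaps(
    assembly: Assembly,
    reads: Dict[str, str],
    config: Optional[PipelineConfig] = None,
    mode: str = "intra_only",
) -> PipelineResult:
    """Run the whole pipeline and return the gap-closed assembly."""
    cfg = config or PipelineConfig()

    read_alns = map_reads(assembly, reads, cfg)
    masks = compute_masks(assembly, read_alns, cfg)
    filtered = filter_reliable(
        read_alns,
        masks["final"],
        min_anchor=cfg.min_anchor_length,
        allowance=cfg.proper_alignment_allowance,
    )

    g = build_graph(assembly, filtered, cfg)
    g = resolve_small_cycles(g, reads, assembly, cfg)
    g = resolve_conflicts(g, cfg.best_pile_up_margin, cfg.existing_gap_bonus)
    min_span = 1 if cfg.allow_single_reads else cfg.min_spanning_reads
    pileups = prune_and_collect(g, min_span)

    insertions: List[Insertion] = []
    for pileup in pileups:
        cropped = crop_pileup(pileup, assembly, reads, cfg)
        if cropped is None:
            continue
        ins = build_insertion(cropped, cfg)
        if ins is not None:
            insertions.append(ins)

    pending = [i for i in insertions if i.validated == "pending"]
    draft, records = apply_insertions(assembly, pending, mode)
    draft_alns = map_reads(draft, reads, cfg)
    checked = validate_gaps(draft, records, pending, draft_alns, cfg)

    passed = [i for i in checked if i.validated == "pass"]
    final_assembly, applied = apply_insertions(assembly, passed, mode)

    failed = [i for i in checked if i.validated != "pass"] + [
        i for i in insertions if i.validated == "fail"
    ]
    return PipelineResult(
        assembly=final_assembly,
        insertions=passed + failed,
        applied=applied,
        final_mask=masks["final"],
        n_reads_mapped=len({a.query_id for a in read_alns}),
        n_filtered_alignments=len(filtered),
        n_pileups=len(pileups),
    )
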