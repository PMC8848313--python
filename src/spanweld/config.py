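"""Pipeline configuration.

Field names mirror the command-line flags (kebab-case on the CLI):
``--max-coverage-self``, ``--proper-alignment-allowance``,
``--min-anchor-length``, ``--best-pile-up-margin``, ``--existing-gap-bonus``,
``--min-spanning-reads``, ``--max-indel``, ``--max-chain-gap``,
``--max-relative-overlap``, ``--bad-fraction``, ``--region-context``,
``--weak-coverage-window``, ``--min-coverage-reads``, ``--read-coverage``,
``--ploidy``, ``--cmax-tail-prob``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Optional

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    #: global long-read coverage C (summed read length / genome size)
    read_coverage: float = 20.0
    ploidy: int = 1

    # repeat annotation
    max_coverage_self: int = 4
    max_coverage_reads: Optional[int] = None  # C_max override; else Poisson-derived
    cmax_tail_prob: float = 1e-3
    max_improper_coverage_reads: Optional[float] = None  # default C/2

    # alignment filtering
    proper_alignment_allowance: int = 100  # bp of unaligned read tail tolerated
    min_anchor_length: int = 500  # bp of non-repetitive reference anchor

    # scaffold graph
    best_pile_up_margin: float = 3.0
    existing_gap_bonus: float = 6.0
    min_spanning_reads: int = 3
    allow_single_reads: bool = False

    # chaining
    max_indel: int = 1000  # bp, bound on gapSizeDiff
    max_chain_gap: int = 10000  # bp, bound on gap_A and gap_B
    max_relative_overlap: float = 0.3

    # consensus
    bad_fraction: float = 0.08
    qv_window: int = 100  # bp, intrinsic QV window
    consensus_window: int = 100  # bp, majority-vote window
    anchor_exact_run: int = 24  # bp of exact match required at insert sites

    # validation
    region_context: int = 1000  # bp of flank inspected around a closed gap
    weak_coverage_window: int = 500  # bp, continuous-coverage window w
    min_coverage_reads: Optional[float] = None  # default 0.5 * C / ploidy

    # built-in aligner
    seed_k: int = 12
    max_alignment_error: float = 0.25
    min_alignment_length: int = 200

    def __post_init__(self) -> None:
        positive = [
            "read_coverage",
            "max_coverage_self",
            "proper_alignment_allowance",
            "min_anchor_length",
            "best_pile_up_margin",
            "existing_gap_bonus",
            "min_spanning_reads",
            "max_indel",
            "max_chain_gap",
            "region_context",
            "weak_coverage_window",
            "qv_window",
            "consensus_window",
            "anchor_exact_run",
            "seed_k",
            "min_alignment_length",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.bad_fraction < 1:
            raise ValueError("bad_fraction must lie in (0, 1)")
        if not 0 < self.max_relative_overlap <= 1:
            raise ValueError("max_relative_overlap must lie in (0, 1]")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 0 < self.cmax_tail_prob < 1:
            raise ValueError("cmax_tail_prob must lie in (0, 1)")

    # -- derived defaults ----------------------------------------------
    @property
    def improper_threshold(self) -> float:
        """Improper-alignment depth above which a region is repetitive."""
        if self.max_improper_coverage_reads is not None:
            return self.max_improper_coverage_reads
        return self.read_coverage / 2.0

    @property
    def validation_min_coverage(self) -> float:
        """Minimum continuous alignment coverage for validating a gap:
        half the read coverage expected from a haploid locus."""
        if self.min_coverage_reads is not None:
            return self.min_coverage_reads
        return 0.5 * self.read_coverage / self.ploidy

    # -- (de)serialisation ---------------------------------------------
    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from JSON or TOML, keys in snake_case or kebab-case."""
        text = open(path).read()
        if str(path).endswith(".toml"):
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for key, val in data.items():
            name = key.replace("-", "_")
            if name not in known:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[name] = val
        return cls(**kwargs)
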