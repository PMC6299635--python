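"""Pipeline configuration.

Every tunable threshold of the method is a named field with its published
default, so a run can be reproduced (or re-tuned) from a single YAML block.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format=LOG_FORMAT)


@dataclass
class PipelineConfig:
    """All thresholds of the four-phase insertion caller.

    Defaults are the published ones: clip length > 5 bp, breakpoint support
    > 10% of coverage, clipped base quality > 59 (ASCII encoding, i.e.
    phred > 26 at offset 33), profile similarity > 95% over >= 10 bp,
    zygosity ratios 10%/90%, breakpoint vicinity < 25 bp, homology identity
    > 90% over > 70% of the mean read length, assembly k = 51 with contigs
    >= 500 bp, <= 5 alignments per read, >= 2 supporting reads per contig,
    boundary-trimming DP scores 1/-3/-5/-2 with the 75% acceptance rule,
    and 20 bp breakpoint-matching tolerance.
    """

    # inputs / outputs
    sam_path: Optional[str] = None
    reference_path: Optional[str] = None
    library_path: Optional[str] = None
    output_dir: str = "mgescout_out"

    # read classification
    min_clip_length: int = 5          # clips must be strictly longer
    max_insert: int = 500             # distant-pair rescue threshold (bp)

    # breakpoint prediction
    min_support_fraction: float = 0.10
    clip_quality_threshold: float = 59.0
    clip_quality_mode: str = "ascii"  # "ascii" (phred+33) or "phred"
    min_profile_length: int = 10
    min_profile_similarity: float = 0.95
    polya_fraction: float = 0.8       # A/T dominance that bypasses the profile
    het_min_ratio: float = 0.10
    hom_min_ratio: float = 0.90
    call_heterozygous: bool = True
    max_vicinity: int = 25            # breakpoint interval width strictly below
    coverage_window: int = 100        # half-window for local coverage
    repeat_flank: int = 50
    depth_imbalance: float = 3.0

    # MGE annotation
    min_identity: float = 0.90
    min_length_fraction: float = 0.70
    support_window: int = 500         # anchor-to-breakpoint distance (insert size)
    homology_match: int = 1
    homology_mismatch: int = -2
    homology_gap_open: int = -5
    homology_gap_extend: int = -2

    # de novo assembly
    assemble: bool = True
    kmer_size: int = 51
    min_contig_length: int = 500
    max_alignments_per_read: int = 5
    min_read_support: int = 2
    trim_match: int = 1
    trim_mismatch: int = -3
    trim_gap_open: int = -5
    trim_gap_extend: int = -2
    accept_fraction: float = 0.75

    # evaluation
    tolerance: int = 20

    # misc
    seed: int = 1
    threads: int = 1                  # accepted for symmetry; results never depend on it
    log_level: str = "INFO"

    # filter toggles (QC / ablation; all on by default)
    enable_support_filter: bool = True
    enable_quality_filter: bool = True
    enable_profile_filter: bool = True
    enable_zygosity_filter: bool = True
    enable_repeat_filter: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate_inputs(self) -> None:
        """Collect every missing input in one error message."""
        problems = []
        for label, p in (("SAM", self.sam_path), ("reference FASTA", self.reference_path),
                         ("MGE library FASTA", self.library_path)):
            if p is None:
                problems.append(f"{label} path not set")
            elif not Path(p).exists():
                problems.append(f"{label} not found: {p}")
        if problems:
            raise FileNotFoundError("; ".join(problems))
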