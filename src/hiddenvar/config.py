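"""Pipeline-wide configuration.

Every numeric constant used by a pipeline stage lives here exactly once, so a
run is fully described by one :class:`PipelineConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds for every stage of the rescued-read pipeline.

    Defaults are the analysis constants: MAPQ < 20 defines a poorly aligned
    read, contigs < 1 kb are discarded, contigs are collapsed when > 90 % of
    the shorter contig aligns to the larger, direct placements need an
    alignment block >= 500 bp, presence/absence LD uses r^2 > 0.9, pair
    proximity is judged at 10 kb, GWAS distance sweeps at 0/100/1000 bp,
    biobank peaks are merged within 50 kb and related to contigs within 1 Mb
    at p <= 1e-6, and RNA-seq tallies are reported at > 100 and > 1000 reads.
    """

    mapq_threshold: int = 20
    min_contig_length: int = 1000
    collapse_threshold: float = 0.9
    min_block: int = 500
    min_anchors: int = 2
    mate_window: int = 1000
    agree_window: int = 100_000
    anchor_window: int = 100_000
    r2_threshold: float = 0.9
    ld_distance: int = 10_000
    gwas_thresholds: tuple[int, ...] = (0, 100, 1000)
    peak_merge: int = 50_000
    peak_distance: int = 1_000_000
    p_threshold: float = 1e-6
    id_min: float = 0.9
    cov_min: float = 0.5
    cross_mapq_min: int = 30
    vcf_window: int = 1000
    rna_thresholds: tuple[int, ...] = (100, 1000)
    blast_evalue_max: float = 1e-5
    blast_alen_min: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mapq_threshold", "min_contig_length", "min_block", "min_anchors",
            "mate_window", "agree_window", "anchor_window", "ld_distance",
            "peak_merge", "peak_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.collapse_threshold <= 1:
            raise ValueError("collapse_threshold must be in (0, 1]")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gwas_thresholds"] = list(self.gwas_thresholds)
        d["rna_thresholds"] = list(self.rna_thresholds)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gwas_thresholds" in raw:
            raw["gwas_thresholds"] = tuple(raw["gwas_thresholds"])
        if "rna_thresholds" in raw:
            raw["rna_thresholds"] = tuple(raw["rna_thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
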