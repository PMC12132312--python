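"""Configuration and ground-truth containers for the synthetic cohort.

The generator plants non-reference insertions into a random reference at
controlled population frequencies, emits reads/alignments/contigs/catalogs
from that truth, and records everything in a :class:`TruthManifest` so every
downstream result can be checked against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    ``seed`` fixes all outputs byte-identically. Insertion frequencies are
    cycled over insertions; each donor carries insertion *m* independently
    with probability ``f_m`` and each carried copy receives point mutations at
    ``mutation_rate`` (exercising the 90 %-containment collapsing rule).
    ``unplaceable_fraction`` of insertions are emitted without reference
    flanks, so their contigs have no direct reference alignment;
    ``n_linked_pairs`` leading insertion pairs share identical carrier sets
    (perfect presence/absence linkage by construction).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_donors: int = 20
    n_insertions: int = 12
    insertion_length_range: tuple[int, int] = (1000, 3000)
    insertion_frequencies: tuple[float, ...] = (0.5, 0.25, 0.1, 0.75, 1.0)
    read_length: int = 100
    insert_mean: int = 350
    insert_sd: int = 50
    coverage: float = 3.0
    error_rate: float = 0.001
    n_contaminants: int = 3
    mutation_rate: float = 0.002
    flank_len: int = 600
    unplaceable_fraction: float = 0.1
    low_mapq_fraction: float = 0.05
    n_linked_pairs: int = 1
    min_locus_separation: int = 12_000

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("chromosome count and length must be positive")
        if self.n_donors <= 0:
            raise ValueError("n_donors must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length <= 0 or self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be at least twice read_length")
        lo, hi = self.insertion_length_range
        if lo < 1000 or hi < lo:
            raise ValueError(
                "insertion_length_range minimum is 1000 bp (planted contigs "
                "must survive the 1 kb filter unless deliberately short)"
            )
        for f in self.insertion_frequencies:
            if not 0 < f <= 1:
                raise ValueError(f"insertion frequency {f} outside (0, 1]")
        if 2 * self.n_linked_pairs > self.n_insertions:
            raise ValueError("too many linked pairs for n_insertions")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def donor_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_donors)]

    def frequency_of(self, ins_index: int) -> float:
        return self.insertion_frequencies[ins_index % len(self.insertion_frequencies)]


@dataclass
class InsertionTruth:
    """One planted non-reference insertion."""

    insertion_id: str
    chrom: str
    point: int            # 0-based: inserted immediately before reference base `point`
    length: int
    sequence: str
    frequency: float
    carriers: list[str]
    placeable: bool
    linked_partner: str | None = None


@dataclass
class ContaminantTruth:
    """One contaminant sequence injected as read pairs and contigs."""

    contaminant_id: str
    sequence: str
    donors: list[str]
    label: str            # classifier label, e.g. a bacterial taxon name


@dataclass
class FeatureTruth:
    ftype: str            # gene / transcript / exon / CDS
    chrom: str
    start: int            # 0-based half-open
    end: int
    name: str
    near_insertion: str


@dataclass
class GwasSiteTruth:
    site_id: str
    chrom: str
    pos: int              # 0-based
    offset: int           # designed distance to the insertion's placement interval
    near_insertion: str


@dataclass
class SumstatLocusTruth:
    trait: str
    chrom: str
    pos: int
    neglog10p: float
    cluster: str          # loci sharing a cluster id lie within the merge window
    near_insertion: str | None


@dataclass
class TruthManifest:
    """Everything the generator planted, keyed by unique identifiers."""

    insertions: list[InsertionTruth] = field(default_factory=list)
    contaminants: list[ContaminantTruth] = field(default_factory=list)
    features: list[FeatureTruth] = field(default_factory=list)
    gwas_sites: list[GwasSiteTruth] = field(default_factory=list)
    sumstat_loci: list[SumstatLocusTruth] = field(default_factory=list)
    rna_counts: dict[str, int] = field(default_factory=dict)
    vcf_calls: list[dict] = field(default_factory=list)

    def insertion(self, insertion_id: str) -> InsertionTruth:
        for ins in self.insertions:
            if ins.insertion_id == insertion_id:
                return ins
        raise KeyError(insertion_id)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            insertions=[InsertionTruth(**d) for d in raw["insertions"]],
            contaminants=[ContaminantTruth(**d) for d in raw["contaminants"]],
            features=[FeatureTruth(**d) for d in raw["features"]],
            gwas_sites=[GwasSiteTruth(**d) for d in raw["gwas_sites"]],
            sumstat_loci=[SumstatLocusTruth(**d) for d in raw["sumstat_loci"]],
            rna_counts=raw.get("rna_counts", {}),
            vcf_calls=raw.get("vcf_calls", []),
        )
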