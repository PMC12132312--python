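"""Intersections of placed contigs with annotations, GWAS sites and
biobank association peaks.

Gene features come from GFF3 (1-based closed, converted to 0-based half-open
at parse time); GWAS sites from BED; trait summary statistics from a TSV with
columns chrom/pos/trait/neglog10p. Distance from a placement interval to a
point is zero on containment and otherwise the distance to the nearer of the
interval's first/last base; all distance thresholds are inclusive. Peak
calling keeps, per trait, the most significant locus of every 50 kb cluster
of significant loci (greedy by significance, ties to the left).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from hiddenvar.placement import Placement

logger = logging.getLogger(__name__)

_KNOWN_FTYPES = {"gene", "transcript", "exon", "CDS"}


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int            # 0-based half-open
    end: int
    ftype: str            # gene/transcript/exon/CDS/other
    name: str
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty feature interval for {self.name}")


@dataclass(frozen=True)
class GwasSite:
    chrom: str
    pos: int              # 0-based
    site_id: str
    trait: str | None = None


@dataclass(frozen=True)
class Peak:
    trait: str
    chrom: str
    pos: int
    neglog10p: float


def read_gff3(path: str | Path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = tuple(
                tuple(kv.split("=", 1))
                for kv in f[8].split(";")
                if "=" in kv
            )
            name = dict(attrs).get("Name", dict(attrs).get("ID", f[2]))
            ftype = f[2] if f[2] in _KNOWN_FTYPES else "other"
            features.append(Feature(
                chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
                ftype=ftype, name=name, attributes=attrs,
            ))
    return features


def read_gwas_bed(path: str | Path) -> list[GwasSite]:
    sites = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            sites.append(GwasSite(
                chrom=f[0], pos=int(f[1]),
                site_id=f[3] if len(f) > 3 else f"site{i}",
            ))
    return sites


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """TSV with header chrom/pos/trait/neglog10p; malformed significance
    values are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trait": str})
    df["neglog10p"] = pd.to_numeric(df["neglog10p"], errors="coerce")
    bad = df["neglog10p"].isna() | df["pos"].isna()
    if bad.any():
        logger.warning("skipped %d malformed summary rows", int(bad.sum()))
    return df[~bad].reset_index(drop=True)


def interval_point_distance(start: int, end: int, pos: int) -> int:
    """0 if start <= pos < end, else distance to the nearer of the interval's
    first and last base."""
    if start <= pos < end:
        return 0
    return min(abs(pos - start), abs(pos - (end - 1)))


def intersect_features(
    placements: Iterable[Placement], features: Sequence[Feature]
) -> tuple[pd.DataFrame, dict]:
    """Half-open interval overlap (>= 1 shared base) of placements against
    features, with per-type totals, unique-element counts and per-donor /
    per-chromosome tallies."""
    trees: dict[str, IntervalTree] = {}
    for i, feat in enumerate(features):
        trees.setdefault(feat.chrom, IntervalTree())[feat.start:feat.end] = i

    rows = []
    placements = list(placements)
    chroms_seen = {f.chrom for f in features}
    for p in placements:
        tree = trees.get(p.chrom)
        if tree is None:
            if p.chrom not in chroms_seen:
                logger.warning("placement chromosome %s absent from annotation",
                               p.chrom)
            continue
        for iv in sorted(tree.overlap(p.start, p.end)):
            feat = features[iv.data]
            rows.append((
                p.contig_id, p.contig_id.split(".")[0], p.chrom, p.start, p.end,
                feat.ftype, feat.name, feat.start, feat.end,
            ))
    table = pd.DataFrame(rows, columns=[
        "contig_id", "donor_id", "chrom", "placement_start", "placement_end",
        "ftype", "feature_name", "feature_start", "feature_end",
    ])
    summary = {
        "n_intersections": len(table),
        "per_ftype": table.groupby("ftype").size().to_dict() if len(table) else {},
        "unique_per_ftype": (
            table.groupby("ftype")["feature_name"].nunique().to_dict()
            if len(table) else {}
        ),
        "per_donor": table.groupby("donor_id").size().to_dict() if len(table) else {},
        "per_chromosome": table.groupby("chrom").size().to_dict() if len(table) else {},
    }
    return table, summary


def gwas_distance_sweep(
    placements: Iterable[Placement],
    sites: Sequence[GwasSite],
    thresholds: Sequence[int] = (0, 100, 1000),
) -> tuple[pd.DataFrame, dict]:
    """Distances between every placement and every same-chromosome GWAS site,
    swept over inclusive distance thresholds.

    Returns the distance table (restricted to the largest threshold) and, per
    threshold, the number of placements with a site within it and the number
    of distinct sites hit.
    """
    max_t = max(thresholds)
    rows = []
    for p in placements:
        for s in sites:
            if s.chrom != p.chrom:
                continue
            d = interval_point_distance(p.start, p.end, s.pos)
            if d <= max_t:
                rows.append((p.contig_id, s.site_id, p.chrom, d))
    table = pd.DataFrame(rows, columns=["contig_id", "site_id", "chrom", "distance"])
    sweep = {}
    for t in thresholds:
        sub = table[table["distance"] <= t]
        sweep[int(t)] = {
            "n_placements": int(sub["contig_id"].nunique()),
            "n_unique_sites": int(sub["site_id"].nunique()),
            "n_pairs": len(sub),
        }
    return table, sweep


def biobank_peak_sweep(
    summary: pd.DataFrame,
    p_threshold: float = 1e-6,
    merge_window: int = 50_000,
) -> list[Peak]:
    """Significant loci (p <= threshold i.e. neglog10p >= -log10 threshold)
    reduced to representative peaks: loci are visited by descending
    significance (ties: position ascending) and retained unless an
    already-retained peak for the trait lies on the same chromosome within
    the merge window."""
    cutoff = -math.log10(p_threshold)
    sig = summary[summary["neglog10p"] >= cutoff]
    peaks: list[Peak] = []
    for trait, group in sig.groupby("trait", sort=True):
        ordered = group.sort_values(
            ["neglog10p", "pos", "chrom"], ascending=[False, True, True]
        )
        retained: list[Peak] = []
        for row in ordered.itertuples():
            if any(
                pk.chrom == row.chrom and abs(pk.pos - row.pos) <= merge_window
                for pk in retained
            ):
                continue
            retained.append(Peak(trait, row.chrom, int(row.pos),
                                 float(row.neglog10p)))
        peaks.extend(retained)
    return peaks


def peak_contig_proximity(
    peaks: Iterable[Peak],
    placements: Iterable[Placement],
    distance: int = 1_000_000,
) -> tuple[pd.DataFrame, dict]:
    """All peak/placed-contig pairs within the inclusive distance, using the
    same interval-to-point distance as the GWAS sweep, plus per-trait counts."""
    placements = list(placements)
    rows = []
    for pk in peaks:
        for p in placements:
            if p.chrom != pk.chrom:
                continue
            d = interval_point_distance(p.start, p.end, pk.pos)
            if d <= distance:
                rows.append((pk.trait, pk.chrom, pk.pos, p.contig_id, d))
    table = pd.DataFrame(
        rows, columns=["trait", "chrom", "peak_pos", "contig_id", "distance"]
    )
    summary = {
        "n_pairs": len(table),
        "per_trait": table.groupby("trait").size().to_dict() if len(table) else {},
        "n_traits_with_nearby_contig": (
            int(table["trait"].nunique()) if len(table) else 0
        ),
    }
    return table, summary
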