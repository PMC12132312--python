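"""Orthogonal support for assembled contigs: long reads, RNA-seq, cross-set
alignment and SV-caller comparison.

A contig is long-read validated when its best alignment to the donor's
long-read assembly has identity (residue matches / block length) of at least
``id_min`` and the union of its aligned query intervals covers at least
``cov_min`` of its length. Validation rates of downstream intersections
(genes, GWAS proximity) follow from which contigs validate. Rescued-read
accounting measures how many previously extracted reads align well (MAPQ >=
20) to the new assembly. RNA-seq tallies count primary alignments per contig
(secondary/supplementary records are ignored to avoid multi-mapping inflation
on near-identical contigs) with strict > thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from hiddenvar.annotate import interval_point_distance
from hiddenvar.pafio import AlignmentRecord
from hiddenvar.placement import Placement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationResult:
    contig_id: str
    validated: bool
    best_identity: float
    aligned_fraction: float


@dataclass(frozen=True)
class RnaTally:
    contig_id: str
    read_count: int
    density: float        # reads per kb of contig
    shared: bool | None


def _query_union(intervals: list[tuple[int, int]]) -> int:
    total, end = 0, -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def validate_contigs(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: dict[str, int],
    id_min: float = 0.9,
    cov_min: float = 0.5,
) -> tuple[list[ValidationResult], dict]:
    """Judge each contig against its long-read assembly alignments; contigs
    with no alignment fail. Returns per-contig results and the overall rate
    with its denominator."""
    best_id: dict[str, float] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for rec in alignments:
        if rec.query_id not in contig_lengths:
            logger.warning("validation alignment for unknown contig %s",
                           rec.query_id)
            continue
        best_id[rec.query_id] = max(best_id.get(rec.query_id, 0.0), rec.identity)
        intervals.setdefault(rec.query_id, []).append((rec.qstart, rec.qend))

    results = []
    for cid in sorted(contig_lengths):
        ident = best_id.get(cid, 0.0)
        frac = _query_union(intervals.get(cid, [])) / contig_lengths[cid]
        results.append(ValidationResult(
            cid, ident >= id_min and frac >= cov_min, ident, frac,
        ))
    n_val = sum(r.validated for r in results)
    rate = {
        "n_validated": n_val,
        "n_total": len(results),
        "pct_validated": 100.0 * n_val / len(results) if results else 0.0,
    }
    return results, rate


def validated_rate(
    contig_ids: Iterable[str],
    validated: set[str],
    evaluable: set[str] | None = None,
) -> dict:
    """Fraction of intersections whose contig is validated.

    ``contig_ids`` may repeat (one entry per intersection). Intersections
    whose contig has no long-read data (absent from ``evaluable``) are
    excluded from the denominator and counted separately.
    """
    ids = list(contig_ids)
    if evaluable is None:
        in_scope = ids
        n_excluded = 0
    else:
        in_scope = [c for c in ids if c in evaluable]
        n_excluded = len(ids) - len(in_scope)
    n_val = sum(c in validated for c in in_scope)
    n = len(in_scope)
    return {
        "n_validated": n_val,
        "n_evaluable": n,
        "n_excluded": n_excluded,
        "pct_validated": 100.0 * n_val / n if n else 0.0,
    }


def validated_intersection_rates(
    category_intersections: dict[str, Iterable[str]],
    validated: set[str],
    evaluable: set[str] | None = None,
) -> dict[str, dict]:
    """Per-category validation rates (e.g. gene, GWAS-within-100 bp,
    GWAS-within-1 kb)."""
    return {
        cat: validated_rate(ids, validated, evaluable)
        for cat, ids in category_intersections.items()
    }


def rescued_read_fraction(sam_path: str | Path, mapq_min: int = 20) -> dict:
    """Fraction of previously extracted reads now aligning (MAPQ >= mapq_min)
    to the new assembly."""
    n_total = n_rescued = 0
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        pysam.set_verbosity(save)
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            n_total += 1
            if not rec.is_unmapped and rec.mapping_quality >= mapq_min:
                n_rescued += 1
    return {
        "n_rescued": n_rescued,
        "n_total": n_total,
        "fraction": n_rescued / n_total if n_total else 0.0,
    }


def rnaseq_tally(
    sam_path: str | Path,
    contig_lengths: dict[str, int],
    shared_flags: dict[str, bool] | None = None,
    thresholds: Sequence[int] = (100, 1000),
) -> tuple[list[RnaTally], dict]:
    """Per-contig primary-alignment counts, density per kb and strict >
    threshold counts; the shared flag is joined from collapse membership."""
    counts: dict[str, int] = {}
    n_primary = 0
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        pysam.set_verbosity(save)
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            cid = rec.reference_name
            if cid not in contig_lengths:
                logger.warning("RNA alignment to unknown contig %s", cid)
                continue
            n_primary += 1
            counts[cid] = counts.get(cid, 0) + 1

    tallies = [
        RnaTally(
            cid, n, n / (contig_lengths[cid] / 1000),
            shared_flags.get(cid) if shared_flags else None,
        )
        for cid, n in sorted(counts.items())
    ]
    summary = {
        "n_primary_alignments": n_primary,
        "threshold_counts": {
            int(t): sum(1 for x in tallies if x.read_count > t) for t in thresholds
        },
    }
    return tallies, summary


def cross_set_summary(
    alignments: Iterable[AlignmentRecord],
    query_ids: Iterable[str],
    id_min: float = 0.9,
    mapq_min: int = 30,
    cov_min: float = 0.5,
) -> dict:
    """Fraction of set-A contigs with a high-identity, high-mapping-quality,
    high-coverage alignment into set B (any single alignment must pass all
    three filters)."""
    hit: set[str] = set()
    for rec in alignments:
        if (
            rec.identity >= id_min
            and rec.mapq >= mapq_min
            and (rec.qend - rec.qstart) / rec.query_len >= cov_min
        ):
            hit.add(rec.query_id)
    ids = set(query_ids)
    n_hit = len(hit & ids)
    return {
        "n_with_hit": n_hit,
        "n_queries": len(ids),
        "fraction": n_hit / len(ids) if ids else 0.0,
    }


def read_insertion_calls(vcf_path: str | Path) -> list[dict]:
    """INS (and BND, treated as point loci) calls from a VCF; records without
    an SVTYPE are skipped with a warning. Positions are 0-based."""
    calls = []
    save = pysam.set_verbosity(0)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        pysam.set_verbosity(save)
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                logger.warning("VCF record %s has no SVTYPE; skipped", rec.id)
                continue
            if svtype not in ("INS", "BND"):
                continue
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            calls.append({
                "call_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.start,          # pysam: 0-based
                "svtype": svtype,
                "svlen": abs(int(svlen)) if svlen is not None else None,
            })
    return calls


_SVLEN_BINS = ((0, 100), (100, 500), (500, 1000), (1000, None))


def overlap_vcf_insertions(
    placements: Iterable[Placement],
    calls: list[dict],
    window: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Match placements against insertion calls within an inclusive window,
    summarising matches both ways and stratifying calls by SVLEN."""
    placements = list(placements)
    rows = []
    matched_placements: set[str] = set()
    matched_calls: set[str] = set()
    for call in calls:
        for p in placements:
            if p.chrom != call["chrom"]:
                continue
            d = interval_point_distance(p.start, p.end, call["pos"])
            if d <= window:
                rows.append((p.contig_id, call["call_id"], call["svtype"],
                             call["svlen"], d))
                matched_placements.add(p.contig_id)
                matched_calls.add(call["call_id"])
    table = pd.DataFrame(
        rows, columns=["contig_id", "call_id", "svtype", "svlen", "distance"]
    )

    def bin_label(lo, hi):
        return f"{lo}-{hi}" if hi else f">={lo}"

    by_bin = {}
    for lo, hi in _SVLEN_BINS:
        in_bin = [
            c for c in calls
            if c["svlen"] is not None and c["svlen"] >= lo
            and (hi is None or c["svlen"] < hi)
        ]
        by_bin[bin_label(lo, hi)] = {
            "n_calls": len(in_bin),
            "n_matched": sum(c["call_id"] in matched_calls for c in in_bin),
        }
    n_placements = len({p.contig_id for p in placements})
    summary = {
        "n_placements": n_placements,
        "n_placements_matched": len(matched_placements),
        "n_placements_unmatched": n_placements - len(matched_placements),
        "n_calls": len(calls),
        "n_calls_matched": len(matched_calls),
        "n_calls_unmatched": len(calls) - len(matched_calls),
        "svlen_bins": by_bin,
        "window": window,
    }
    return table, summary
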