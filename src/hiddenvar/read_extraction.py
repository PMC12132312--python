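"""Classification of alignment records and extraction of rescued reads.

Primary paired records are partitioned into five mutually exclusive classes:
well mapped, poorly mapped (MAPQ < 20), unmapped with unmapped mate, unmapped
with mapped mate, and mapped with unmapped mate. The strict extraction mode
recovers the fully unmapped pairs plus the unmapped halves of half-mapped
pairs; the loose mode additionally recovers poorly mapped reads and their
mates so that pairs stay intact for assembly. Every extracted read whose mate
is mapped contributes a mate anchor (chromosome, position, strand, MAPQ) used
later for contig placement.

Coordinates are 0-based half-open internally (converted from the 1-based
source format at parse time, which pysam already does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_THRESHOLD = 20


class ReadClass(Enum):
    WELL_MAPPED = "well_mapped"
    POORLY_MAPPED = "poorly_mapped"
    UNMAPPED_PAIR = "unmapped_pair"
    HALF_MAPPED_UNMAPPED_MATE = "half_mapped_unmapped_mate"
    HALF_MAPPED_MAPPED_MATE = "half_mapped_mapped_mate"


class RecordError(ValueError):
    """Raised for records the classifier does not accept (unpaired,
    secondary or supplementary)."""


@dataclass(frozen=True)
class MateAnchor:
    """The mapped mate of an extracted read, anchoring its contig."""

    read_id: str
    donor_id: str
    mate_chrom: str
    mate_pos: int          # 0-based
    mate_strand: str
    mate_mapq: int


def classify_read(
    record: pysam.AlignedSegment, mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD
) -> ReadClass:
    """Deterministic class of one primary paired record.

    The MAPQ threshold is strict: a mapped read with MAPQ 19 is poorly
    mapped, MAPQ 20 is well mapped.
    """
    if record.is_secondary or record.is_supplementary:
        raise RecordError(f"secondary/supplementary record: {record.query_name}")
    if not record.is_paired:
        raise RecordError(f"unpaired record: {record.query_name}")
    if record.is_unmapped:
        if record.mate_is_unmapped:
            return ReadClass.UNMAPPED_PAIR
        return ReadClass.HALF_MAPPED_UNMAPPED_MATE
    if record.mate_is_unmapped:
        return ReadClass.HALF_MAPPED_MAPPED_MATE
    if record.mapping_quality < mapq_threshold:
        return ReadClass.POORLY_MAPPED
    return ReadClass.WELL_MAPPED


def _iter_primary(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        pysam.set_verbosity(save)
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            yield rec


def _read_id(rec: pysam.AlignedSegment) -> str:
    return f"{rec.query_name}/{1 if rec.is_read1 else 2}"


@dataclass
class ExtractionResult:
    class_counts: dict[ReadClass, int]
    n_extracted: int
    anchors: list[MateAnchor]
    fastq_paths: dict[str, Path]


def extract_read_sets(
    sam_path: str | Path,
    outdir: str | Path,
    donor_id: str,
    mode: str = "strict_unaligned",
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> ExtractionResult:
    """Extract the rescued read sets from one donor's alignment records.

    ``strict_unaligned`` emits reads of class UNMAPPED_PAIR and
    HALF_MAPPED_UNMAPPED_MATE; ``poorly_aligned`` additionally emits
    POORLY_MAPPED reads and their mates (whatever their own class). FASTQ
    files are written per class; a mate anchor is recorded for every
    extracted read whose mate is mapped. Reads appearing with inconsistent
    flags across records raise an error naming the read.
    """
    if mode not in ("strict_unaligned", "poorly_aligned"):
        raise ValueError(f"unknown extraction mode: {mode}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    class_counts: dict[ReadClass, int] = {c: 0 for c in ReadClass}
    classes: dict[str, ReadClass] = {}
    records: dict[str, pysam.AlignedSegment] = {}
    for rec in _iter_primary(sam_path):
        rid = _read_id(rec)
        cls = classify_read(rec, mapq_threshold)
        if rid in classes:
            raise ValueError(f"read {rid} appears in multiple primary records")
        classes[rid] = cls
        class_counts[cls] += 1
        records[rid] = rec

    extract: set[str] = set()
    for rid, cls in classes.items():
        if cls in (ReadClass.UNMAPPED_PAIR, ReadClass.HALF_MAPPED_UNMAPPED_MATE):
            extract.add(rid)
        elif mode == "poorly_aligned" and cls is ReadClass.POORLY_MAPPED:
            extract.add(rid)
            base, mate = rid.rsplit("/", 1)
            extract.add(f"{base}/{2 if mate == '1' else 1}")

    # consistency: a mate flagged mapped must exist as a mapped record
    anchors: list[MateAnchor] = []
    per_class: dict[str, list[str]] = {}
    for rid in sorted(extract):
        rec = records.get(rid)
        if rec is None:
            raise ValueError(f"read {rid} extracted via its mate but absent")
        cls = classes[rid]
        base, mate = rid.rsplit("/", 1)
        mate_rid = f"{base}/{2 if mate == '1' else 1}"
        mate_rec = records.get(mate_rid)
        if rec.is_unmapped and not rec.mate_is_unmapped:
            if mate_rec is None or mate_rec.is_unmapped:
                raise ValueError(
                    f"inconsistent flags for read {base}: mate marked mapped "
                    "but no mapped mate record found"
                )
        if mate_rec is not None and not mate_rec.is_unmapped:
            anchors.append(
                MateAnchor(
                    read_id=rid,
                    donor_id=donor_id,
                    mate_chrom=mate_rec.reference_name,
                    mate_pos=mate_rec.reference_start,
                    mate_strand="-" if mate_rec.is_reverse else "+",
                    mate_mapq=mate_rec.mapping_quality,
                )
            )
        per_class.setdefault(cls.value, []).append(rid)

    fastq_paths: dict[str, Path] = {}
    for cls_name, rids in per_class.items():
        path = outdir / f"{donor_id}.{cls_name}.fastq"
        with open(path, "w") as fh:
            for rid in rids:
                rec = records[rid]
                seq = rec.get_forward_sequence() or ""
                qual = pysam.qualities_to_qualitystring(rec.query_qualities) or ""
                if rec.is_reverse:
                    qual = qual[::-1]
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        fastq_paths[cls_name] = path

    logger.info(
        "%s: extracted %d/%d reads (%s mode); class counts %s",
        donor_id, len(extract), len(classes), mode,
        {c.value: n for c, n in class_counts.items()},
    )
    return ExtractionResult(
        class_counts=class_counts,
        n_extracted=len(extract),
        anchors=anchors,
        fastq_paths=fastq_paths,
    )


def write_anchor_table(anchors: Iterable[MateAnchor], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("read_id\tdonor_id\tmate_chrom\tmate_pos\tmate_strand\tmate_mapq\n")
        for a in anchors:
            fh.write(f"{a.read_id}\t{a.donor_id}\t{a.mate_chrom}\t{a.mate_pos}"
                     f"\t{a.mate_strand}\t{a.mate_mapq}\n")
            n += 1
    return n


def read_anchor_table(path: str | Path) -> list[MateAnchor]:
    anchors = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, donor, chrom, pos, strand, mapq = line.rstrip("\n").split("\t")
            anchors.append(MateAnchor(rid, donor, chrom, int(pos), strand, int(mapq)))
    return anchors
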