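"""Placing contigs on the reference: direct alignment and mate anchoring.

Direct placement keeps, per contig, the longest reference alignment with a
block of at least 500 bp. Mate-pair placement uses the mapped mates of the
reads assembled into a contig: the chromosome with the most anchors wins, the
placement point is the median anchor position, and at least ``min_anchors``
anchors must agree within twice the placement window. When both methods place
a contig, a concordant pair (same chromosome, midpoints within the agreement
window) is reported as method "both" with the alignment interval; a
discordant pair keeps the alignment placement and raises a conflict flag —
direct sequence evidence outranks indirect pairing evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from hiddenvar.pafio import AlignmentRecord
from hiddenvar.read_extraction import MateAnchor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Placement:
    contig_id: str
    chrom: str
    start: int            # 0-based half-open
    end: int
    method: str           # 'alignment' | 'mate_pair' | 'both'
    support: int          # block length (alignment) or anchor count (mate_pair)
    conflict_flag: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty placement interval for {self.contig_id}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def place_by_alignment(
    alignments: Iterable[AlignmentRecord], min_block: int = 500
) -> list[Placement]:
    """Longest qualifying alignment (block >= min_block, boundary accepted)
    defines each contig's placement interval [tstart, tend)."""
    best: dict[str, AlignmentRecord] = {}
    for rec in alignments:
        if rec.block_len < min_block:
            continue
        cur = best.get(rec.query_id)
        # ties broken toward smaller target start, then target name
        if cur is None or (
            (-rec.block_len, rec.tstart, rec.target_id)
            < (-cur.block_len, cur.tstart, cur.target_id)
        ):
            best[rec.query_id] = rec
        else:
            # additional qualifying loci are logged, not reported
            logger.debug("secondary qualifying alignment for %s", rec.query_id)
    return [
        Placement(cid, rec.target_id, rec.tstart, rec.tend, "alignment",
                  rec.block_len)
        for cid, rec in sorted(best.items())
    ]


def place_by_mate(
    read_to_contig: dict[str, str],
    anchors: Iterable[MateAnchor],
    contig_lengths: dict[str, int],
    min_anchors: int = 2,
    window: int = 1000,
) -> tuple[list[Placement], list[str]]:
    """Anchor contigs via the mapped mates of their assembled reads.

    Returns (placements, conflicts) where conflicts lists contigs whose
    anchor chromosomes tied. The placement point is the median anchor
    position on the winning chromosome; the interval is
    [point - window, point + window + contig_length) clamped at zero.
    """
    per_contig: dict[str, dict[str, list[int]]] = {}
    for anchor in anchors:
        contig = read_to_contig.get(anchor.read_id)
        if contig is None:
            continue
        if contig not in contig_lengths:
            logger.warning("anchor references unknown contig %s", contig)
            continue
        per_contig.setdefault(contig, {}).setdefault(anchor.mate_chrom, []).append(
            anchor.mate_pos
        )

    placements: list[Placement] = []
    conflicts: list[str] = []
    for contig in sorted(per_contig):
        by_chrom = per_contig[contig]
        best_n = max(len(v) for v in by_chrom.values())
        winners = [c for c, v in by_chrom.items() if len(v) == best_n]
        if len(winners) > 1:
            conflicts.append(contig)
            continue
        chrom = winners[0]
        positions = sorted(by_chrom[chrom])
        point = positions[(len(positions) - 1) // 2]  # lower median
        close = [p for p in positions if abs(p - point) <= 2 * window]
        if len(close) < min_anchors:
            continue
        start = max(0, point - window)
        end = point + window + contig_lengths[contig]
        placements.append(Placement(contig, chrom, start, end, "mate_pair",
                                    len(close)))
    return placements, conflicts


def merge_placements(
    alignment_placements: Iterable[Placement],
    mate_placements: Iterable[Placement],
    agree_window: int = 100_000,
) -> list[Placement]:
    """Merge the two placement routes; one merged placement per contig."""
    by_aln = {p.contig_id: p for p in alignment_placements}
    by_mate = {p.contig_id: p for p in mate_placements}
    merged = []
    for cid in sorted(set(by_aln) | set(by_mate)):
        a, m = by_aln.get(cid), by_mate.get(cid)
        if a is None:
            merged.append(m)
        elif m is None:
            merged.append(a)
        elif a.chrom == m.chrom and abs(a.midpoint - m.midpoint) <= agree_window:
            merged.append(Placement(cid, a.chrom, a.start, a.end, "both",
                                    a.support))
        else:
            merged.append(Placement(cid, a.chrom, a.start, a.end, "alignment",
                                    a.support, conflict_flag=True))
    return merged


def write_placement_bed(placements: Iterable[Placement], path: str | Path) -> int:
    """BED: chrom, start, end, contig_id, support, method[, conflict]."""
    n = 0
    with open(path, "w") as fh:
        for p in sorted(placements, key=lambda p: (p.chrom, p.start, p.contig_id)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.contig_id}"
                     f"\t{p.support}\t{p.method}\t{int(p.conflict_flag)}\n")
            n += 1
    return n


def read_placement_bed(path: str | Path) -> list[Placement]:
    placements = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            placements.append(Placement(
                contig_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                method=f[5], support=int(f[4]),
                conflict_flag=bool(int(f[6])) if len(f) > 6 else False,
            ))
    return placements
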