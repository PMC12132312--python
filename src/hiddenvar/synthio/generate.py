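"""Reference generation and planting of the donor population."""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hiddenvar.synthio.model import (
    ContaminantTruth,
    InsertionTruth,
    SimConfig,
    TruthManifest,
)

_CONTAMINANT_LABELS = (
    "Escherichia coli str. K-12",
    "Human herpesvirus 4 (Epstein-Barr virus)",
    "Staphylococcus aureus",
    "Pseudomonas aeruginosa",
    "Cutibacterium acnes",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply independent point substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def generate_reference(cfg: SimConfig) -> dict[str, str]:
    """Random uniform-base reference: ``n_chromosomes`` of ``chrom_length`` bp."""
    rng = np.random.default_rng([cfg.seed, 11])
    return {name: _random_seq(rng, cfg.chrom_length) for name in cfg.chrom_names}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class Segment:
    """One piece of a donor chromosome, in donor coordinates."""

    donor_start: int
    donor_end: int
    kind: str                  # 'ref' or 'ins'
    ref_start: int             # for 'ref': offset into the reference chromosome
    insertion_id: str | None   # for 'ins'
    seq: str | None            # for 'ins': this donor's (mutated) copy

    @property
    def length(self) -> int:
        return self.donor_end - self.donor_start


class DonorGenome:
    """A donor's diploid-collapsed genome as reference segments plus insertions.

    Sequences are materialised lazily; coordinate maps between donor and
    reference space are exact because reads carry no indel errors.
    """

    def __init__(self, donor_id: str, segments: dict[str, list[Segment]]):
        self.donor_id = donor_id
        self.segments = segments
        self._starts = {
            chrom: [s.donor_start for s in segs] for chrom, segs in segments.items()
        }

    def chrom_length(self, chrom: str) -> int:
        return self.segments[chrom][-1].donor_end

    @property
    def total_length(self) -> int:
        return sum(self.chrom_length(c) for c in self.segments)

    def sequence(self, chrom: str, reference: dict[str, str]) -> str:
        parts = []
        ref = reference[chrom]
        for seg in self.segments[chrom]:
            if seg.kind == "ref":
                parts.append(ref[seg.ref_start : seg.ref_start + seg.length])
            else:
                parts.append(seg.seq)
        return "".join(parts)

    def segment_at(self, chrom: str, donor_pos: int) -> Segment:
        i = bisect_right(self._starts[chrom], donor_pos) - 1
        return self.segments[chrom][i]

    def overlapping_segments(self, chrom: str, start: int, end: int) -> list[Segment]:
        segs = self.segments[chrom]
        i = bisect_right(self._starts[chrom], start) - 1
        out = []
        while i < len(segs) and segs[i].donor_start < end:
            out.append(segs[i])
            i += 1
        return out

    def donor_to_ref(self, chrom: str, donor_pos: int) -> int | None:
        """Reference coordinate of a donor position, or None inside an insertion."""
        seg = self.segment_at(chrom, donor_pos)
        if seg.kind != "ref":
            return None
        return seg.ref_start + (donor_pos - seg.donor_start)

    def carried_copies(self) -> dict[str, str]:
        """insertion_id -> this donor's copy sequence."""
        out = {}
        for segs in self.segments.values():
            for seg in segs:
                if seg.kind == "ins":
                    out[seg.insertion_id] = seg.seq
        return out


def _draw_insertion_loci(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Uniform loci excluding 2*insert_mean from chromosome ends, kept at
    least ``min_locus_separation`` apart so planted signals do not cross-talk."""
    # catalog sites are planted up to ~2 kb from a point, so keep headroom
    margin = max(2 * cfg.insert_mean, 2000)
    loci: list[tuple[str, int]] = []
    attempts = 0
    while len(loci) < cfg.n_insertions:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(
                "cannot place insertions: chromosome too short for the "
                "requested count and separation"
            )
        chrom = cfg.chrom_names[rng.integers(0, cfg.n_chromosomes)]
        point = int(rng.integers(margin, cfg.chrom_length - margin))
        if all(
            c != chrom or abs(p - point) >= cfg.min_locus_separation
            for c, p in loci
        ):
            loci.append((chrom, point))
    return loci


def plant_population(
    cfg: SimConfig, reference: dict[str, str]
) -> tuple[list[DonorGenome], TruthManifest]:
    """Draw insertion loci/sequences/carriers and build every donor genome.

    Each donor carries insertion *m* independently with probability ``f_m``;
    the first ``n_linked_pairs`` insertion pairs share identical carrier sets.
    The trailing ``unplaceable_fraction`` of insertions (plus the second
    member of each linked pair) are flagged unplaceable: their contigs will be
    emitted without reference flanks.
    """
    rng = np.random.default_rng([cfg.seed, 12])
    loci = _draw_insertion_loci(cfg, rng)

    n = cfg.n_insertions
    lo, hi = cfg.insertion_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    sequences = [_random_seq(rng, int(L)) for L in lengths]

    carrier_masks = []
    for m in range(n):
        f = cfg.frequency_of(m)
        carrier_masks.append(rng.random(cfg.n_donors) < f)
    linked: dict[int, int] = {}
    for k in range(cfg.n_linked_pairs):
        a, b = 2 * k, 2 * k + 1
        carrier_masks[b] = carrier_masks[a].copy()
        linked[a], linked[b] = b, a

    unplaceable = {2 * k + 1 for k in range(cfg.n_linked_pairs)}
    want = round(cfg.unplaceable_fraction * n)
    extra = [m for m in range(n) if m not in unplaceable and m not in linked]
    for m in reversed(extra):
        if len(unplaceable) >= want:
            break
        unplaceable.add(m)

    manifest = TruthManifest()
    for m in range(n):
        chrom, point = loci[m]
        manifest.insertions.append(
            InsertionTruth(
                insertion_id=f"INS{m:03d}",
                chrom=chrom,
                point=point,
                length=int(lengths[m]),
                sequence=sequences[m],
                frequency=cfg.frequency_of(m) if m not in linked
                else cfg.frequency_of(min(m, linked[m])),
                carriers=[
                    cfg.donor_ids[d]
                    for d in range(cfg.n_donors)
                    if carrier_masks[m][d]
                ],
                placeable=m not in unplaceable,
                linked_partner=f"INS{linked[m]:03d}" if m in linked else None,
            )
        )

    for k in range(cfg.n_contaminants):
        mask = rng.random(cfg.n_donors) < 0.3
        if not mask.any():
            mask[int(rng.integers(0, cfg.n_donors))] = True
        manifest.contaminants.append(
            ContaminantTruth(
                contaminant_id=f"CONT{k:02d}",
                sequence=_random_seq(rng, 2000),
                donors=[cfg.donor_ids[d] for d in range(cfg.n_donors) if mask[d]],
                label=_CONTAMINANT_LABELS[k % len(_CONTAMINANT_LABELS)],
            )
        )

    by_chrom: dict[str, list[int]] = {c: [] for c in cfg.chrom_names}
    for m, (chrom, _) in enumerate(loci):
        by_chrom[chrom].append(m)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda m: loci[m][1])

    donors = []
    for d, donor_id in enumerate(cfg.donor_ids):
        segments: dict[str, list[Segment]] = {}
        for chrom in cfg.chrom_names:
            segs: list[Segment] = []
            cursor_ref = 0
            cursor_donor = 0
            for m in by_chrom[chrom]:
                if not carrier_masks[m][d]:
                    continue
                point = loci[m][1]
                if point > cursor_ref:
                    segs.append(Segment(cursor_donor, cursor_donor + point - cursor_ref,
                                        "ref", cursor_ref, None, None))
                    cursor_donor += point - cursor_ref
                    cursor_ref = point
                copy_rng = np.random.default_rng([cfg.seed, 13, d, m])
                copy = _mutate(copy_rng, sequences[m], cfg.mutation_rate)
                segs.append(Segment(cursor_donor, cursor_donor + len(copy),
                                    "ins", -1, f"INS{m:03d}", copy))
                cursor_donor += len(copy)
            tail = cfg.chrom_length - cursor_ref
            segs.append(Segment(cursor_donor, cursor_donor + tail, "ref",
                                cursor_ref, None, None))
            segments[chrom] = segs
        donors.append(DonorGenome(donor_id, segments))

    return donors, manifest
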