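"""Paired-read and alignment-record emission for the synthetic cohort.

Alignment records are constructed from truth rather than produced by an
aligner: read pairs fully inside a planted insertion become unmapped-pair
records, pairs straddling an insertion boundary become half-mapped records
whose mapped mate carries its true reference coordinate, contaminant pairs
are unmapped, and all other pairs are mapped (MAPQ 60, with a configurable
fraction emitted at MAPQ 10 to exercise the poorly-aligned class). Reads are
uniform-random with independent substitution errors and no indels, so donor
and reference coordinates stay in exact correspondence.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from hiddenvar.synthio.generate import DonorGenome
from hiddenvar.synthio.model import SimConfig, TruthManifest

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    arr = bytearray(seq, "ascii")
    bases = b"ACGT"
    for pos in rng.choice(len(seq), size=k, replace=False):
        cur = arr[pos]
        repl = bases[rng.integers(0, 4)]
        while repl == cur:
            repl = bases[rng.integers(0, 4)]
        arr[pos] = repl
    return arr.decode()


def expected_pair_count(cfg: SimConfig, donor_total_length: int) -> int:
    return round(cfg.coverage * donor_total_length / (2 * cfg.read_length))


def _sam_header(cfg: SimConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": cfg.chrom_length} for c in cfg.chrom_names],
        }
    )


def _segment(name, flag, seq, qual, header, chrom=None, pos=-1, mapq=0,
             cigar=None, mchrom=None, mpos=-1, tlen=0):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(qual)
    if chrom is not None:
        a.reference_id = header.get_tid(chrom)
        a.reference_start = pos
    if cigar is not None:
        a.cigarstring = cigar
    a.mapping_quality = mapq
    if mchrom is not None:
        a.next_reference_id = header.get_tid(mchrom)
        a.next_reference_start = mpos
    a.template_length = tlen
    return a


def emit_reads_for_donor(
    cfg: SimConfig,
    reference: dict[str, str],
    donor: DonorGenome,
    manifest: TruthManifest,
    outdir: str | Path,
    donor_index: int,
) -> dict:
    """Write one donor's FASTQ pair, constructed SAM and per-read truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 21, donor_index])
    rl = cfg.read_length
    qual = "I" * rl
    header = _sam_header(cfg)

    chroms = list(donor.segments)
    lengths = np.array([donor.chrom_length(c) for c in chroms], dtype=float)
    donor_seqs = {c: donor.sequence(c, reference) for c in chroms}
    n_pairs = expected_pair_count(cfg, int(lengths.sum()))

    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / lengths.sum())
    isizes = np.clip(
        rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs).round().astype(int),
        2 * rl,
        cfg.insert_mean + 4 * cfg.insert_sd,
    )
    low_mapq = rng.random(n_pairs) < cfg.low_mapq_fraction

    counts = {"mapped": 0, "low_mapq": 0, "unmapped_pair": 0, "half_mapped": 0,
              "contaminant": 0}
    sam_path = outdir / f"{donor.donor_id}.sam"
    fq1_path = outdir / f"{donor.donor_id}_1.fastq"
    fq2_path = outdir / f"{donor.donor_id}_2.fastq"
    truth_path = outdir / f"{donor.donor_id}.reads.tsv"

    with pysam.AlignmentFile(sam_path, "w", header=header) as sam, \
            open(fq1_path, "w") as fq1, open(fq2_path, "w") as fq2, \
            open(truth_path, "w") as truth:
        truth.write("read_id\tmate\tprovenance\tsam_class\n")

        def fastq(fh, name, seq):
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

        def emit_pair(name, chrom, s1, s2, seq1, seq2, prov1, prov2, mapq):
            """seq1/seq2 are sequenced reads (seq2 already reverse-complemented)."""
            fastq(fq1, name, seq1)
            fastq(fq2, name, seq2)
            r1_ref = donor.donor_to_ref(chrom, s1) if prov1 == "ref" else None
            r2_ref = donor.donor_to_ref(chrom, s2) if prov2 == "ref" else None
            if prov1 == "ref" and prov2 == "ref":
                tlen = r2_ref + rl - r1_ref
                sam.write(_segment(name, 99, seq1, qual, header, chrom, r1_ref,
                                   mapq, f"{rl}M", chrom, r2_ref, tlen))
                sam.write(_segment(name, 147, revcomp(seq2), qual, header, chrom,
                                   r2_ref, mapq, f"{rl}M", chrom, r1_ref, -tlen))
                cls = "mapped" if mapq >= 20 else "low_mapq"
                counts[cls] += 1
                truth.write(f"{name}\t1\t{prov1}\t{cls}\n{name}\t2\t{prov2}\t{cls}\n")
            elif prov1 != "ref" and prov2 != "ref":
                sam.write(_segment(name, 77, seq1, qual, header))
                sam.write(_segment(name, 141, seq2, qual, header))
                counts["unmapped_pair"] += 1
                truth.write(f"{name}\t1\t{prov1}\tunmapped\n"
                            f"{name}\t2\t{prov2}\tunmapped\n")
            elif prov1 == "ref":
                # r1 mapped forward, r2 unmapped
                sam.write(_segment(name, 73, seq1, qual, header, chrom, r1_ref,
                                   mapq, f"{rl}M", chrom, r1_ref))
                sam.write(_segment(name, 133, seq2, qual, header, chrom, r1_ref,
                                   0, None, chrom, r1_ref))
                counts["half_mapped"] += 1
                truth.write(f"{name}\t1\t{prov1}\thalf_mapped_mapped\n"
                            f"{name}\t2\t{prov2}\thalf_mapped_unmapped\n")
            else:
                # r2 mapped reverse, r1 unmapped
                sam.write(_segment(name, 101, seq1, qual, header, chrom, r2_ref,
                                   0, None, chrom, r2_ref))
                sam.write(_segment(name, 153, revcomp(seq2), qual, header, chrom,
                                   r2_ref, mapq, f"{rl}M", chrom, r2_ref))
                counts["half_mapped"] += 1
                truth.write(f"{name}\t1\t{prov1}\thalf_mapped_unmapped\n"
                            f"{name}\t2\t{prov2}\thalf_mapped_mapped\n")

        serial = 0
        for i in range(n_pairs):
            chrom = chroms[chrom_idx[i]]
            L = donor.chrom_length(chrom)
            isize = int(min(isizes[i], L))
            s1 = int(rng.integers(0, L - isize + 1))
            s2 = s1 + isize - rl
            dseq = donor_seqs[chrom]
            seq1 = _apply_errors(rng, dseq[s1 : s1 + rl], cfg.error_rate)
            seq2 = _apply_errors(rng, revcomp(dseq[s2 : s2 + rl]), cfg.error_rate)

            def prov(s):
                segs = donor.overlapping_segments(chrom, s, s + rl)
                if len(segs) == 1 and segs[0].kind == "ref":
                    return "ref"
                ins = next(sg for sg in segs if sg.kind == "ins")
                return ins.insertion_id

            p1, p2 = prov(s1), prov(s2)
            mapq = 10 if (low_mapq[i] and p1 == "ref" and p2 == "ref") else 60
            name = f"{donor.donor_id}.p{serial:06d}"
            serial += 1
            emit_pair(name, chrom, s1, s2, seq1, seq2, p1, p2, mapq)

        for cont in manifest.contaminants:
            if donor.donor_id not in cont.donors:
                continue
            cl = len(cont.sequence)
            n_c = max(5, round(cfg.coverage * cl / (2 * rl)))
            for _ in range(n_c):
                isize = int(np.clip(
                    round(rng.normal(cfg.insert_mean, cfg.insert_sd)),
                    2 * rl, min(cfg.insert_mean + 4 * cfg.insert_sd, cl),
                ))
                s1 = int(rng.integers(0, cl - isize + 1))
                s2 = s1 + isize - rl
                seq1 = _apply_errors(rng, cont.sequence[s1 : s1 + rl], cfg.error_rate)
                seq2 = _apply_errors(
                    rng, revcomp(cont.sequence[s2 : s2 + rl]), cfg.error_rate
                )
                name = f"{donor.donor_id}.p{serial:06d}"
                serial += 1
                fastq(fq1, name, seq1)
                fastq(fq2, name, seq2)
                sam.write(_segment(name, 77, seq1, qual, header))
                sam.write(_segment(name, 141, seq2, qual, header))
                counts["contaminant"] += 1
                truth.write(f"{name}\t1\tcon\tunmapped\n{name}\t2\tcon\tunmapped\n")

    # read -> contig assignment (what the assembler would report): extracted
    # insertion-derived reads belong to that donor's contig for the insertion
    assign_path = outdir / f"{donor.donor_id}.assign.tsv"
    with open(truth_path) as fh, open(assign_path, "w") as out:
        out.write("read_id\tcontig_id\n")
        next(fh)
        for line in fh:
            read_id, mate, prov2, sam_class = line.rstrip("\n").split("\t")
            if sam_class in ("unmapped", "half_mapped_unmapped") and \
                    prov2.startswith("INS"):
                out.write(f"{read_id}/{mate}\t{donor.donor_id}.{prov2}\n")

    counts["n_pairs_genome"] = n_pairs
    return counts


def emit_reads_and_alignments(
    cfg: SimConfig,
    reference: dict[str, str],
    donors: list[DonorGenome],
    manifest: TruthManifest,
    outdir: str | Path,
) -> dict[str, dict]:
    """Emit FASTQ pair + constructed SAM + read truth table for every donor."""
    return {
        donor.donor_id: emit_reads_for_donor(
            cfg, reference, donor, manifest, outdir, i
        )
        for i, donor in enumerate(donors)
    }


def spot_check_sam(
    cfg: SimConfig,
    reference: dict[str, str],
    donor: DonorGenome,
    sam_path: str | Path,
    n_records: int = 1000,
    max_mismatch_frac: float = 0.05,
) -> int:
    """Verify that mapped records re-derive from the donor genome.

    Checks coordinates against the donor->reference map and that the stored
    sequence matches the reference-projected donor sequence up to the
    substitution-error budget. Returns the number of records checked; raises
    AssertionError on an inconsistency.
    """
    checked = 0
    donor_seqs = {}
    with pysam.AlignmentFile(str(sam_path)) as fh:
        for rec in fh:
            if checked >= n_records:
                break
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if chrom not in donor_seqs:
                donor_seqs[chrom] = donor.sequence(chrom, reference)
            # recover the donor coordinate of this reference position
            seg = None
            for s in donor.segments[chrom]:
                if s.kind == "ref" and s.ref_start <= rec.reference_start < s.ref_start + s.length:
                    seg = s
                    break
            assert seg is not None, f"{rec.query_name}: mapped inside an insertion"
            donor_pos = seg.donor_start + (rec.reference_start - seg.ref_start)
            expect = donor_seqs[chrom][donor_pos : donor_pos + cfg.read_length]
            got = rec.query_sequence
            mism = sum(a != b for a, b in zip(expect, got))
            assert mism / cfg.read_length <= max_mismatch_frac, (
                f"{rec.query_name}: {mism} mismatches to donor genome"
            )
            checked += 1
    return checked
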