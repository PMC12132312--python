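"""Auxiliary truth-derived inputs: rescue alignments, RNA-seq alignments and
an SV-caller-style insertion VCF.

These emulate the downstream evidence sources the validation stage consumes:
re-alignment of previously extracted reads to a personalised long-read
assembly, RNA-seq reads aligned to the contig set, and insertion calls from a
conventional short-read SV caller.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pysam

from hiddenvar.synthio.contigs import EmittedContig
from hiddenvar.synthio.generate import DonorGenome
from hiddenvar.synthio.model import SimConfig, TruthManifest


def emit_rescue_alignments(
    cfg: SimConfig,
    donors: list[DonorGenome],
    reads_dir: str | Path,
    outpath: str | Path,
) -> dict:
    """SAM of previously extracted (strict-set) reads vs the long-read
    assembly surrogate: insertion-derived reads align at MAPQ 60, contaminant
    reads stay unmapped."""
    reads_dir = Path(reads_dir)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": f"{d.donor_id}.{chrom}", "LN": d.chrom_length(chrom)}
            for d in donors for chrom in d.segments
        ],
    })
    n_mapped = n_unmapped = 0
    with pysam.AlignmentFile(outpath, "w", header=header) as sam:
        for donor in donors:
            chrom0 = f"{donor.donor_id}.{next(iter(donor.segments))}"
            with open(reads_dir / f"{donor.donor_id}.reads.tsv") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    if row["sam_class"] not in ("unmapped", "half_mapped_unmapped"):
                        continue
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{row['read_id']}/{row['mate']}"
                    if row["provenance"] == "con":
                        a.flag = 4
                        n_unmapped += 1
                    else:
                        a.flag = 0
                        a.reference_id = header.get_tid(chrom0)
                        a.reference_start = 0
                        a.cigarstring = f"{cfg.read_length}M"
                        a.mapping_quality = 60
                        n_mapped += 1
                    sam.write(a)
    return {"mapped": n_mapped, "unmapped": n_unmapped}


def emit_rna_alignments(
    cfg: SimConfig,
    contigs: list[EmittedContig],
    manifest: TruthManifest,
    outpath: str | Path,
) -> dict[str, int]:
    """RNA-seq-style SAM against the contig set with planted per-contig
    primary-alignment counts straddling the >100 and >1000 reporting
    thresholds; a sprinkling of secondary records must be ignored."""
    expressed = [c for c in contigs if not c.is_contaminant][:4]
    planted = (1200, 150, 100, 40)
    counts = {c.contig_id: n for c, n in zip(expressed, planted)}
    manifest.rna_counts = dict(counts)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.contig_id, "LN": len(c.sequence)} for c in contigs
               if not c.is_contaminant],
    })
    serial = 0
    with pysam.AlignmentFile(outpath, "w", header=header) as sam:
        for contig in expressed:
            n = counts[contig.contig_id]
            for i in range(n):
                a = pysam.AlignedSegment(header)
                a.query_name = f"rna{serial:06d}"
                serial += 1
                a.flag = 0
                a.reference_id = header.get_tid(contig.contig_id)
                a.reference_start = i % max(1, len(contig.sequence) - 100)
                a.cigarstring = "100M"
                a.mapping_quality = 60
                sam.write(a)
                if i % 50 == 0:  # secondary alignment: must not be counted
                    b = pysam.AlignedSegment(header)
                    b.query_name = a.query_name
                    b.flag = 256
                    b.reference_id = a.reference_id
                    b.reference_start = a.reference_start
                    b.cigarstring = "100M"
                    b.mapping_quality = 0
                    sam.write(b)
    return counts


def emit_insertion_vcf(
    cfg: SimConfig, manifest: TruthManifest, outpath: str | Path
) -> list[dict]:
    """Insertion calls at or near planted insertion points, in the style of a
    short-read SV caller: most INS calls at the exact point, every third
    offset by 900 bp (detectable only at a 1 kb window), one breakend record,
    and one record with no SVTYPE (to be skipped with a warning)."""
    calls = []
    with open(outpath, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in cfg.chrom_names:
            fh.write(f"##contig=<ID={chrom},length={cfg.chrom_length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        placeable = [i for i in manifest.insertions if i.placeable]
        for k, ins in enumerate(placeable):
            offset = 900 if k % 3 == 2 else 0
            pos0 = ins.point + offset
            svtype = "BND" if k == len(placeable) - 1 and len(placeable) > 2 else "INS"
            call = {
                "call_id": f"SV{k:03d}", "chrom": ins.chrom, "pos": pos0,
                "svtype": svtype, "svlen": ins.length, "offset": offset,
                "near_insertion": ins.insertion_id,
            }
            calls.append(call)
            if svtype == "BND":
                alt = f"N[{ins.chrom}:{pos0 + 1}["
                fh.write(f"{ins.chrom}\t{pos0 + 1}\tSV{k:03d}\tN\t{alt}\t.\tPASS"
                         f"\tSVTYPE=BND\n")
            else:
                fh.write(f"{ins.chrom}\t{pos0 + 1}\tSV{k:03d}\tN\t<INS>\t.\tPASS"
                         f"\tSVTYPE=INS;SVLEN={ins.length}\n")
        # malformed row: no SVTYPE
        chrom = cfg.chrom_names[0]
        fh.write(f"{chrom}\t100\tNOSVTYPE\tN\t<DEL>\t.\tPASS\t.\n")
    manifest.vcf_calls = calls
    return calls
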