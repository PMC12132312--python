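"""Contig sets and alignment catalogs derived from planted truth.

Stands in for an assembler plus aligner: per-donor contigs are the carried
insertion copies with optional reference flanks, and PAF catalogs (all-vs-all,
contig-vs-reference, contig-vs-long-read-assembly) are computed by exact
comparison of the known sequences, so coordinates and residue-match counts
are correct by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from hiddenvar.pafio import AlignmentRecord, write_paf
from hiddenvar.synthio.generate import DonorGenome, write_fasta
from hiddenvar.synthio.model import SimConfig, TruthManifest


@dataclass
class EmittedContig:
    contig_id: str
    donor_id: str
    sequence: str
    source: str            # insertion id or contaminant id
    is_contaminant: bool
    flank: int             # reference flank length on each side (0 if none)


def build_contigs(
    cfg: SimConfig,
    reference: dict[str, str],
    donors: list[DonorGenome],
    manifest: TruthManifest,
) -> list[EmittedContig]:
    """One contig per carried insertion copy, plus planted contaminant contigs.

    Placeable insertions get ``flank_len`` of true reference sequence on both
    sides; unplaceable ones get none. Each contaminant contributes a short
    (< 1 kb) contig to every donor it was injected into, and the first
    contaminant additionally contributes one >= 1 kb contig (removable only
    via its planted classifier hit).
    """
    ins_by_id = {i.insertion_id: i for i in manifest.insertions}
    contigs: list[EmittedContig] = []
    for donor in donors:
        for ins_id, copy in sorted(donor.carried_copies().items()):
            truth = ins_by_id[ins_id]
            flank = cfg.flank_len if truth.placeable else 0
            ref = reference[truth.chrom]
            left = ref[truth.point - flank : truth.point]
            right = ref[truth.point : truth.point + flank]
            contigs.append(
                EmittedContig(
                    contig_id=f"{donor.donor_id}.{ins_id}",
                    donor_id=donor.donor_id,
                    sequence=left + copy + right,
                    source=ins_id,
                    is_contaminant=False,
                    flank=flank,
                )
            )
    for k, cont in enumerate(manifest.contaminants):
        for donor_id in cont.donors:
            contigs.append(
                EmittedContig(
                    contig_id=f"{donor_id}.{cont.contaminant_id}.short",
                    donor_id=donor_id,
                    sequence=cont.sequence[:600],
                    source=cont.contaminant_id,
                    is_contaminant=True,
                    flank=0,
                )
            )
        if k == 0 and cont.donors:
            contigs.append(
                EmittedContig(
                    contig_id=f"{cont.donors[0]}.{cont.contaminant_id}.long",
                    donor_id=cont.donors[0],
                    sequence=cont.sequence[:1200],
                    source=cont.contaminant_id,
                    is_contaminant=True,
                    flank=0,
                )
            )
    return contigs


def _group_pairs(contigs: list[EmittedContig]) -> list[AlignmentRecord]:
    """All-vs-all records: full-length comparison within each source group."""
    groups: dict[str, list[EmittedContig]] = {}
    for c in contigs:
        groups.setdefault(c.source, []).append(c)
    records = []
    for source in sorted(groups):
        group = sorted(groups[source], key=lambda c: c.contig_id)
        arrays = [np.frombuffer(c.sequence.encode(), dtype=np.uint8) for c in group]
        for (i, a), (j, b) in combinations(enumerate(group), 2):
            L = min(len(a.sequence), len(b.sequence))
            mism = int(np.count_nonzero(arrays[i][:L] != arrays[j][:L]))
            records.append(
                AlignmentRecord(
                    query_id=a.contig_id, query_len=len(a.sequence),
                    qstart=0, qend=L, strand="+",
                    target_id=b.contig_id, target_len=len(b.sequence),
                    tstart=0, tend=L,
                    n_match=L - mism, block_len=L, mapq=60,
                )
            )
    return records


def _reference_records(
    cfg: SimConfig, contigs: list[EmittedContig], manifest: TruthManifest
) -> list[AlignmentRecord]:
    """Flank alignments against the reference: one record per planted flank."""
    ins_by_id = {i.insertion_id: i for i in manifest.insertions}
    records = []
    for c in contigs:
        if c.is_contaminant or c.flank == 0:
            continue
        truth = ins_by_id[c.source]
        clen = len(c.sequence)
        copy_len = clen - 2 * c.flank
        records.append(AlignmentRecord(
            query_id=c.contig_id, query_len=clen, qstart=0, qend=c.flank,
            strand="+", target_id=truth.chrom, target_len=cfg.chrom_length,
            tstart=truth.point - c.flank, tend=truth.point,
            n_match=c.flank, block_len=c.flank, mapq=60,
        ))
        records.append(AlignmentRecord(
            query_id=c.contig_id, query_len=clen,
            qstart=c.flank + copy_len, qend=clen, strand="+",
            target_id=truth.chrom, target_len=cfg.chrom_length,
            tstart=truth.point, tend=truth.point + c.flank,
            n_match=c.flank, block_len=c.flank, mapq=60,
        ))
    return records


def _assembly_records(
    contigs: list[EmittedContig], donors: list[DonorGenome]
) -> list[AlignmentRecord]:
    """Full-length alignments of each donor's insertion contigs to that
    donor's genome (the long-read-assembly surrogate). Contaminant contigs
    have no alignment."""
    by_donor = {d.donor_id: d for d in donors}
    records = []
    for c in contigs:
        if c.is_contaminant:
            continue
        donor = by_donor[c.donor_id]
        for chrom, segs in donor.segments.items():
            for seg in segs:
                if seg.kind == "ins" and seg.insertion_id == c.source:
                    start = seg.donor_start - c.flank
                    clen = len(c.sequence)
                    records.append(AlignmentRecord(
                        query_id=c.contig_id, query_len=clen, qstart=0,
                        qend=clen, strand="+",
                        target_id=f"{donor.donor_id}.{chrom}",
                        target_len=donor.chrom_length(chrom),
                        tstart=start, tend=start + clen,
                        n_match=clen, block_len=clen, mapq=60,
                    ))
    return records


def _classifier_reports(
    contigs: list[EmittedContig], manifest: TruthManifest, outdir: Path
) -> None:
    """BLAST outfmt-6-style and centrifuge-style label reports plus the
    label->taxon map. Short contaminant contigs get centrifuge labels, the
    long one only a BLAST hit (each removal path exercised); a couple of
    insertion contigs get innocuous human-labelled hits."""
    labels = {c.contaminant_id: c.label for c in manifest.contaminants}
    blast_rows, cent_rows = [], []
    human_tagged = 0
    for c in contigs:
        if c.is_contaminant and c.contig_id.endswith(".long"):
            blast_rows.append(
                (c.contig_id, "NC_000913.3", 98.5, 300, 1e-50, 550.0,
                 labels[c.source])
            )
        elif c.is_contaminant:
            cent_rows.append((c.contig_id, labels[c.source]))
        elif human_tagged < 2:
            blast_rows.append(
                (c.contig_id, "NT_187361.1", 99.0, 500, 1e-80, 900.0,
                 "Homo sapiens chromosome scaffold")
            )
            cent_rows.append((c.contig_id, "Homo sapiens"))
            human_tagged += 1
    with open(outdir / "blast.tsv", "w") as fh:
        for row in blast_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(outdir / "centrifuge.tsv", "w") as fh:
        for row in cent_rows:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "taxon_map.tsv", "w") as fh:
        fh.write("Homo sapiens chromosome scaffold\thuman\n")
        fh.write("Homo sapiens\thuman\n")
        for label in sorted(set(labels.values())):
            fh.write(f"{label}\tnon_human\n")


def emit_contigs_and_alignment_catalogs(
    cfg: SimConfig,
    reference: dict[str, str],
    donors: list[DonorGenome],
    manifest: TruthManifest,
    outdir: str | Path,
) -> dict:
    """Write per-donor contig FASTAs, the three PAF catalogs and the
    classifier reports; return the emitted contig list and paths."""
    outdir = Path(outdir)
    (outdir / "contigs").mkdir(parents=True, exist_ok=True)
    (outdir / "paf").mkdir(exist_ok=True)
    (outdir / "classifier").mkdir(exist_ok=True)

    contigs = build_contigs(cfg, reference, donors, manifest)
    by_donor: dict[str, dict[str, str]] = {d.donor_id: {} for d in donors}
    for c in contigs:
        by_donor[c.donor_id][c.contig_id] = c.sequence
    for donor_id, seqs in by_donor.items():
        write_fasta(seqs, outdir / "contigs" / f"{donor_id}.fa")
    write_fasta(
        {c.contig_id: c.sequence for c in contigs}, outdir / "all_contigs.fa"
    )

    write_paf(_group_pairs(contigs), outdir / "paf" / "all_vs_all.paf")
    write_paf(_reference_records(cfg, contigs, manifest),
              outdir / "paf" / "contigs_vs_ref.paf")
    write_paf(_assembly_records(contigs, donors),
              outdir / "paf" / "contigs_vs_assembly.paf")
    _classifier_reports(contigs, manifest, outdir / "classifier")

    return {
        "contigs": contigs,
        "all_contigs_fasta": outdir / "all_contigs.fa",
        "all_vs_all_paf": outdir / "paf" / "all_vs_all.paf",
        "contigs_vs_ref_paf": outdir / "paf" / "contigs_vs_ref.paf",
        "contigs_vs_assembly_paf": outdir / "paf" / "contigs_vs_assembly.paf",
        "blast_report": outdir / "classifier" / "blast.tsv",
        "centrifuge_report": outdir / "classifier" / "centrifuge.tsv",
        "taxon_map": outdir / "classifier" / "taxon_map.tsv",
    }
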