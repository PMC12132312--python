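"""Planted annotation, GWAS-site and summary-statistic catalogs.

Features are planted overlapping chosen insertion points so that placed
contigs (whose placement interval is the left reference flank,
``[point - flank, point)``) intersect them; GWAS sites are planted at designed
distances 0/100/1000 bp from that interval; summary-statistic loci are planted
in clusters within and beyond the 50 kb merge window with controlled
significance.
"""

from __future__ import annotations

from pathlib import Path

from hiddenvar.synthio.model import (
    FeatureTruth,
    GwasSiteTruth,
    SimConfig,
    SumstatLocusTruth,
    TruthManifest,
)

GWAS_OFFSETS = (0, 100, 1000)

# cluster member offsets (bp) from the anchor point; all pairwise within 50 kb
_CLUSTER_OFFSETS = (0, 20_000, 40_000)
_CLUSTER_SCORES = (9.0, 7.5, 8.2)
_ISOLATED_OFFSET = 95_000          # > 50 kb from every cluster member
_ISOLATED_SCORE = 8.0
_WEAK_OFFSET = 10_000
_WEAK_SCORE = 3.0                  # below any sensible significance threshold


def emit_feature_catalogs(
    cfg: SimConfig, manifest: TruthManifest, outdir: str | Path
) -> dict:
    """Write GFF3 annotation, GWAS-site BED and per-trait summary TSV; record
    every planted entry in the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    placeable = [i for i in manifest.insertions if i.placeable]

    gff_path = outdir / "annotation.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        n_genes = max(1, len(placeable) // 2)
        for g, ins in enumerate(placeable[:n_genes]):
            name = f"GENE{g:03d}"
            p = ins.point
            spans = {
                "gene": (p - 800, p + 800),
                "transcript": (p - 800, p + 800),
                "exon": (p - 400, p + 400),
                "CDS": (p - 200, p + 200),
            }
            parent = {"gene": None, "transcript": name,
                      "exon": f"{name}-T1", "CDS": f"{name}-T1"}
            ident = {"gene": name, "transcript": f"{name}-T1",
                     "exon": f"{name}-E1", "CDS": f"{name}-C1"}
            for ftype, (s, e) in spans.items():
                s = max(0, s)
                e = min(cfg.chrom_length, e)
                attrs = f"ID={ident[ftype]};Name={name}"
                if parent[ftype]:
                    attrs += f";Parent={parent[ftype]}"
                # GFF3 is 1-based closed
                fh.write(
                    f"{ins.chrom}\tsynthio\t{ftype}\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
                )
                manifest.features.append(
                    FeatureTruth(ftype, ins.chrom, s, e, name, ins.insertion_id)
                )

    bed_path = outdir / "gwas.bed"
    with open(bed_path, "w") as fh:
        for g, ins in enumerate(placeable):
            offset = GWAS_OFFSETS[g % len(GWAS_OFFSETS)]
            # the placement interval is [point - flank, point); a site at
            # point - 1 + offset sits `offset` bp right of its last base
            pos = ins.point - 1 + offset
            site_id = f"GWAS{g:03d}"
            fh.write(f"{ins.chrom}\t{pos}\t{pos + 1}\t{site_id}\n")
            manifest.gwas_sites.append(
                GwasSiteTruth(site_id, ins.chrom, pos, offset, ins.insertion_id)
            )

    tsv_path = outdir / "sumstats.tsv"
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tpos\ttrait\tneglog10p\n")
        for t, ins in enumerate(placeable[:2]):
            trait = f"trait_{chr(ord('A') + t)}"
            p = ins.point
            direction = 1 if p < cfg.chrom_length // 2 else -1
            rows = []
            for off, score in zip(_CLUSTER_OFFSETS, _CLUSTER_SCORES):
                rows.append((p + direction * off, score, f"{trait}.cluster"))
            rows.append((p + direction * _ISOLATED_OFFSET, _ISOLATED_SCORE,
                         f"{trait}.isolated"))
            rows.append((p + direction * _WEAK_OFFSET, _WEAK_SCORE,
                         f"{trait}.weak"))
            for pos, score, cluster in rows:
                pos = min(max(pos, 0), cfg.chrom_length - 1)
                fh.write(f"{ins.chrom}\t{pos}\t{trait}\t{score}\n")
                manifest.sumstat_loci.append(
                    SumstatLocusTruth(trait, ins.chrom, pos, score, cluster,
                                      ins.insertion_id)
                )

    return {"annotation_gff3": gff_path, "gwas_bed": bed_path,
            "sumstats_tsv": tsv_path}
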