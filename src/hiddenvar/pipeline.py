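"""End-to-end orchestration of the rescued-read analysis.

Stages run in order extract -> qc -> collapse -> place -> ld -> annotate ->
peaks -> validate, each writing its outputs under the run directory and its
summary numbers into a machine-readable JSON report. Optional inputs
(annotation, summary statistics, long-read/RNA/VCF evidence) that are absent
cause their stage to be skipped with an explicit report flag. Re-running with
identical inputs and config reproduces an identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from hiddenvar import annotate as ann
from hiddenvar import collapse as clp
from hiddenvar import contigqc as qc
from hiddenvar import ldgrid
from hiddenvar import placement as plc
from hiddenvar import validate as val
from hiddenvar.config import PipelineConfig
from hiddenvar.pafio import read_paf
from hiddenvar.read_extraction import extract_read_sets, write_anchor_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _exists(inputs: dict, key: str) -> bool:
    return key in inputs and inputs[key] is not None and Path(inputs[key]).exists()


def run_pipeline(config: PipelineConfig, inputs: dict, outdir: str | Path) -> dict:
    """Run every stage over the given input manifest.

    ``inputs`` maps input names to paths: donor_ids (list), reads_dir
    (per-donor SAM + assignment tables), all_contigs_fasta, all_vs_all_paf,
    contigs_vs_ref_paf, taxon_map, blast_report, centrifuge_report and the
    optional annotation_gff3 / gwas_bed / sumstats_tsv / contigs_vs_assembly_paf
    / rescue_sam / rna_sam / insertions_vcf.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    donor_ids = list(inputs["donor_ids"])

    # ---- extract ---------------------------------------------------------
    stage = "extract"
    anchors = []
    try:
        if _exists(inputs, "reads_dir"):
            ex_dir = outdir / "extract"
            totals: dict[str, int] = {}
            n_extracted = 0
            for donor in donor_ids:
                sam = Path(inputs["reads_dir"]) / f"{donor}.sam"
                res = extract_read_sets(sam, ex_dir, donor, mode="strict_unaligned",
                                        mapq_threshold=config.mapq_threshold)
                n_extracted += res.n_extracted
                anchors.extend(res.anchors)
                for cls, n in res.class_counts.items():
                    totals[cls.value] = totals.get(cls.value, 0) + n
            write_anchor_table(anchors, outdir / "anchors.tsv")
            report["stages"][stage] = {
                "class_counts": totals, "n_extracted": n_extracted,
                "n_anchors": len(anchors),
            }
        else:
            report["stages"][stage] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- qc --------------------------------------------------------------
    stage = "qc"
    try:
        contigs = qc.load_contigs_fasta(inputs["all_contigs_fasta"])
        contigs = qc.length_filter(contigs, config.min_contig_length)
        taxon_map = (
            qc.load_taxon_map(inputs["taxon_map"])
            if _exists(inputs, "taxon_map") else {}
        )
        hits = qc.parse_classifier_reports(
            inputs.get("blast_report"), inputs.get("centrifuge_report"), taxon_map
        )
        policy = qc.ScreenPolicy(config.blast_evalue_max, config.blast_alen_min)
        contigs, removal = qc.screen_contaminants(contigs, hits, policy)
        removal.write(outdir / "removed_contigs.tsv")
        qc.write_pass_fasta(contigs, outdir / "contigs.pass.fa")
        passing = qc.passing(contigs)
        report["stages"][stage] = {
            "n_input": len(contigs),
            "n_pass": len(passing),
            "n_too_short": sum(c.qc_status is qc.QcStatus.TOO_SHORT for c in contigs),
            "n_contaminant": sum(
                c.qc_status is qc.QcStatus.CONTAMINANT for c in contigs
            ),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    lengths = {c.contig_id: c.length for c in passing}
    donor_of = {c.contig_id: c.donor_id for c in passing}

    # ---- collapse --------------------------------------------------------
    stage = "collapse"
    try:
        candidates = clp.containment_candidates(
            read_paf(inputs["all_vs_all_paf"]), lengths, config.collapse_threshold
        )
        supercontigs = clp.collapse_to_fixed_point(passing, candidates)
        membership = clp.membership_table(supercontigs, donor_of)
        clp.write_membership(membership, outdir / "membership.tsv")
        spectrum, spec_summary = clp.occurrence_spectrum(supercontigs, len(donor_ids))
        spectrum.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
        report["stages"][stage] = spec_summary
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- place -----------------------------------------------------------
    stage = "place"
    try:
        aln_records = [
            r for r in read_paf(inputs["contigs_vs_ref_paf"]) if r.query_id in lengths
        ]
        by_alignment = plc.place_by_alignment(aln_records, config.min_block)
        read_to_contig: dict[str, str] = {}
        if _exists(inputs, "reads_dir"):
            for donor in donor_ids:
                assign = Path(inputs["reads_dir"]) / f"{donor}.assign.tsv"
                if assign.exists():
                    with open(assign) as fh:
                        next(fh)
                        for line in fh:
                            rid, cid = line.rstrip("\n").split("\t")
                            read_to_contig[rid] = cid
        by_mate, mate_conflicts = plc.place_by_mate(
            read_to_contig, anchors, lengths,
            config.min_anchors, config.mate_window,
        )
        placements = plc.merge_placements(by_alignment, by_mate,
                                          config.agree_window)
        plc.write_placement_bed(placements, outdir / "placements.bed")
        report["stages"][stage] = {
            "n_by_alignment": len(by_alignment),
            "n_by_mate": len(by_mate),
            "n_mate_conflicts": len(mate_conflicts),
            "n_placed": len(placements),
            "n_unplaced": len(lengths) - len(placements),
            "n_method_both": sum(p.method == "both" for p in placements),
            "n_conflict": sum(p.conflict_flag for p in placements),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- ld --------------------------------------------------------------
    stage = "ld"
    try:
        matrix = ldgrid.build_matrix(membership, donor_ids, shared_only=True)
        matrix.write_tsv(outdir / "presence_matrix.tsv")
        pairs, ld_stats = ldgrid.pairwise_r2(matrix, config.r2_threshold)
        pairs, cls_summary = ldgrid.classify_pairs(pairs, placements,
                                                   config.ld_distance)
        ldgrid.write_pairs_tsv(pairs, outdir / "ld_pairs.tsv")
        anchors_df = ldgrid.anchor_unplaced(pairs, placements,
                                            config.anchor_window)
        anchors_df.to_csv(outdir / "ld_anchors.bed", sep="\t", index=False,
                          header=False,
                          columns=["chrom", "start", "end", "unplaced_id"])
        report["stages"][stage] = {**ld_stats, **cls_summary,
                                   "n_anchor_regions": len(anchors_df)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- annotate --------------------------------------------------------
    stage = "annotate"
    gene_table = None
    gwas_table = None
    try:
        stage_report = {}
        if _exists(inputs, "annotation_gff3"):
            features = ann.read_gff3(inputs["annotation_gff3"])
            gene_table, feat_summary = ann.intersect_features(placements, features)
            gene_table.to_csv(outdir / "feature_intersections.tsv", sep="\t",
                              index=False)
            stage_report["features"] = feat_summary
        else:
            stage_report["features"] = {"skipped": True}
        if _exists(inputs, "gwas_bed"):
            sites = ann.read_gwas_bed(inputs["gwas_bed"])
            gwas_table, sweep = ann.gwas_distance_sweep(
                placements, sites, config.gwas_thresholds
            )
            gwas_table.to_csv(outdir / "gwas_distances.tsv", sep="\t", index=False)
            stage_report["gwas_sweep"] = sweep
        else:
            stage_report["gwas_sweep"] = {"skipped": True}
        report["stages"][stage] = stage_report
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- peaks -----------------------------------------------------------
    stage = "peaks"
    try:
        if _exists(inputs, "sumstats_tsv"):
            sumstats = ann.read_sumstats(inputs["sumstats_tsv"])
            peaks = ann.biobank_peak_sweep(sumstats, config.p_threshold,
                                           config.peak_merge)
            prox_table, prox_summary = ann.peak_contig_proximity(
                peaks, placements, config.peak_distance
            )
            prox_table.to_csv(outdir / "peak_proximity.tsv", sep="\t", index=False)
            report["stages"][stage] = {
                "n_peaks": len(peaks),
                "per_trait_peaks": {
                    t: sum(p.trait == t for p in peaks)
                    for t in sorted({p.trait for p in peaks})
                },
                **prox_summary,
            }
        else:
            report["stages"][stage] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- validate --------------------------------------------------------
    stage = "validate"
    try:
        stage_report = {}
        validated: set[str] = set()
        if _exists(inputs, "contigs_vs_assembly_paf"):
            results, rate = val.validate_contigs(
                read_paf(inputs["contigs_vs_assembly_paf"]), lengths,
                config.id_min, config.cov_min,
            )
            validated = {r.contig_id for r in results if r.validated}
            stage_report["long_read_validation"] = rate
            categories = {}
            if gene_table is not None and len(gene_table):
                categories["gene"] = list(
                    gene_table[gene_table["ftype"] == "gene"]["contig_id"]
                )
            if gwas_table is not None and len(gwas_table):
                for t in (100, 1000):
                    categories[f"gwas_within_{t}"] = list(
                        gwas_table[gwas_table["distance"] <= t]["contig_id"]
                    )
            if categories:
                stage_report["validated_intersections"] = (
                    val.validated_intersection_rates(categories, validated)
                )
        else:
            stage_report["long_read_validation"] = {"skipped": True}
        if _exists(inputs, "rescue_sam"):
            stage_report["rescued_reads"] = val.rescued_read_fraction(
                inputs["rescue_sam"], config.mapq_threshold
            )
        else:
            stage_report["rescued_reads"] = {"skipped": True}
        if _exists(inputs, "rna_sam"):
            shared_flags: dict[str, bool] = {}
            occ = membership.groupby("representative_id")["donor_id"].nunique()
            rep_of = dict(zip(membership["member_id"],
                              membership["representative_id"]))
            for cid in lengths:
                rep = rep_of.get(cid)
                shared_flags[cid] = bool(rep is not None and occ.get(rep, 0) >= 2)
            tallies, rna_summary = val.rnaseq_tally(
                inputs["rna_sam"], lengths, shared_flags, config.rna_thresholds
            )
            with open(outdir / "rna_tally.tsv", "w") as fh:
                fh.write("contig_id\tread_count\tdensity\tshared\n")
                for t in tallies:
                    fh.write(f"{t.contig_id}\t{t.read_count}\t{t.density:.3f}"
                             f"\t{t.shared}\n")
            stage_report["rnaseq"] = rna_summary
        else:
            stage_report["rnaseq"] = {"skipped": True}
        if _exists(inputs, "insertions_vcf"):
            calls = val.read_insertion_calls(inputs["insertions_vcf"])
            _, vcf_summary = val.overlap_vcf_insertions(
                placements, calls, config.vcf_window
            )
            stage_report["vcf_comparison"] = vcf_summary
        else:
            stage_report["vcf_comparison"] = {"skipped": True}
        report["stages"][stage] = stage_report
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete; report at %s", outdir / "report.json")
    return report


def inputs_from_cohort(cohort: dict) -> dict:
    """Input manifest for :func:`run_pipeline` from a
    :func:`hiddenvar.synthio.simulate_cohort` result."""
    keys = (
        "all_contigs_fasta", "all_vs_all_paf", "contigs_vs_ref_paf",
        "contigs_vs_assembly_paf", "blast_report", "centrifuge_report",
        "taxon_map", "annotation_gff3", "gwas_bed", "sumstats_tsv",
        "rescue_sam", "rna_sam", "insertions_vcf", "reads_dir",
    )
    manifest = {k: cohort[k] for k in keys if k in cohort}
    manifest["donor_ids"] = [d.donor_id for d in cohort["donors"]]
    return manifest
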