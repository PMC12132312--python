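"""Synthetic cohort generator with planted, recoverable truth.

Generates every input the rescued-read pipeline consumes — reference, donor
genomes with planted non-reference insertions at controlled frequencies,
paired reads with constructed alignment records, contig sets with exact PAF
catalogs, classifier reports, annotation/GWAS/summary-statistic catalogs and
auxiliary validation inputs — all deterministic under one seed and recorded
in a truth manifest.
"""

from __future__ import annotations

from pathlib import Path

from hiddenvar.synthio.catalogs import emit_feature_catalogs
from hiddenvar.synthio.contigs import (
    EmittedContig,
    build_contigs,
    emit_contigs_and_alignment_catalogs,
)
from hiddenvar.synthio.extras import (
    emit_insertion_vcf,
    emit_rescue_alignments,
    emit_rna_alignments,
)
from hiddenvar.synthio.generate import (
    DonorGenome,
    generate_reference,
    plant_population,
    write_fasta,
)
from hiddenvar.synthio.model import SimConfig, TruthManifest
from hiddenvar.synthio.reads import (
    emit_reads_and_alignments,
    expected_pair_count,
    spot_check_sam,
)

__all__ = [
    "SimConfig", "TruthManifest", "DonorGenome", "EmittedContig",
    "generate_reference", "plant_population", "write_fasta",
    "emit_reads_and_alignments", "expected_pair_count", "spot_check_sam",
    "build_contigs", "emit_contigs_and_alignment_catalogs",
    "emit_feature_catalogs", "emit_rescue_alignments", "emit_rna_alignments",
    "emit_insertion_vcf", "simulate_cohort",
]


def simulate_cohort(
    cfg: SimConfig,
    outdir: str | Path,
    with_reads: bool = True,
    with_extras: bool = True,
) -> dict:
    """Run every generator stage into ``outdir`` and return a path/object map.

    ``with_reads=False`` skips per-donor FASTQ/SAM emission (the contig-level
    analyses do not need reads); ``with_extras=False`` skips the rescue SAM,
    RNA SAM and insertion VCF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = generate_reference(cfg)
    write_fasta(reference, outdir / "reference.fa")
    donors, manifest = plant_population(cfg, reference)

    out = {
        "outdir": outdir,
        "reference": reference,
        "reference_fasta": outdir / "reference.fa",
        "donors": donors,
        "manifest": manifest,
    }

    if with_reads:
        out["read_summaries"] = emit_reads_and_alignments(
            cfg, reference, donors, manifest, outdir / "reads"
        )
        out["reads_dir"] = outdir / "reads"

    out.update(
        emit_contigs_and_alignment_catalogs(cfg, reference, donors, manifest, outdir)
    )
    out.update(emit_feature_catalogs(cfg, manifest, outdir / "catalogs"))

    if with_extras:
        if with_reads:
            out["rescue_sam"] = outdir / "rescue.sam"
            out["rescue_summary"] = emit_rescue_alignments(
                cfg, donors, outdir / "reads", out["rescue_sam"]
            )
        out["rna_sam"] = outdir / "rna.sam"
        emit_rna_alignments(cfg, out["contigs"], manifest, out["rna_sam"])
        out["insertions_vcf"] = outdir / "insertions.vcf"
        emit_insertion_vcf(cfg, manifest, out["insertions_vcf"])

    manifest.to_json(outdir / "truth.json")
    out["truth_json"] = outdir / "truth.json"
    return out
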