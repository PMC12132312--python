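"""Long-read validation thresholds, rescued-read accounting, RNA-seq
tallies, cross-set summaries and VCF insertion overlap."""

from __future__ import annotations

import pysam
import pytest

from hiddenvar.pafio import AlignmentRecord
from hiddenvar.placement import Placement
from hiddenvar.validate import (
    cross_set_summary,
    overlap_vcf_insertions,
    read_insertion_calls,
    rescued_read_fraction,
    rnaseq_tally,
    validate_contigs,
    validated_rate,
)


def aln(q, qlen, qs, qe, ident=1.0, mapq=60, target="asm"):
    block = qe - qs
    return AlignmentRecord(q, qlen, qs, qe, "+", target, 1_000_000, 0, block,
                           int(round(ident * block)), block, mapq)


def test_validation_thresholds():
    records = [
        aln("good", 1000, 0, 800, ident=0.95),
        aln("low_identity", 1000, 0, 800, ident=0.85),
        aln("low_coverage", 1000, 0, 400, ident=0.99),
    ]
    lengths = {"good": 1000, "low_identity": 1000, "low_coverage": 1000,
               "no_alignment": 1000}
    results, rate = validate_contigs(records, lengths, id_min=0.9, cov_min=0.5)
    by_id = {r.contig_id: r for r in results}
    assert by_id["good"].validated
    assert not by_id["low_identity"].validated
    assert not by_id["low_coverage"].validated
    assert not by_id["no_alignment"].validated
    assert rate["n_total"] == 4
    assert rate["pct_validated"] == pytest.approx(25.0)


def test_aligned_fraction_unions_split_blocks():
    records = [aln("c", 1000, 0, 300), aln("c", 1000, 250, 650)]
    (res,), _ = validate_contigs(records, {"c": 1000})
    assert res.aligned_fraction == pytest.approx(0.65)
    assert res.validated


def test_validation_rate_monotone_in_thresholds():
    records = [aln("a", 1000, 0, 900, ident=0.92),
               aln("b", 1000, 0, 600, ident=0.97)]
    lengths = {"a": 1000, "b": 1000}
    loose = validate_contigs(records, lengths, id_min=0.9, cov_min=0.5)[1]
    strict = validate_contigs(records, lengths, id_min=0.95, cov_min=0.8)[1]
    assert strict["n_validated"] <= loose["n_validated"]


def test_validated_rate_and_exclusions():
    validated = {f"c{i}" for i in range(8)}
    ids = [f"c{i}" for i in range(10)] + ["nolr"] * 2
    out = validated_rate(ids, validated, evaluable={f"c{i}" for i in range(10)})
    assert out["n_evaluable"] == 10
    assert out["n_excluded"] == 2
    assert out["pct_validated"] == pytest.approx(80.0)


def _write_sam(path, flags_mapqs, ref="c1", ln=5000):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref, "LN": ln}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, (flag, mapq) in enumerate(flags_mapqs):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"r{i}"
            rec.flag = flag
            if not flag & 4:
                rec.reference_id = 0
                rec.reference_start = 10
                rec.cigarstring = "50M"
                rec.mapping_quality = mapq
            fh.write(rec)


def test_rescued_fraction_extremes(tmp_path):
    all_mapped = tmp_path / "all.sam"
    _write_sam(all_mapped, [(0, 60)] * 5)
    assert rescued_read_fraction(all_mapped)["fraction"] == 1.0
    none_mapped = tmp_path / "none.sam"
    _write_sam(none_mapped, [(4, 0)] * 5)
    assert rescued_read_fraction(none_mapped)["fraction"] == 0.0


def test_cohort_rescue_splits_by_provenance(cohort):
    """Insertion-derived extracted reads all re-align to the donor assembly;
    contaminant reads do not."""
    rescue = cohort["rescue_sam"]
    truth_prov = {}
    for donor in cohort["donors"]:
        with open(cohort["reads_dir"] / f"{donor.donor_id}.reads.tsv") as fh:
            next(fh)
            for line in fh:
                rid, mate, prov, cls = line.rstrip("\n").split("\t")
                truth_prov[f"{rid}/{mate}"] = prov
    n_ins = n_ins_rescued = n_con = n_con_rescued = 0
    with pysam.AlignmentFile(str(rescue), check_sq=False) as fh:
        for rec in fh:
            prov = truth_prov[rec.query_name]
            ok = not rec.is_unmapped and rec.mapping_quality >= 20
            if prov == "con":
                n_con += 1
                n_con_rescued += ok
            else:
                n_ins += 1
                n_ins_rescued += ok
    assert n_ins and n_con
    assert n_ins_rescued / n_ins >= 0.95
    assert n_con_rescued / n_con == 0.0


def test_rna_tally_counts_and_strict_thresholds(cohort):
    manifest = cohort["manifest"]
    lengths = {c.contig_id: len(c.sequence) for c in cohort["contigs"]}
    tallies, summary = rnaseq_tally(cohort["rna_sam"], lengths)
    got = {t.contig_id: t.read_count for t in tallies}
    assert got == manifest.rna_counts      # secondary records not counted
    planted = list(manifest.rna_counts.values())
    assert summary["threshold_counts"][100] == sum(n > 100 for n in planted)
    assert summary["threshold_counts"][1000] == sum(n > 1000 for n in planted)
    for t in tallies:
        assert t.density == pytest.approx(
            t.read_count / (lengths[t.contig_id] / 1000)
        )


def test_cross_set_fractions():
    perfect = [aln(f"c{i}", 1000, 0, 1000) for i in range(4)]
    ids = [f"c{i}" for i in range(4)]
    assert cross_set_summary(perfect, ids)["fraction"] == 1.0
    assert cross_set_summary([], ids)["fraction"] == 0.0
    weak = [aln("c0", 1000, 0, 1000, ident=0.8)]
    assert cross_set_summary(weak, ids)["n_with_hit"] == 0
    low_mapq = [aln("c0", 1000, 0, 1000, mapq=10)]
    assert cross_set_summary(low_mapq, ids)["n_with_hit"] == 0


def test_vcf_overlap_windows():
    calls = [{"call_id": "i1", "chrom": "chr1", "pos": 5000, "svtype": "INS",
              "svlen": 2000},
             {"call_id": "i2", "chrom": "chr1", "pos": 6899, "svtype": "INS",
              "svlen": 300}]
    placements = [Placement("c", "chr1", 4800, 6000, "alignment", 600)]
    _, at0 = overlap_vcf_insertions(placements, calls, window=0)
    assert at0["n_calls_matched"] == 1          # i1 inside the interval
    _, at1kb = overlap_vcf_insertions(placements, calls, window=1000)
    assert at1kb["n_calls_matched"] == 2        # i2 is 900 bp from the edge
    assert at1kb["svlen_bins"]["100-500"]["n_matched"] == 1


def test_cohort_vcf_calls_round_trip(cohort):
    calls = read_insertion_calls(cohort["insertions_vcf"])
    planted = cohort["manifest"].vcf_calls
    assert len(calls) == len(planted)           # no-SVTYPE row skipped
    got = {(c["call_id"], c["chrom"], c["pos"], c["svtype"]) for c in calls}
    want = {(c["call_id"], c["chrom"], c["pos"], c["svtype"]) for c in planted}
    assert got == want
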