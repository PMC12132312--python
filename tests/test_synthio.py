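"""The generator's outputs must be deterministic, statistically calibrated
and exactly re-derivable from the planted truth."""

from __future__ import annotations

import filecmp

import numpy as np
import pysam
import pytest

from hiddenvar.pafio import read_paf
from hiddenvar.synthio import (
    SimConfig,
    expected_pair_count,
    generate_reference,
    plant_population,
    simulate_cohort,
    spot_check_sam,
)


def test_reference_shape_and_composition():
    cfg = SimConfig(seed=3, n_chromosomes=2, chrom_length=200_000)
    ref = generate_reference(cfg)
    assert list(ref) == ["chr1", "chr2"]
    for seq in ref.values():
        assert len(seq) == 200_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # uniform base model: GC is binomial(L, 0.5), 3 SD ~ 0.34 %
        assert 0.48 <= gc <= 0.52
    assert generate_reference(cfg) == ref  # determinism


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(chrom_length=-1)
    with pytest.raises(ValueError):
        SimConfig(insertion_frequencies=(0.0,))
    with pytest.raises(ValueError):
        SimConfig(insertion_length_range=(500, 2000))
    with pytest.raises(ValueError):
        SimConfig(coverage=0)


def test_carrier_counts_are_binomial_realizations():
    """At f=0.5 and N=100 the carrier count stays within 3 binomial SDs."""
    cfg = SimConfig(seed=5, n_donors=100, n_insertions=6,
                    insertion_frequencies=(0.5,), n_linked_pairs=0)
    ref = generate_reference(cfg)
    _, manifest = plant_population(cfg, ref)
    sd = (100 * 0.5 * 0.5) ** 0.5
    for ins in manifest.insertions:
        assert abs(len(ins.carriers) - 50) <= 3 * sd


def test_full_frequency_means_every_donor_carries():
    cfg = SimConfig(seed=5, n_donors=12, n_insertions=3,
                    insertion_frequencies=(1.0,), n_linked_pairs=0)
    _, manifest = plant_population(cfg, generate_reference(cfg))
    for ins in manifest.insertions:
        assert len(ins.carriers) == 12


def test_zero_mutation_rate_gives_identical_copies():
    cfg = SimConfig(seed=5, n_donors=6, n_insertions=4, mutation_rate=0.0,
                    insertion_frequencies=(1.0,), n_linked_pairs=0)
    donors, manifest = plant_population(cfg, generate_reference(cfg))
    catalog = {i.insertion_id: i.sequence for i in manifest.insertions}
    for donor in donors:
        for ins_id, copy in donor.carried_copies().items():
            assert copy == catalog[ins_id]


def test_cohort_is_byte_identical_under_seed(tmp_path):
    cfg = SimConfig(seed=42, n_donors=3, n_insertions=4, coverage=0.5)
    a = simulate_cohort(cfg, tmp_path / "a")
    b = simulate_cohort(cfg, tmp_path / "b")
    for key in ("reference_fasta", "truth_json", "all_contigs_fasta",
                "all_vs_all_paf", "contigs_vs_ref_paf"):
        assert filecmp.cmp(a[key], b[key], shallow=False), key
    assert filecmp.cmp(a["reads_dir"] / "D000.sam", b["reads_dir"] / "D000.sam",
                       shallow=False)


def test_read_pair_count_matches_coverage_formula(cohort, sim_cfg):
    for donor in cohort["donors"]:
        expected = expected_pair_count(sim_cfg, donor.total_length)
        emitted = cohort["read_summaries"][donor.donor_id]["n_pairs_genome"]
        assert abs(emitted - expected) <= max(1, 0.01 * expected)


def test_unmapped_pair_records_have_both_unmapped_flags(cohort):
    reads_dir = cohort["reads_dir"]
    unmapped_names = set()
    with open(reads_dir / "D000.reads.tsv") as fh:
        next(fh)
        for line in fh:
            rid, mate, prov, cls = line.rstrip("\n").split("\t")
            if cls == "unmapped":
                unmapped_names.add(rid)
    assert unmapped_names, "cohort should contain unmapped pairs"
    seen = 0
    with pysam.AlignmentFile(str(reads_dir / "D000.sam"), check_sq=False) as fh:
        for rec in fh:
            if rec.query_name in unmapped_names:
                assert rec.is_unmapped and rec.mate_is_unmapped
                seen += 1
    assert seen == 2 * len(unmapped_names)


def test_half_mapped_anchor_lies_near_planted_insertion(cohort, sim_cfg):
    """The mapped mate of a half-mapped pair must sit within
    insert_mean + 4*insert_sd of the insertion the unmapped mate came from."""
    manifest = cohort["manifest"]
    point_of = {i.insertion_id: (i.chrom, i.point) for i in manifest.insertions}
    bound = sim_cfg.insert_mean + 4 * sim_cfg.insert_sd
    for donor in cohort["donors"][:3]:
        truth = {}
        with open(cohort["reads_dir"] / f"{donor.donor_id}.reads.tsv") as fh:
            next(fh)
            for line in fh:
                rid, mate, prov, cls = line.rstrip("\n").split("\t")
                truth.setdefault(rid, {})[cls] = prov
        n_checked = 0
        sam = cohort["reads_dir"] / f"{donor.donor_id}.sam"
        with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
            for rec in fh:
                info = truth.get(rec.query_name, {})
                if "half_mapped_mapped" not in info or rec.is_unmapped:
                    continue
                ins_id = info["half_mapped_unmapped"]
                chrom, point = point_of[ins_id]
                assert rec.reference_name == chrom
                assert abs(rec.reference_start - point) <= bound
                n_checked += 1
        assert n_checked > 0


def test_sam_records_rederive_from_donor_genome(cohort, sim_cfg):
    donor = cohort["donors"][0]
    sam = cohort["reads_dir"] / f"{donor.donor_id}.sam"
    assert spot_check_sam(sim_cfg, cohort["reference"], donor, sam, 1000) > 0


def test_all_vs_all_match_counts_are_exact(cohort):
    """PAF residue-match counts equal a direct base-by-base comparison of the
    emitted contig sequences."""
    seqs = {}
    with pysam.FastxFile(str(cohort["all_contigs_fasta"])) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence
    checked = 0
    for rec in read_paf(cohort["all_vs_all_paf"]):
        if checked >= 50:
            break
        a, b = seqs[rec.query_id], seqs[rec.target_id]
        L = min(len(a), len(b))
        n_match = sum(x == y for x, y in zip(a[:L], b[:L]))
        assert rec.n_match == n_match and rec.block_len == L
        checked += 1
    assert checked > 0


def test_reference_alignments_are_flank_blocks(cohort, sim_cfg):
    manifest = cohort["manifest"]
    placeable = {i.insertion_id for i in manifest.insertions if i.placeable}
    per_contig: dict[str, int] = {}
    for rec in read_paf(cohort["contigs_vs_ref_paf"]):
        assert rec.block_len == sim_cfg.flank_len
        ins_id = rec.query_id.split(".", 1)[1]
        assert ins_id in placeable
        per_contig[rec.query_id] = per_contig.get(rec.query_id, 0) + 1
    assert set(per_contig.values()) == {2}  # left and right flank


def test_catalogs_match_manifest(cohort):
    manifest = cohort["manifest"]
    n_gff = sum(
        1 for line in open(cohort["annotation_gff3"]) if not line.startswith("#")
    )
    assert n_gff == len(manifest.features)
    n_bed = sum(1 for line in open(cohort["gwas_bed"]) if line.strip())
    assert n_bed == len(manifest.gwas_sites)
    n_stats = sum(1 for line in open(cohort["sumstats_tsv"])) - 1
    assert n_stats == len(manifest.sumstat_loci)
    offsets = {s.offset for s in manifest.gwas_sites}
    assert offsets == {0, 100, 1000}
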