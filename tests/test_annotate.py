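"""Interval intersections, GWAS distance sweeps and biobank peak calling,
with brute-force oracles and monotonicity properties."""

from __future__ import annotations

import random

import pandas as pd
import pytest

from hiddenvar.annotate import (
    Feature,
    GwasSite,
    biobank_peak_sweep,
    gwas_distance_sweep,
    intersect_features,
    interval_point_distance,
    peak_contig_proximity,
    read_gff3,
)
from hiddenvar.placement import Placement


def place(cid, start, end, chrom="chr1"):
    return Placement(cid, chrom, start, end, "alignment", end - start)


def feat(start, end, ftype="gene", name="g", chrom="chr1"):
    return Feature(chrom, start, end, ftype, name)


def test_gff3_coordinates_convert_to_half_open(tmp_path):
    gff = tmp_path / "t.gff3"
    gff.write_text("##gff-version 3\nchr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
    (f,) = read_gff3(gff)
    assert (f.start, f.end) == (100, 200)
    assert f.ftype == "gene"


def test_overlap_is_half_open():
    table, _ = intersect_features([place("c", 100, 200)],
                                  [feat(150, 300), feat(200, 300, name="h")])
    assert len(table) == 1          # [100,200) does not touch [200,300)
    assert table.loc[0, "feature_name"] == "g"


def test_intersections_match_all_pairs_oracle():
    rng = random.Random(5)
    placements = [
        place(f"c{i}", s := rng.randrange(0, 90_000), s + rng.randrange(500, 5000))
        for i in range(20)
    ]
    features = [
        feat(s := rng.randrange(0, 90_000), s + rng.randrange(100, 8000),
             name=f"g{j}")
        for j in range(30)
    ]
    table, summary = intersect_features(placements, features)
    oracle = sum(
        1 for p in placements for f in features
        if p.start < f.end and f.start < p.end
    )
    assert len(table) == oracle
    assert summary["n_intersections"] == oracle


def test_distance_function():
    assert interval_point_distance(100, 200, 150) == 0
    assert interval_point_distance(100, 200, 100) == 0
    assert interval_point_distance(100, 200, 200) == 1   # half-open end
    assert interval_point_distance(100, 200, 0) == 100
    assert interval_point_distance(100, 200, 299) == 100


def test_sweep_boundaries_and_counts():
    placements = [place("c", 1000, 2000)]
    sites = [GwasSite("chr1", 1500, "inside"),
             GwasSite("chr1", 900, "at100"),
             GwasSite("chr1", 2999, "at1000"),
             GwasSite("chr2", 1500, "otherchrom")]
    table, sweep = gwas_distance_sweep(placements, sites, (0, 100, 1000))
    assert sweep[0] == {"n_placements": 1, "n_unique_sites": 1, "n_pairs": 1}
    assert sweep[100]["n_unique_sites"] == 2
    assert sweep[1000]["n_unique_sites"] == 3
    assert "otherchrom" not in set(table["site_id"])


def test_sweep_counts_are_monotone():
    rng = random.Random(13)
    placements = [
        place(f"c{i}", s := rng.randrange(0, 500_000), s + 2000)
        for i in range(40)
    ]
    sites = [GwasSite("chr1", rng.randrange(0, 500_000), f"s{j}")
             for j in range(60)]
    thresholds = [0, 10, 100, 1000, 10_000]
    _, sweep = gwas_distance_sweep(placements, sites, thresholds)
    for lo, hi in zip(thresholds, thresholds[1:]):
        assert sweep[lo]["n_placements"] <= sweep[hi]["n_placements"]
        assert sweep[lo]["n_unique_sites"] <= sweep[hi]["n_unique_sites"]


def sumstats(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "trait", "neglog10p"])


def test_peak_sweep_greedy_by_significance():
    df = sumstats([
        ("chr1", 100_000, "t", 9.0),
        ("chr1", 120_000, "t", 7.0),
        ("chr1", 500_000, "t", 8.0),
    ])
    peaks = biobank_peak_sweep(df, 1e-6, 50_000)
    assert [(p.pos, p.neglog10p) for p in peaks] == [(100_000, 9.0),
                                                     (500_000, 8.0)]


def test_equal_significance_tie_keeps_left():
    df = sumstats([("chr1", 60_000, "t", 8.0), ("chr1", 10_001, "t", 8.0)])
    peaks = biobank_peak_sweep(df, 1e-6, 50_000)
    assert [(p.pos,) for p in peaks] == [(10_001,)]   # 49,999 bp apart: merged


def test_no_significant_loci_means_no_peaks():
    df = sumstats([("chr1", 1000, "t", 3.0)])
    assert biobank_peak_sweep(df, 1e-6) == []


def _random_sumstats(rng, n=80):
    return sumstats([
        ("chr1" if rng.random() < 0.7 else "chr2",
         rng.randrange(0, 2_000_000),
         rng.choice(["tA", "tB"]),
         rng.uniform(2, 12))
        for _ in range(n)
    ])


def test_peak_invariants_on_random_inputs():
    """No two retained peaks of a trait within the merge window; every
    discarded significant locus is dominated within the window."""
    rng = random.Random(99)
    for _ in range(10):
        df = _random_sumstats(rng)
        peaks = biobank_peak_sweep(df, 1e-6, 50_000)
        by_trait: dict[str, list] = {}
        for p in peaks:
            by_trait.setdefault(p.trait, []).append(p)
        for trait, ps in by_trait.items():
            for i, a in enumerate(ps):
                for b in ps[i + 1:]:
                    assert a.chrom != b.chrom or abs(a.pos - b.pos) > 50_000
        retained = {(p.trait, p.chrom, p.pos) for p in peaks}
        sig = df[df["neglog10p"] >= 6.0]
        for row in sig.itertuples():
            if (row.trait, row.chrom, row.pos) in retained:
                continue
            assert any(
                p.trait == row.trait and p.chrom == row.chrom
                and abs(p.pos - row.pos) <= 50_000
                and p.neglog10p >= row.neglog10p
                for p in peaks
            )


def test_peak_count_monotone_in_threshold_and_window():
    rng = random.Random(55)
    df = _random_sumstats(rng, 120)
    n_loose = len(biobank_peak_sweep(df, 1e-4, 50_000))
    n_tight = len(biobank_peak_sweep(df, 1e-8, 50_000))
    assert n_tight <= n_loose
    n_small_win = len(biobank_peak_sweep(df, 1e-6, 10_000))
    n_big_win = len(biobank_peak_sweep(df, 1e-6, 200_000))
    assert n_big_win <= n_small_win


def test_peak_proximity_windows():
    from hiddenvar.annotate import Peak

    peaks = [Peak("t", "chr1", 1_000_000, 8.0)]
    placements = [place("near", 1_900_000, 1_902_000),
                  place("contains", 999_000, 1_002_000)]
    _, at_10kb = peak_contig_proximity(peaks, placements, 10_000)
    _, at_1mb = peak_contig_proximity(peaks, placements, 1_000_000)
    assert at_10kb["n_pairs"] == 1          # only the containing placement
    assert at_1mb["n_pairs"] == 2           # ~900 kb contig joins at 1 Mb
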