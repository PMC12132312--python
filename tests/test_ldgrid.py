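"""Presence/absence grid construction and pairwise r^2 behaviour, checked
against hand-computed Pearson values and a brute-force covariance formula."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hiddenvar.ldgrid import (
    LDPair,
    PresenceMatrix,
    anchor_unplaced,
    build_matrix,
    classify_pairs,
    fraction_of_all_pairs,
    pairwise_r2,
    summarize_pairs,
)
from hiddenvar.placement import Placement


def matrix_from_columns(cols: dict[str, list[int]]) -> PresenceMatrix:
    ids = list(cols)
    cells = np.array(list(zip(*cols.values())), dtype=np.int8)
    donors = [f"d{i}" for i in range(cells.shape[0])]
    return PresenceMatrix(donors, ids, cells)


def test_build_matrix_column_and_sums():
    membership = pd.DataFrame({
        "member_id": ["m1", "m2", "m3"],
        "representative_id": ["S", "S", "S"],
        "donor_id": ["d1", "d3", "d3"],
    })
    mat = build_matrix(membership, ["d1", "d2", "d3"], shared_only=False)
    assert mat.cells[:, 0].tolist() == [1, 0, 1]
    assert mat.column_sums() == {"S": 2}


def test_build_matrix_rejects_unknown_donor():
    membership = pd.DataFrame({
        "member_id": ["m1"], "representative_id": ["S"], "donor_id": ["dX"],
    })
    with pytest.raises(ValueError, match="dX"):
        build_matrix(membership, ["d1"])


def test_shared_only_drops_singletons():
    membership = pd.DataFrame({
        "member_id": ["m1", "m2", "m3"],
        "representative_id": ["S", "S", "U"],
        "donor_id": ["d1", "d2", "d1"],
    })
    mat = build_matrix(membership, ["d1", "d2"])
    assert mat.supercontig_ids == ["S"]


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),          # identical
        ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),          # complementary: r = -1
        ([1, 1, 1, 0], [1, 1, 0, 0], 1 / 3),        # hand Pearson value
    ],
)
def test_r2_hand_values(x, y, expected):
    mat = matrix_from_columns({"a": x, "b": y})
    pairs, _ = pairwise_r2(mat, threshold=1e-9)
    assert len(pairs) == 1
    assert pairs[0].r2 == pytest.approx(expected, abs=1e-12)


def test_orthogonal_columns_have_zero_r2():
    mat = matrix_from_columns({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]})
    pairs, stats = pairwise_r2(mat, threshold=1e-9)
    assert pairs == []          # r2 = 0 is not strictly above any threshold
    assert stats["n_tested_columns"] == 2


def test_constant_columns_excluded_with_count():
    mat = matrix_from_columns({
        "fixed": [1, 1, 1, 1], "absent": [0, 0, 0, 0],
        "a": [1, 0, 1, 0], "b": [1, 0, 1, 0],
    })
    pairs, stats = pairwise_r2(mat, 0.9)
    assert stats["n_constant_columns"] == 2
    assert {(p.id_a, p.id_b) for p in pairs} == {("a", "b")}


def test_r2_matches_covariance_formula_on_random_matrices():
    """Brute-force oracle: r = (n Sxy - Sx Sy) / sqrt((n Sxx - Sx^2)(n Syy - Sy^2))."""
    rng = np.random.default_rng(17)
    for _ in range(3):
        cells = (rng.random((30, 40)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        mat = PresenceMatrix(
            [f"d{i}" for i in range(30)], [f"s{j}" for j in range(40)], cells
        )
        pairs, _ = pairwise_r2(mat, threshold=1e-6)
        got = {(p.id_a, p.id_b): p.r2 for p in pairs}
        X = cells.astype(float)
        n = X.shape[0]
        for (a, b), r2 in got.items():
            x = X[:, mat.supercontig_ids.index(a)]
            y = X[:, mat.supercontig_ids.index(b)]
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = (n * (x * x).sum() - x.sum() ** 2) * \
                  (n * (y * y).sum() - y.sum() ** 2)
            assert r2 == pytest.approx(num**2 / den, abs=1e-12)


def test_fraction_uses_ordered_pair_denominator():
    assert fraction_of_all_pairs(4, 10) == pytest.approx(4.0)
    assert fraction_of_all_pairs(0, 0) == 0.0


def test_classify_pairs_distances():
    placements = [
        Placement("a", "chr1", 0, 2000, "alignment", 600),
        Placement("b", "chr1", 8000, 10_000, "alignment", 600),
        Placement("c", "chr2", 0, 2000, "alignment", 600),
    ]
    pairs = [LDPair("a", "b", 0.95), LDPair("a", "c", 0.95),
             LDPair("a", "u", 0.95)]
    annotated, summary = classify_pairs(pairs, placements, 10_000)
    by_key = {(p.id_a, p.id_b): p for p in annotated}
    assert by_key[("a", "b")].same_chromosome
    assert by_key[("a", "b")].pair_distance == 8000
    assert by_key[("a", "c")].same_chromosome is False
    assert by_key[("a", "u")].same_chromosome is None
    assert summary["n_same_chromosome"] == 1
    assert summary["n_within_distance"] == 1
    assert summary["n_both_placed"] == 2


def test_summarize_pairs_percentage():
    pairs = [LDPair("a", "b", 0.95, True, 5000)] * 3 + \
            [LDPair("c", "d", 0.95, False, None)] * 7
    summary = summarize_pairs(pairs, 10_000)
    assert summary["pct_same_chromosome_of_high"] == pytest.approx(30.0)


def test_anchor_regions():
    placements = [Placement("p", "chr5", 100_000, 102_000, "alignment", 600),
                  Placement("q", "chr5", 50_000, 51_000, "alignment", 600)]
    pairs = [LDPair("p", "u", 0.95), LDPair("q", "u", 0.95),
             LDPair("p", "q", 0.99)]
    table = anchor_unplaced(pairs, placements, anchor_window=100_000)
    assert len(table) == 2                      # two anchors for u, none for p/q
    first = table.iloc[0]
    assert first["start"] == 0                  # clamped at zero
    assert first["end"] == 202_000 or first["end"] == 151_000


def test_low_r2_pairs_never_reach_anchoring():
    """The r^2 > 0.9 cutoff is strict and applied upstream."""
    mat = matrix_from_columns({"a": [1, 1, 0, 0, 1], "b": [1, 1, 0, 1, 0]})
    pairs, _ = pairwise_r2(mat, 0.9)
    assert pairs == []           # r2 ~ 0.17 here; nothing to anchor
    assert anchor_unplaced(pairs, [], 1000).empty
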