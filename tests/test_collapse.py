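"""Containment candidates, fixed-point collapsing and the occurrence
spectrum: the partition must match a brute-force transitive closure and be
invariant to input order."""

from __future__ import annotations

import random
from dataclasses import dataclass

import pytest

from hiddenvar.collapse import (
    collapse_to_fixed_point,
    containment_candidates,
    membership_table,
    occurrence_spectrum,
)
from hiddenvar.pafio import AlignmentRecord


@dataclass(frozen=True)
class FakeContig:
    contig_id: str
    donor_id: str
    length: int


def paf(q, ql, qs, qe, t, tl, ts, te, mapq=60):
    block = max(qe - qs, te - ts)
    return AlignmentRecord(q, ql, qs, qe, "+", t, tl, ts, te, block, block, mapq)


def test_full_length_identical_pair_is_candidate():
    recs = [paf("a", 2000, 0, 2000, "b", 2000, 0, 2000)]
    assert containment_candidates(recs, {"a": 2000, "b": 2000}) == {("a", "b")}


def test_partial_alignment_at_80pct_is_not_candidate():
    recs = [paf("a", 1000, 0, 800, "b", 3000, 100, 900)]
    assert containment_candidates(recs, {"a": 1000, "b": 3000}) == set()


def test_split_blocks_union_on_shorter_contig():
    """Two 700 bp blocks covering 1400 of a 1500 bp contig: 0.933 > 0.9."""
    recs = [
        paf("a", 1500, 0, 700, "b", 4000, 0, 700),
        paf("a", 1500, 750, 1450, "b", 4000, 800, 1500),
    ]
    assert containment_candidates(recs, {"a": 1500, "b": 4000}) == {("a", "b")}
    # overlapping blocks must not double-count
    recs_overlap = [
        paf("a", 1500, 0, 700, "b", 4000, 0, 700),
        paf("a", 1500, 300, 1000, "b", 4000, 300, 1000),
    ]
    assert containment_candidates(recs_overlap, {"a": 1500, "b": 4000}) == set()


def test_unknown_contig_alignment_skipped():
    recs = [paf("a", 2000, 0, 2000, "ghost", 2000, 0, 2000)]
    assert containment_candidates(recs, {"a": 2000}) == set()


def test_transitive_chain_resolves_to_largest():
    contigs = [FakeContig("A", "d1", 1000), FakeContig("B", "d2", 2000),
               FakeContig("C", "d3", 3000)]
    scs = collapse_to_fixed_point(contigs, {("A", "B"), ("B", "C")})
    assert len(scs) == 1
    assert scs[0].representative_id == "C"
    assert scs[0].member_ids == {"A", "B", "C"}
    assert scs[0].occurrence == 3


def test_equal_length_tie_picks_lexicographically_smaller():
    contigs = [FakeContig("B", "d1", 2000), FakeContig("A", "d2", 2000)]
    scs = collapse_to_fixed_point(contigs, {("A", "B")})
    assert scs[0].representative_id == "A"


def test_no_candidates_means_singletons():
    contigs = [FakeContig(c, "d", 1000 + i) for i, c in enumerate("xyz")]
    scs = collapse_to_fixed_point(contigs, set())
    assert len(scs) == 3
    assert all(len(sc.member_ids) == 1 for sc in scs)


def _random_instance(rng, n):
    contigs = [
        FakeContig(f"c{i:02d}", f"d{rng.randrange(5)}",
                   rng.randrange(1000, 9000))
        for i in range(n)
    ]
    ids = [c.contig_id for c in contigs]
    candidates = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.06:
                candidates.add((ids[i], ids[j]))
    return contigs, candidates


def brute_force_partition(contigs, candidates):
    """Independent oracle: expand groups until closure, then pick the longest
    (lexicographically smallest on ties) member as representative."""
    groups = [{c.contig_id} for c in contigs]
    changed = True
    while changed:
        changed = False
        for a, b in candidates:
            ga = next(g for g in groups if a in g)
            gb = next(g for g in groups if b in g)
            if ga is not gb:
                ga |= gb
                groups.remove(gb)
                changed = True
    length = {c.contig_id: c.length for c in contigs}
    return {
        min(g, key=lambda c: (-length[c], c)): frozenset(g) for g in groups
    }


def test_partition_matches_brute_force_closure():
    rng = random.Random(123)
    for _ in range(50):
        contigs, candidates = _random_instance(rng, rng.randrange(2, 50))
        scs = collapse_to_fixed_point(contigs, candidates)
        got = {sc.representative_id: sc.member_ids for sc in scs}
        assert got == brute_force_partition(contigs, candidates)


def test_collapse_idempotent_and_permutation_invariant():
    rng = random.Random(321)
    contigs, candidates = _random_instance(rng, 40)
    scs = collapse_to_fixed_point(contigs, candidates)
    # idempotence: collapsing the representative set again changes nothing
    reps = [FakeContig(sc.representative_id, "d", sc.representative_length)
            for sc in scs]
    rep_ids = {r.contig_id for r in reps}
    again = collapse_to_fixed_point(
        reps, {(a, b) for a, b in candidates if a in rep_ids and b in rep_ids}
    )
    assert {sc.representative_id for sc in again} == rep_ids
    # permutation invariance
    shuffled = contigs[:]
    rng.shuffle(shuffled)
    scs2 = collapse_to_fixed_point(shuffled, set(reversed(sorted(candidates))))
    assert {sc.representative_id: sc.member_ids for sc in scs} == \
           {sc.representative_id: sc.member_ids for sc in scs2}


def test_member_conservation():
    rng = random.Random(9)
    contigs, candidates = _random_instance(rng, 35)
    scs = collapse_to_fixed_point(contigs, candidates)
    assert sum(len(sc.member_ids) for sc in scs) == len(contigs)


def test_occurrence_counts_distinct_donors():
    contigs = [FakeContig("A", "d1", 3000), FakeContig("B", "d2", 1500),
               FakeContig("C", "d2", 1400)]
    scs = collapse_to_fixed_point(contigs, {("A", "B"), ("A", "C")})
    assert scs[0].occurrence == 2        # d2 counted once
    assert scs[0].shared

    table, summary = occurrence_spectrum(scs, 10)
    assert summary == {**summary, "n_shared": 1, "n_unique": 0}
    assert table.loc[0, "frequency"] == 0.2


def test_all_singletons_are_unique():
    contigs = [FakeContig(f"c{i}", f"d{i}", 2000) for i in range(4)]
    scs = collapse_to_fixed_point(contigs, set())
    _, summary = occurrence_spectrum(scs, 4)
    assert summary["n_shared"] == 0
    assert summary["n_unique"] == 4


def test_spectrum_rejects_small_cohort():
    contigs = [FakeContig("a", "d1", 2000), FakeContig("b", "d2", 2000)]
    scs = collapse_to_fixed_point(contigs, {("a", "b")})
    with pytest.raises(ValueError):
        occurrence_spectrum(scs, 1)


def test_membership_table_partitions_input():
    rng = random.Random(77)
    contigs, candidates = _random_instance(rng, 30)
    scs = collapse_to_fixed_point(contigs, candidates)
    table = membership_table(scs, {c.contig_id: c.donor_id for c in contigs})
    assert sorted(table["member_id"]) == sorted(c.contig_id for c in contigs)
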