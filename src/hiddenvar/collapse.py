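"""Collapsing near-identical contigs into a non-redundant super-contig set.

Two contigs are considered the same sequence when the aligned length between
them exceeds 90 % of the shorter contig's length (multiple alignment blocks
are merged by interval union on the shorter contig first). The larger contig
becomes the representative "super-contig" and absorbs the smaller; absorption
chains resolve transitively, and iteration until no further collapse occurs
makes the final partition the connected components of the candidate relation.
Determinism: contigs are processed sorted by (length descending, id
ascending), and an equal-length tie makes the lexicographically smaller id
the representative.

The occurrence spectrum — how many donors each super-contig appears in — is
the analog of an allele-frequency spectrum for non-reference sequence; a
super-contig seen in two or more donors is "shared", otherwise "unique".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

import pandas as pd

from hiddenvar.pafio import AlignmentRecord

logger = logging.getLogger(__name__)


class ContigLike(Protocol):
    contig_id: str
    donor_id: str

    @property
    def length(self) -> int: ...


@dataclass(frozen=True)
class SuperContig:
    representative_id: str
    member_ids: frozenset[str]
    donor_ids: frozenset[str]
    representative_length: int

    @property
    def occurrence(self) -> int:
        return len(self.donor_ids)

    @property
    def shared(self) -> bool:
        return self.occurrence >= 2


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def containment_candidates(
    alignments: Iterable[AlignmentRecord],
    lengths: dict[str, int],
    threshold: float = 0.9,
    mapq_floor: int = 0,
) -> set[tuple[str, str]]:
    """Unordered contig pairs whose mutual aligned length exceeds
    ``threshold`` of the shorter contig's length.

    Aligned length per pair is the union of non-overlapping block intervals
    projected onto the shorter contig. Self-hits are excluded; records naming
    unknown contigs are skipped with a warning.
    """
    per_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_unknown = 0
    for rec in alignments:
        if rec.query_id == rec.target_id:
            continue
        if rec.mapq < mapq_floor:
            continue
        if rec.query_id not in lengths or rec.target_id not in lengths:
            n_unknown += 1
            logger.debug("alignment references unknown contig (%s vs %s); skipped",
                         rec.query_id, rec.target_id)
            continue
        a, b = sorted((rec.query_id, rec.target_id))
        shorter = min((rec.query_id, rec.target_id), key=lambda c: (lengths[c], c))
        iv = (rec.qstart, rec.qend) if shorter == rec.query_id else (rec.tstart, rec.tend)
        per_pair.setdefault((a, b), []).append(iv)

    if n_unknown:
        logger.warning("%d alignments referenced unknown contigs; skipped",
                       n_unknown)
    candidates = set()
    for (a, b), ivs in per_pair.items():
        shorter = min((a, b), key=lambda c: (lengths[c], c))
        if _union_length(ivs) > threshold * lengths[shorter]:
            candidates.add((a, b))
    return candidates


def collapse_to_fixed_point(
    contigs: Iterable[ContigLike], candidates: set[tuple[str, str]]
) -> list[SuperContig]:
    """Absorb the smaller member of every candidate pair into the larger
    until a full pass makes no change; the result partitions the input.

    Implemented as the transitive closure of the candidate relation (which is
    what the pairwise absorption converges to): each connected component
    becomes one super-contig whose representative is its longest member,
    ties broken toward the lexicographically smaller id.
    """
    by_id = {c.contig_id: c for c in contigs}
    parent = {cid: cid for cid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in sorted(candidates):
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups: dict[str, set[str]] = {}
    for cid in by_id:
        groups.setdefault(find(cid), set()).add(cid)

    supercontigs = []
    for members in groups.values():
        rep = min(members, key=lambda c: (-by_id[c].length, c))
        supercontigs.append(
            SuperContig(
                representative_id=rep,
                member_ids=frozenset(members),
                donor_ids=frozenset(by_id[m].donor_id for m in members),
                representative_length=by_id[rep].length,
            )
        )
    supercontigs.sort(key=lambda sc: sc.representative_id)
    assert sum(len(sc.member_ids) for sc in supercontigs) == len(by_id)
    return supercontigs


def occurrence_spectrum(
    supercontigs: Iterable[SuperContig], n_individuals: int
) -> tuple[pd.DataFrame, dict]:
    """Per super-contig occurrence/frequency table plus summary counts and a
    10-bin frequency histogram."""
    supercontigs = list(supercontigs)
    max_occ = max((sc.occurrence for sc in supercontigs), default=0)
    if n_individuals < max_occ:
        raise ValueError(
            f"n_individuals={n_individuals} below maximum occurrence {max_occ}"
        )
    table = pd.DataFrame(
        {
            "representative_id": [sc.representative_id for sc in supercontigs],
            "occurrence": [sc.occurrence for sc in supercontigs],
            "frequency": [sc.occurrence / n_individuals for sc in supercontigs],
            "shared": [sc.shared for sc in supercontigs],
            "n_members": [len(sc.member_ids) for sc in supercontigs],
        }
    )
    bins = [i / 10 for i in range(11)]
    hist = (
        pd.cut(table["frequency"], bins=bins, include_lowest=True)
        .value_counts()
        .sort_index()
    )
    summary = {
        "n_supercontigs": len(table),
        "n_shared": int(table["shared"].sum()),
        "n_unique": int((~table["shared"]).sum()),
        "frequency_histogram": {str(k): int(v) for k, v in hist.items()},
    }
    return table, summary


def membership_table(supercontigs: Iterable[SuperContig],
                     donor_of: dict[str, str]) -> pd.DataFrame:
    rows = [
        (member, sc.representative_id, donor_of[member])
        for sc in supercontigs
        for member in sorted(sc.member_ids)
    ]
    return pd.DataFrame(rows, columns=["member_id", "representative_id", "donor_id"])


def write_membership(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_membership(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
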