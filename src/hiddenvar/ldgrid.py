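"""Presence/absence linkage disequilibrium of shared super-contigs.

Each column of the donors x super-contigs binary grid is a super-contig's
carrier indicator across the cohort; r^2 between two columns is the squared
Pearson correlation. Pairs exceeding the threshold (strictly) are "high-LD";
with placement data they are classified by chromosome and midpoint distance,
and a placed member of a high-LD pair acts as an anchor constraining the
likely location of an unplaced partner.

The reported fraction of all pairs uses the ordered-pair denominator M^2.
Constant columns (contigs fixed present in every donor, or in none) have
undefined r^2 and are excluded with an explicit count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hiddenvar.placement import Placement


@dataclass
class PresenceMatrix:
    donor_ids: list[str]
    supercontig_ids: list[str]
    cells: np.ndarray          # binary, donors x supercontigs

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.donor_ids), len(self.supercontig_ids)):
            raise ValueError("matrix shape does not match id lists")

    def column_sums(self) -> dict[str, int]:
        sums = self.cells.sum(axis=0)
        return {sc: int(s) for sc, s in zip(self.supercontig_ids, sums)}

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.cells, index=self.donor_ids,
                          columns=self.supercontig_ids)
        df.to_csv(path, sep="\t", index_label="donor_id")
        with open(str(path) + ".json", "w") as fh:
            json.dump({"n_donors": len(self.donor_ids),
                       "n_supercontigs": len(self.supercontig_ids)}, fh)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="donor_id")
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=np.int8))


@dataclass(frozen=True)
class LDPair:
    id_a: str
    id_b: str
    r2: float
    same_chromosome: bool | None = None
    pair_distance: int | None = None


def build_matrix(
    membership: pd.DataFrame,
    donor_ids: list[str],
    shared_only: bool = True,
) -> PresenceMatrix:
    """Binary grid from the collapse membership table (member_id,
    representative_id, donor_id); restricted to shared super-contigs
    (occurrence >= 2) by default."""
    known = set(donor_ids)
    unknown = set(membership["donor_id"]) - known
    if unknown:
        raise ValueError(f"membership names donors absent from donor list: "
                         f"{sorted(unknown)[:5]}")
    carriers = (
        membership.groupby("representative_id")["donor_id"].agg(set).to_dict()
    )
    reps = sorted(
        rep for rep, ds in carriers.items()
        if not shared_only or len(ds) >= 2
    )
    donor_index = {d: i for i, d in enumerate(donor_ids)}
    cells = np.zeros((len(donor_ids), len(reps)), dtype=np.int8)
    for j, rep in enumerate(reps):
        for d in carriers[rep]:
            cells[donor_index[d], j] = 1
    return PresenceMatrix(list(donor_ids), reps, cells)


def pairwise_r2(
    matrix: PresenceMatrix, threshold: float = 0.9
) -> tuple[list[LDPair], dict]:
    """All-pairs r^2 over non-constant columns; returns pairs with
    r2 strictly above the threshold plus bookkeeping counts."""
    X = matrix.cells.astype(float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two donors")
    sums = X.sum(axis=0)
    constant = (sums == 0) | (sums == n)
    keep = np.nonzero(~constant)[0]
    ids = [matrix.supercontig_ids[j] for j in keep]
    pairs: list[LDPair] = []
    if len(keep) >= 2:
        corr = np.corrcoef(X[:, keep], rowvar=False)
        r2 = corr**2
        iu, ju = np.triu_indices(len(keep), k=1)
        mask = r2[iu, ju] > threshold
        for i, j in zip(iu[mask], ju[mask]):
            pairs.append(LDPair(ids[i], ids[j], float(r2[i, j])))
    stats = {
        "n_supercontigs": m,
        "n_constant_columns": int(constant.sum()),
        "n_tested_columns": int(len(keep)),
        "n_high_ld_pairs": len(pairs),
        "pct_of_all_pairs": fraction_of_all_pairs(len(pairs), m),
    }
    return pairs, stats


def fraction_of_all_pairs(n_high: int, n_supercontigs: int) -> float:
    """Percentage of all (ordered) pairs: 100 * n_high / M^2."""
    if n_supercontigs == 0:
        return 0.0
    return 100.0 * n_high / (n_supercontigs**2)


def summarize_pairs(
    annotated: Sequence[LDPair], distance_threshold: int = 10_000
) -> dict:
    """Summary counts/percentages over an annotated high-LD pair list."""
    n_high = len(annotated)
    n_both = sum(p.same_chromosome is not None for p in annotated)
    n_same = sum(bool(p.same_chromosome) for p in annotated)
    n_within = sum(
        p.pair_distance is not None and p.pair_distance <= distance_threshold
        for p in annotated
    )
    return {
        "n_high_ld_pairs": n_high,
        "n_both_placed": n_both,
        "n_same_chromosome": n_same,
        "n_within_distance": n_within,
        "distance_threshold": distance_threshold,
        "pct_same_chromosome_of_high": 100.0 * n_same / n_high if n_high else 0.0,
    }


def classify_pairs(
    pairs: Iterable[LDPair],
    placements: Iterable[Placement],
    distance_threshold: int = 10_000,
) -> tuple[list[LDPair], dict]:
    """Annotate high-LD pairs with placement chromosome/distance and report
    summary counts and percentages."""
    by_contig = {p.contig_id: p for p in placements}
    annotated: list[LDPair] = []
    for pair in pairs:
        pa, pb = by_contig.get(pair.id_a), by_contig.get(pair.id_b)
        if pa is None or pb is None:
            annotated.append(LDPair(pair.id_a, pair.id_b, pair.r2))
            continue
        same = pa.chrom == pb.chrom
        dist = int(abs(pa.midpoint - pb.midpoint)) if same else None
        annotated.append(LDPair(pair.id_a, pair.id_b, pair.r2, same, dist))
    return annotated, summarize_pairs(annotated, distance_threshold)


def anchor_unplaced(
    pairs: Iterable[LDPair],
    placements: Iterable[Placement],
    anchor_window: int = 100_000,
) -> pd.DataFrame:
    """Candidate regions for unplaced contigs in high LD with a placed one:
    the placed partner's interval widened by the anchor window (clamped at 0).
    An unplaced contig in high LD with several placed contigs gets one row
    per anchor."""
    by_contig = {p.contig_id: p for p in placements}
    rows = []
    for pair in pairs:
        for unplaced, placed in ((pair.id_a, pair.id_b), (pair.id_b, pair.id_a)):
            if unplaced in by_contig or placed not in by_contig:
                continue
            p = by_contig[placed]
            rows.append((
                p.chrom, max(0, p.start - anchor_window), p.end + anchor_window,
                unplaced, placed, pair.r2,
            ))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "unplaced_id", "anchor_id", "r2"],
    ).sort_values(["unplaced_id", "chrom", "start"]).reset_index(drop=True)


def write_pairs_tsv(pairs: Iterable[LDPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr2\tsame_chromosome\tpair_distance\n")
        for p in pairs:
            same = "" if p.same_chromosome is None else int(p.same_chromosome)
            dist = "" if p.pair_distance is None else p.pair_distance
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.r2:.6f}\t{same}\t{dist}\n")
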