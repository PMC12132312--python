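"""Reference synthetic recovery study: fixed cohort conditions and metrics.

Defines the cohort the recovery analyses are judged on — 200 donors, 40
planted insertions (1–3 kb) over a 4 x 250 kb reference, two insertion pairs
with identical carrier sets, one in ten insertions unplaceable — and runs the
contig-level pipeline (QC -> collapse -> placement -> presence/absence LD)
against it, measuring:

* frequency recovery: for how many insertions the estimated carrier
  frequency (super-contig occurrence / N) lies within three binomial
  standard deviations of the planted frequency;
* placement recall: the fraction of carried, placeable insertions recovered
  as a placement whose interval lies within the tolerance window of the true
  insertion point;
* presence/absence LD calibration: identical-carrier insertion pairs must
  reach r^2 = 1 while independently planted pairs stay below the 0.9
  threshold;
* contaminant screening exactness: the surviving contig set is precisely
  the planted insertion contigs.

Problem sizes are chosen so the whole study runs in minutes on one core at
contig level (reads are not needed for these metrics).
"""

from __future__ import annotations

import math
from itertools import combinations
from pathlib import Path

import numpy as np

from hiddenvar import collapse as clp
from hiddenvar import contigqc as qc
from hiddenvar import ldgrid
from hiddenvar import placement as plc
from hiddenvar.annotate import interval_point_distance
from hiddenvar.config import PipelineConfig
from hiddenvar.pafio import read_paf
from hiddenvar.synthio import SimConfig, simulate_cohort


def study_config(seed: int) -> SimConfig:
    """The recovery-study cohort conditions."""
    return SimConfig(
        seed=seed,
        n_donors=200,
        n_insertions=40,
        n_chromosomes=4,
        chrom_length=250_000,
        n_linked_pairs=2,
    )


def run_recovery_study(
    seed: int,
    workdir: str | Path,
    pipeline_config: PipelineConfig | None = None,
    point_window: int = 1000,
) -> dict:
    """Simulate the study cohort (contig level) and measure recovery."""
    cfg = study_config(seed)
    pcfg = pipeline_config or PipelineConfig(seed=seed)
    cohort = simulate_cohort(cfg, workdir, with_reads=False, with_extras=False)
    manifest = cohort["manifest"]
    donor_ids = [d.donor_id for d in cohort["donors"]]

    contigs = qc.length_filter(
        qc.load_contigs_fasta(cohort["all_contigs_fasta"]),
        pcfg.min_contig_length,
    )
    taxon_map = qc.load_taxon_map(cohort["taxon_map"])
    hits = qc.parse_classifier_reports(
        cohort["blast_report"], cohort["centrifuge_report"], taxon_map
    )
    contigs, _ = qc.screen_contaminants(contigs, hits)
    passing = qc.passing(contigs)
    lengths = {c.contig_id: c.length for c in passing}
    donor_of = {c.contig_id: c.donor_id for c in passing}

    # screening exactness: survivors must be exactly the insertion contigs
    planted_ok = {
        f"{d}.{ins.insertion_id}"
        for ins in manifest.insertions for d in ins.carriers
    }
    screen_exact = set(lengths) == planted_ok

    candidates = clp.containment_candidates(
        read_paf(cohort["all_vs_all_paf"]), lengths, pcfg.collapse_threshold
    )
    supercontigs = clp.collapse_to_fixed_point(passing, candidates)
    membership = clp.membership_table(supercontigs, donor_of)

    # map each insertion to its super-contig representative
    rep_of_member = dict(zip(membership["member_id"],
                             membership["representative_id"]))
    ins_rep: dict[str, str] = {}
    occ_of_rep = membership.groupby("representative_id")["donor_id"].nunique()
    for ins in manifest.insertions:
        if ins.carriers:
            member = f"{ins.carriers[0]}.{ins.insertion_id}"
            ins_rep[ins.insertion_id] = rep_of_member[member]

    n = cfg.n_donors
    n_within_3sd = 0
    for ins in manifest.insertions:
        occ = int(occ_of_rep.get(ins_rep.get(ins.insertion_id, ""), 0))
        est = occ / n
        sd = math.sqrt(ins.frequency * (1 - ins.frequency) / n)
        if abs(est - ins.frequency) <= 3 * sd:
            n_within_3sd += 1

    placements = plc.place_by_alignment(
        [r for r in read_paf(cohort["contigs_vs_ref_paf"]) if r.query_id in lengths],
        pcfg.min_block,
    )
    by_contig = {p.contig_id: p for p in placements}
    recall_num = recall_den = 0
    for ins in manifest.insertions:
        if not ins.placeable or not ins.carriers:
            continue
        recall_den += 1
        for d in ins.carriers:
            p = by_contig.get(f"{d}.{ins.insertion_id}")
            if p is not None and p.chrom == ins.chrom and \
                    interval_point_distance(p.start, p.end, ins.point) <= point_window:
                recall_num += 1
                break

    matrix = ldgrid.build_matrix(membership, donor_ids, shared_only=True)
    col = {sc: j for j, sc in enumerate(matrix.supercontig_ids)}
    X = matrix.cells.astype(float)

    def r2_between(rep_a: str, rep_b: str) -> float | None:
        if rep_a not in col or rep_b not in col or rep_a == rep_b:
            return None
        a, b = X[:, col[rep_a]], X[:, col[rep_b]]
        if a.std() == 0 or b.std() == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    linked_r2 = []
    linked_ids = set()
    for ins in manifest.insertions:
        if ins.linked_partner and ins.insertion_id < ins.linked_partner:
            linked_ids.update({ins.insertion_id, ins.linked_partner})
            r2 = r2_between(ins_rep.get(ins.insertion_id),
                            ins_rep.get(ins.linked_partner))
            if r2 is not None:
                linked_r2.append(r2)

    independent = [
        i.insertion_id for i in manifest.insertions
        if i.insertion_id not in linked_ids and i.insertion_id in ins_rep
    ]
    indep_r2 = [
        r2 for a, b in combinations(independent, 2)
        if (r2 := r2_between(ins_rep[a], ins_rep[b])) is not None
    ]
    n_indep = len(indep_r2)
    n_below = sum(r2 < pcfg.r2_threshold for r2 in indep_r2)

    return {
        "n_donors": n,
        "n_insertions": cfg.n_insertions,
        "n_pass_contigs": len(lengths),
        "screen_exact": screen_exact,
        "freq_within_3sd": n_within_3sd,
        "placement_recall_pct": 100.0 * recall_num / recall_den if recall_den else 0.0,
        "placement_recall_n": recall_den,
        "linked_pair_r2": linked_r2,
        "min_linked_pair_r2": min(linked_r2) if linked_r2 else None,
        "n_independent_pairs": n_indep,
        "pct_independent_below_threshold": (
            100.0 * n_below / n_indep if n_indep else 0.0
        ),
    }
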