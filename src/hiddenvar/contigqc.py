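"""Length filtering and contaminant screening of assembled contigs.

Contigs shorter than 1 kb are discarded (the boundary is kept: 999 bp is
removed, 1000 bp kept). Remaining contigs are screened against classifier
reports — BLAST tabular hits and centrifuge-style per-sequence labels — and
removed if any qualifying hit maps to a non-human taxon. "High scoring" is
operationalised as a configurable policy (BLAST e-value <= 1e-5 and aligned
length >= 100 bp; any centrifuge non-human label), permissive toward removal:
human-labelled hits never rescue a contig that also has qualifying non-human
hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import pysam

logger = logging.getLogger(__name__)


class QcStatus(Enum):
    PASS = "PASS"
    TOO_SHORT = "TOO_SHORT"
    CONTAMINANT = "CONTAMINANT"


@dataclass(frozen=True)
class Contig:
    contig_id: str
    donor_id: str
    sequence: str
    qc_status: QcStatus = QcStatus.PASS
    qc_reason: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


class TaxonClass(Enum):
    HUMAN = "human"
    NON_HUMAN = "non_human"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierHit:
    contig_id: str
    source: str                     # 'blast_tabular' or 'centrifuge_label'
    subject_label: str
    taxon_class: TaxonClass
    evalue: float | None = None     # blast only
    bitscore: float | None = None   # blast only
    aligned_len: int | None = None  # blast only


@dataclass
class ScreenPolicy:
    """A non-human BLAST hit qualifies if e-value <= evalue_max and aligned
    length >= aligned_len_min; any centrifuge non-human label qualifies."""

    evalue_max: float = 1e-5
    aligned_len_min: int = 100


def load_contigs_fasta(path: str | Path, donor_of=None) -> list[Contig]:
    """Read contigs from FASTA; donor id is derived from the name prefix
    before the first '.' unless a ``donor_of`` callable is given."""
    contigs = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            donor = donor_of(entry.name) if donor_of else entry.name.split(".")[0]
            contigs.append(Contig(entry.name, donor, entry.sequence.upper()))
    return contigs


def length_filter(contigs: Iterable[Contig], min_length: int = 1000) -> list[Contig]:
    """Mark contigs shorter than ``min_length`` as TOO_SHORT (>= kept)."""
    out = []
    for c in contigs:
        if c.length < min_length:
            out.append(replace(c, qc_status=QcStatus.TOO_SHORT,
                               qc_reason=f"length {c.length} < {min_length}"))
        else:
            out.append(replace(c, qc_status=QcStatus.PASS, qc_reason=""))
    return out


def _lookup_taxon(label: str, taxon_map: dict[str, str]) -> TaxonClass:
    cls = taxon_map.get(label)
    if cls is None:
        return TaxonClass.UNCLASSIFIED
    return TaxonClass(cls)


def load_taxon_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: subject label -> taxon class (human/non_human)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                label, cls = line.rstrip("\n").split("\t")
                out[label] = cls
    return out


def parse_classifier_reports(
    blast_path: str | Path | None,
    centrifuge_path: str | Path | None,
    taxon_map: dict[str, str],
) -> list[ClassifierHit]:
    """Parse BLAST outfmt-6-style and centrifuge-style label reports.

    BLAST columns: qseqid sseqid pident length evalue bitscore stitle.
    Centrifuge: contig_id <tab> label. Labels missing from the taxon map are
    recorded as unclassified; malformed rows are reported with line numbers;
    an absent file skips that source with a warning.
    """
    hits: list[ClassifierHit] = []
    if blast_path is not None and Path(blast_path).exists():
        with open(blast_path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 7:
                    raise ValueError(
                        f"{blast_path}:{ln}: expected 7 BLAST columns, got {len(f)}"
                    )
                try:
                    evalue, bitscore, alen = float(f[4]), float(f[5]), int(f[3])
                except ValueError as exc:
                    raise ValueError(f"{blast_path}:{ln}: {exc}") from None
                hits.append(ClassifierHit(
                    contig_id=f[0], source="blast_tabular", subject_label=f[6],
                    taxon_class=_lookup_taxon(f[6], taxon_map),
                    evalue=evalue, bitscore=bitscore, aligned_len=alen,
                ))
    elif blast_path is not None:
        logger.warning("BLAST report %s absent; source skipped", blast_path)
    if centrifuge_path is not None and Path(centrifuge_path).exists():
        with open(centrifuge_path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 2:
                    raise ValueError(
                        f"{centrifuge_path}:{ln}: expected 2 columns, got {len(f)}"
                    )
                hits.append(ClassifierHit(
                    contig_id=f[0], source="centrifuge_label", subject_label=f[1],
                    taxon_class=_lookup_taxon(f[1], taxon_map),
                ))
    elif centrifuge_path is not None:
        logger.warning("centrifuge report %s absent; source skipped", centrifuge_path)
    return hits


def _hit_qualifies(hit: ClassifierHit, policy: ScreenPolicy) -> bool:
    if hit.taxon_class is not TaxonClass.NON_HUMAN:
        return False
    if hit.source == "centrifuge_label":
        return True
    return hit.evalue <= policy.evalue_max and hit.aligned_len >= policy.aligned_len_min


@dataclass
class RemovalReport:
    rows: list[tuple[str, str]] = field(default_factory=list)  # contig_id, reason

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_id\treason\n")
            for cid, reason in self.rows:
                fh.write(f"{cid}\t{reason}\n")


def screen_contaminants(
    contigs: Iterable[Contig],
    hits: Iterable[ClassifierHit],
    policy: ScreenPolicy | None = None,
) -> tuple[list[Contig], RemovalReport]:
    """Mark contigs with any qualifying non-human hit as CONTAMINANT.

    Hits are unioned over sources; hits naming unknown contigs are ignored
    with a warning; TOO_SHORT contigs keep their status.
    """
    policy = policy or ScreenPolicy()
    contigs = list(contigs)
    known = {c.contig_id for c in contigs}
    reasons: dict[str, list[str]] = {}
    for hit in hits:
        if hit.contig_id not in known:
            logger.warning("classifier hit for unknown contig %s ignored",
                           hit.contig_id)
            continue
        if _hit_qualifies(hit, policy):
            reasons.setdefault(hit.contig_id, []).append(
                f"{hit.source}:{hit.subject_label}"
            )
    out = []
    report = RemovalReport()
    for c in contigs:
        if c.qc_status is QcStatus.PASS and c.contig_id in reasons:
            reason = "; ".join(reasons[c.contig_id])
            out.append(replace(c, qc_status=QcStatus.CONTAMINANT, qc_reason=reason))
            report.rows.append((c.contig_id, reason))
        else:
            out.append(c)
    return out, report


def passing(contigs: Iterable[Contig]) -> list[Contig]:
    return [c for c in contigs if c.qc_status is QcStatus.PASS]


def write_pass_fasta(contigs: Iterable[Contig], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for c in contigs:
            if c.qc_status is QcStatus.PASS:
                fh.write(f">{c.contig_id}\n{c.sequence}\n")
                n += 1
    return n
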