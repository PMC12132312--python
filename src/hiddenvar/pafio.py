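"""Reading and writing pairwise alignments in the 12-column PAF dialect.

All coordinates are 0-based half-open, as in the format itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment (PAF row)."""

    query_id: str
    query_len: int
    qstart: int
    qend: int
    strand: str
    target_id: str
    target_len: int
    tstart: int
    tend: int
    n_match: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.query_len):
            raise ValueError(
                f"bad query interval [{self.qstart},{self.qend}) for "
                f"{self.query_id} (len {self.query_len})"
            )
        if not (0 <= self.tstart < self.tend <= self.target_len):
            raise ValueError(
                f"bad target interval [{self.tstart},{self.tend}) for "
                f"{self.target_id} (len {self.target_len})"
            )
        if self.n_match > self.block_len:
            raise ValueError("n_match exceeds block_len")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def identity(self) -> float:
        """Residue matches over block length (gap-compressed identity not used)."""
        return self.n_match / self.block_len

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.query_id, self.query_len, self.qstart, self.qend,
                self.strand,
                self.target_id, self.target_len, self.tstart, self.tend,
                self.n_match, self.block_len, self.mapq,
            )
        )


def parse_paf_line(line: str) -> AlignmentRecord:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"PAF line has {len(f)} columns, expected >= 12")
    return AlignmentRecord(
        query_id=f[0], query_len=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
        strand=f[4],
        target_id=f[5], target_len=int(f[6]), tstart=int(f[7]), tend=int(f[8]),
        n_match=int(f[9]), block_len=int(f[10]), mapq=int(f[11]),
    )


def read_paf(path: str | Path) -> Iterator[AlignmentRecord]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield parse_paf_line(line)


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
            n += 1
    return n
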