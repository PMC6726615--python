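"""Effective sequence counts from multiple sequence alignments.

Neff is the number of clusters at 62% sequence identity; Nf uses an 80%
threshold and may optionally be normalized by the square root of the
alignment length. Clustering is a transparent greedy leader algorithm over
full pairwise identities (rows in input order; a row joins the first cluster
whose leader it matches at or above the threshold). Identity is matches
divided by columns where at least one row is non-gap; columns gapped in both
rows are ignored (this denominator differs from CD-HIT's ungapped-sequence
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

GAP = "-"


@dataclass
class MSA:
    rows: list
    target_index: int = 0
    names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows must have equal length")
        if not self.names:
            self.names = [f"seq{i}" for i in range(len(self.rows))]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where at least one row is
    non-gap. Returns 0.0 when no such column exists."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    matches = 0
    columns = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        columns += 1
        if x == y:
            matches += 1
    return matches / columns if columns else 0.0


def _leader_clusters(msa: MSA, threshold: float) -> list[list[int]]:
    clusters: list[list[int]] = []
    leaders: list[str] = []
    for idx, row in enumerate(msa.rows):
        for ci, leader in enumerate(leaders):
            if pairwise_identity(row, leader) >= threshold:
                clusters[ci].append(idx)
                break
        else:
            clusters.append([idx])
            leaders.append(row)
    return clusters


def neff(msa: MSA, threshold: float = 0.62) -> int:
    """Effective sequence count: greedy leader cluster count at 62% identity."""
    return len(_leader_clusters(msa, threshold))


def nf(msa: MSA, threshold: float = 0.80,
       normalize_by_sqrt_length: bool = False) -> float:
    """Cluster count at 80% identity, optionally divided by sqrt(alignment
    length)."""
    count = len(_leader_clusters(msa, threshold))
    if normalize_by_sqrt_length:
        return count / math.sqrt(msa.width)
    return float(count)


# ---------------------------------------------------------------------------
# Reading alignments
# ---------------------------------------------------------------------------

def read_fasta_msa(text: str) -> MSA:
    """Aligned FASTA (equal-length rows, '-' gaps)."""
    names, rows = _parse_fasta(text)
    return MSA(rows, names=names)


def read_a3m(text: str) -> MSA:
    """A3M: lower-case insert-state columns are dropped on read, leaving a
    flush alignment in match columns."""
    names, rows = _parse_fasta(text)
    rows = ["".join(ch for ch in row if not ch.islower()) for row in rows]
    return MSA(rows, names=names)


def _parse_fasta(text: str):
    names, rows, cur = [], [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ";")):
            continue
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            names.append(line[1:].split()[0] if len(line) > 1 else "")
        else:
            cur.append(line)
    if cur:
        rows.append("".join(cur))
    if not rows:
        raise ValueError("no sequences found")
    return names, rows


def write_fasta_msa(msa: MSA) -> str:
    return "".join(f">{n}\n{r}\n" for n, r in zip(msa.names, msa.rows))
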