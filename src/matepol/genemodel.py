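"""Stranded gene models and GFF3 / FASTA input.

Coordinates are 1-based inclusive in GFF3 files and 0-based half-open
internally; all intervals are stored sorted by genomic (plus-strand)
coordinate, and coding-strand order is recovered from the strand on demand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio.Seq import Seq

__all__ = [
    "Role",
    "GeneModel",
    "read_gff3",
    "fetch",
    "extract_cds",
    "translate_cds",
    "reverse_complement_annotation",
]

Interval = tuple[int, int]  # 0-based half-open


class Role(enum.Enum):
    """Functional tag of a gene at (or near) a mating locus."""

    BETA_FG = "beta-fg"
    HD1 = "HD1"
    HD2 = "HD2"
    MIP = "MIP"
    PR = "PR"
    PP = "PP"
    OTHER = "other"

    @classmethod
    def from_label(cls, text: str | None) -> "Role":
        if not text:
            return cls.OTHER
        t = text.strip().upper().replace("_", "-")
        if t in ("BETA-FG", "B-FG", "Β-FG", "BFG"):
            return cls.BETA_FG
        if t.startswith("HD1"):
            return cls.HD1
        if t.startswith("HD2"):
            return cls.HD2
        if t.startswith("MIP"):
            return cls.MIP
        if t.startswith("PR"):
            return cls.PR
        if t.startswith("PP"):
            return cls.PP
        return cls.OTHER


def _merge_sorted(intervals: list[Interval]) -> list[Interval]:
    return sorted((int(s), int(e)) for s, e in intervals)


@dataclass
class GeneModel:
    """One gene: exon/CDS structure on a named sequence.

    ``exons`` and ``cds`` are 0-based half-open intervals sorted by genomic
    coordinate regardless of strand.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    role_label: Role = Role.OTHER

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = _merge_sorted(self.exons)
        self.cds = _merge_sorted(self.cds)
        for ivs in (self.exons, self.cds):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 > s2:
                    raise ValueError(f"overlapping intervals in gene {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")

    # -- genomic extent ---------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    # -- UTRs (strand-aware) ----------------------------------------------
    def _utr_intervals(self) -> tuple[list[Interval], list[Interval]]:
        """(left-of-CDS, right-of-CDS) exonic intervals in genomic order."""
        if not self.cds:
            return [], []
        cs, ce = self.cds[0][0], self.cds[-1][1]
        left: list[Interval] = []
        right: list[Interval] = []
        for s, e in self.exons:
            if s < cs:
                left.append((s, min(e, cs)))
            if e > ce:
                right.append((max(s, ce), e))
        return left, right

    def utr5(self) -> list[Interval]:
        left, right = self._utr_intervals()
        return left if self.strand == "+" else right

    def utr3(self) -> list[Interval]:
        left, right = self._utr_intervals()
        return right if self.strand == "+" else left

    # -- coding-strand coordinate mapping ----------------------------------
    def cds_genomic_positions(self) -> list[int]:
        """Genomic (0-based) position of each CDS base in coding order."""
        pos = [p for s, e in self.cds for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]


def fetch(genome, seq_id: str, start: int, end: int) -> str:
    """Subsequence [start, end) (0-based) from a dict of strings or a
    pyfaidx.Fasta-like mapping."""
    seq = genome[seq_id]
    return str(seq[start:end]).upper()


def extract_cds(gene: GeneModel, genome) -> str:
    """Spliced CDS on the coding strand."""
    parts = [fetch(genome, gene.seq_id, s, e) for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def spliced_sequence(gene: GeneModel, genome, intervals: list[Interval]) -> str:
    """Spliced sequence of arbitrary exonic intervals on the coding strand."""
    seq = "".join(fetch(genome, gene.seq_id, s, e) for s, e in sorted(intervals))
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_cds(cds_seq: str) -> str:
    """Standard-code translation including the terminal '*' if present."""
    return str(Seq(cds_seq).translate())


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3 file.

    Role labels are taken from a ``role=`` attribute on the gene feature
    (falling back to ``Name=``).  Exons and CDS are collected from all
    mRNA children; one transcript per gene is assumed.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(g, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(g, featuretype="CDS", order_by="start")
        ]
        role_txt = (g.attributes.get("role") or g.attributes.get("Name") or [None])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                seq_id=g.seqid,
                strand=g.strand,
                exons=exons,
                cds=cds,
                role_label=Role.from_label(role_txt),
            )
        )
    return genes


def reverse_complement_annotation(
    genes: list[GeneModel], seq_lengths: dict[str, int]
) -> list[GeneModel]:
    """Remap gene models onto the reverse-complemented replicons.

    Every interval (s, e) on a replicon of length L becomes (L-e, L-s) and
    strands flip; used to check that locus finding is orientation-free.
    """
    out = []
    for g in genes:
        L = seq_lengths[g.seq_id]
        flip = lambda iv: (L - iv[1], L - iv[0])
        out.append(
            GeneModel(
                gene_id=g.gene_id,
                seq_id=g.seq_id,
                strand="-" if g.strand == "+" else "+",
                exons=[flip(iv) for iv in g.exons],
                cds=[flip(iv) for iv in g.cds],
                role_label=g.role_label,
            )
        )
    return out
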