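"""SNP/indel consequence annotation and mating-type allele sharing.

Classifies variants against stranded gene models (frameshift, stop-codon
insertion, synonymous/nonsynonymous, splice, UTR, ...) and aggregates
per-group effect profiles at the mating-determinant genes to decide which
mating-type allele a reference strain shares with each resequenced strain
group — the logic by which a reference monokaryon's A and B alleles are
read off from where protein-breaking variation is, and is not, found.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genemodel import GeneModel, extract_cds, fetch
from .types import MatingType

__all__ = [
    "EffectCategory",
    "IMPACTFUL_PAPER",
    "IMPACTFUL_STRICT",
    "Variant",
    "Windows",
    "EffectAnnotation",
    "annotate_variant",
    "normalize_variant",
    "read_vcf",
    "group_effect_profile",
    "AlleleSharingCall",
    "ReferenceTypeCall",
    "assign_reference_type",
]

_DNA = set("ACGT")


class EffectCategory(enum.Enum):
    SYNONYMOUS_CODING = "synonymous_coding"
    NONSYNONYMOUS_CODING = "nonsynonymous_coding"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_GAINED = "start_gained"
    SPLICE_SITE = "splice_site"
    FRAME_SHIFT = "frame_shift"
    CODON_DELETION = "codon_deletion"
    CODON_INSERTION = "codon_insertion"
    STOP_CODON_INSERTION = "stop_codon_insertion"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRON = "intron"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


#: "Nonsynonymous" in the broad sense used for allele-sharing decisions:
#: protein-altering plus splice and UTR variants.
IMPACTFUL_PAPER = frozenset(
    {
        EffectCategory.NONSYNONYMOUS_CODING,
        EffectCategory.STOP_GAINED,
        EffectCategory.STOP_LOST,
        EffectCategory.START_GAINED,
        EffectCategory.SPLICE_SITE,
        EffectCategory.FRAME_SHIFT,
        EffectCategory.CODON_DELETION,
        EffectCategory.CODON_INSERTION,
        EffectCategory.STOP_CODON_INSERTION,
        EffectCategory.UTR5,
        EffectCategory.UTR3,
    }
)

#: Strict alternative: only variants that change the encoded protein or its
#: splicing count as impactful.
IMPACTFUL_STRICT = frozenset(
    {
        EffectCategory.NONSYNONYMOUS_CODING,
        EffectCategory.STOP_GAINED,
        EffectCategory.STOP_LOST,
        EffectCategory.SPLICE_SITE,
        EffectCategory.FRAME_SHIFT,
        EffectCategory.CODON_DELETION,
        EffectCategory.CODON_INSERTION,
        EffectCategory.STOP_CODON_INSERTION,
    }
)


@dataclass(frozen=True)
class Variant:
    """One biallelic variant, VCF-style: 1-based ``pos``, explicit alleles."""

    seq_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not self.ref or not self.alt:
            raise ValueError("empty allele; use anchor-base representation")
        bad = (set(self.ref.upper()) | set(self.alt.upper())) - _DNA
        if bad:
            raise ValueError(f"non-ACGT characters in alleles: {sorted(bad)}")

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNP" if len(self.ref) == 1 else "MNP"
        return "INSERTION" if len(self.alt) > len(self.ref) else "DELETION"


@dataclass(frozen=True)
class Windows:
    """Annotation windows in bp: gene-flank extents and splice-region depth."""

    upstream_bp: int = 1000
    downstream_bp: int = 1000
    splice_bp: int = 2


@dataclass(frozen=True)
class EffectAnnotation:
    variant: Variant
    gene_id: str
    category: EffectCategory
    impactful: bool


def _overlaps(iv: tuple[int, int], feats: Iterable[tuple[int, int]]) -> bool:
    s0, e0 = iv
    if s0 == e0:  # insertion point between bases s0-1 and s0
        return any(s < s0 < e for s, e in feats)
    return any(max(s, s0) < min(e, e0) for s, e in feats)


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


def normalize_variant(v: Variant, genome) -> Variant:
    """Left-align and parsimony-trim an indel (SNPs pass through).

    Repeatedly strips a shared trailing base and, when an allele would
    empty, extends both alleles one reference base to the left — the
    standard left-normalisation used by variant callers.
    """
    pos0, ref, alt = v.pos - 1, v.ref.upper(), v.alt.upper()
    # trim shared suffix / extend left
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos0 == 0:
                    raise ValueError("cannot left-extend past the sequence start")
                pos0 -= 1
                b = fetch(genome, v.seq_id, pos0, pos0 + 1)
                ref, alt = b + ref, b + alt
        else:
            break
    # trim shared prefix (keep the anchor base of indels)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return Variant(v.seq_id, pos0 + 1, ref, alt)


def annotate_variant(
    v: Variant,
    gene: GeneModel,
    genome,
    windows: Windows = Windows(),
    convention: str = "paper",
) -> EffectAnnotation:
    """Classify one variant's consequence on one gene.

    The affected region is resolved in priority order splice > CDS > UTR >
    intron > upstream > downstream > intergenic; within the CDS, indels are
    frameshifts unless their net length is a multiple of 3 (then whole-codon
    insertion/deletion, with stop-codon insertion recognised in frame), and
    SNPs are classified by translating the affected codon on the coding
    strand.  A SNP or indel in the 5' leader that creates a new upstream ATG
    is reported as a start gain.

    ``convention`` selects which categories count as impactful: ``"paper"``
    (protein-altering + splice + UTR) or ``"strict"`` (protein-altering +
    splice only).
    """
    if v.seq_id != gene.seq_id:
        raise ValueError(
            f"variant on {v.seq_id} cannot be annotated against gene "
            f"{gene.gene_id} on {gene.seq_id}"
        )
    pos0 = v.pos - 1
    ref, alt = v.ref.upper(), v.alt.upper()
    observed = fetch(genome, v.seq_id, pos0, pos0 + len(ref))
    if observed != ref:
        raise ValueError(
            f"reference mismatch at {v.seq_id}:{v.pos}: VCF says {ref!r}, "
            f"genome has {observed!r}"
        )

    # strip the shared prefix (anchor base of indels)
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    del_iv = (pos0 + k, pos0 + len(ref))  # deleted reference bases (may be empty)
    ins_seq = alt[k:]  # inserted bases (may be empty)
    if del_iv[0] == del_iv[1] and not ins_seq:  # pure SNP/MNP: k stops at mismatch
        pass
    aff = del_iv if del_iv[1] > del_iv[0] else (pos0 + k, pos0 + k)
    if len(ref) == len(alt):  # substitution: affected bases, not a point
        aff = (pos0 + k, pos0 + len(ref))

    category = _resolve_category(v, gene, genome, windows, aff, del_iv, ins_seq)
    impactful_set = IMPACTFUL_PAPER if convention == "paper" else IMPACTFUL_STRICT
    return EffectAnnotation(
        variant=v,
        gene_id=gene.gene_id,
        category=category,
        impactful=category in impactful_set,
    )


def _resolve_category(
    v: Variant,
    gene: GeneModel,
    genome,
    windows: Windows,
    aff: tuple[int, int],
    del_iv: tuple[int, int],
    ins_seq: str,
) -> EffectCategory:
    sb = windows.splice_bp
    splice = [
        iv
        for s, e in gene.introns()
        if e - s > 2 * sb
        for iv in ((s, s + sb), (e - sb, e))
    ]
    if _overlaps(aff, splice):
        return EffectCategory.SPLICE_SITE
    if _overlaps(aff, gene.cds):
        return _cds_category(v, gene, genome, aff, del_iv, ins_seq)
    if _overlaps(aff, gene.utr5()):
        return _leader_category(v, gene, genome, del_iv, ins_seq)
    if _overlaps(aff, gene.utr3()):
        return EffectCategory.UTR3
    if _overlaps(aff, gene.introns()):
        return EffectCategory.INTRON
    if gene.strand == "+":
        upstream = [(max(0, gene.start - windows.upstream_bp), gene.start)]
        downstream = [(gene.end, gene.end + windows.downstream_bp)]
    else:
        upstream = [(gene.end, gene.end + windows.upstream_bp)]
        downstream = [(max(0, gene.start - windows.downstream_bp), gene.start)]
    if _overlaps(aff, upstream):
        return EffectCategory.UPSTREAM
    if _overlaps(aff, downstream):
        return EffectCategory.DOWNSTREAM
    return EffectCategory.INTERGENIC


def _cds_category(
    v: Variant,
    gene: GeneModel,
    genome,
    aff: tuple[int, int],
    del_iv: tuple[int, int],
    ins_seq: str,
) -> EffectCategory:
    net = len(ins_seq) - (del_iv[1] - del_iv[0])
    cds_seq = extract_cds(gene, genome)
    positions = gene.cds_genomic_positions()
    index_of = {g: i for i, g in enumerate(positions)}

    if len(v.ref) != len(v.alt):  # indel
        if net % 3 != 0:
            return EffectCategory.FRAME_SHIFT
        if net > 0:
            j = aff[0]  # insertion point: between genomic j-1 and j
            anchor = j if gene.strand == "+" else j - 1
            if anchor not in index_of:
                return EffectCategory.CODON_INSERTION
            i = index_of[anchor]
            coding_ins = (
                ins_seq
                if gene.strand == "+"
                else str(Seq(ins_seq).reverse_complement())
            )
            phase = i % 3
            mut = cds_seq[i - phase : i] + coding_ins + cds_seq[i : i + (3 - phase) + 3]
            ref_win = cds_seq[i - phase : i + (3 - phase) + 3]
            mut_aa = str(Seq(mut[: len(mut) - len(mut) % 3]).translate())
            ref_aa = str(Seq(ref_win[: len(ref_win) - len(ref_win) % 3]).translate())
            if "*" in mut_aa and "*" not in ref_aa:
                return EffectCategory.STOP_CODON_INSERTION
            return EffectCategory.CODON_INSERTION
        return EffectCategory.CODON_DELETION

    # substitution: rebuild the affected codon(s) on the coding strand
    edits: dict[int, str] = {}
    for off in range(len(v.ref)):
        g = v.pos - 1 + off
        if g not in index_of or v.ref[off] == v.alt[off]:
            continue
        base = v.alt[off].upper()
        edits[index_of[g]] = base if gene.strand == "+" else _complement(base)
    if not edits:
        return EffectCategory.SYNONYMOUS_CODING
    first, last = min(edits), max(edits)
    c0, c1 = first // 3, last // 3
    ref_codons = cds_seq[3 * c0 : 3 * c1 + 3]
    mut_codons = list(ref_codons)
    for i, b in edits.items():
        mut_codons[i - 3 * c0] = b
    ref_aa = str(Seq(ref_codons).translate())
    mut_aa = str(Seq("".join(mut_codons)).translate())
    if mut_aa == ref_aa:
        return EffectCategory.SYNONYMOUS_CODING
    if "*" in mut_aa and "*" not in ref_aa:
        return EffectCategory.STOP_GAINED
    if "*" in ref_aa and "*" not in mut_aa:
        return EffectCategory.STOP_LOST
    return EffectCategory.NONSYNONYMOUS_CODING


def _leader_category(
    v: Variant,
    gene: GeneModel,
    genome,
    del_iv: tuple[int, int],
    ins_seq: str,
) -> EffectCategory:
    """A 5'-leader variant is a start gain when it creates a new ATG."""
    ref_leader = _spliced_with_edit(gene, genome, gene.utr5(), None, None)
    mut_leader = _spliced_with_edit(gene, genome, gene.utr5(), del_iv, ins_seq)
    if mut_leader.count("ATG") > ref_leader.count("ATG"):
        return EffectCategory.START_GAINED
    return EffectCategory.UTR5


def _spliced_with_edit(
    gene: GeneModel,
    genome,
    intervals: list[tuple[int, int]],
    del_iv: tuple[int, int] | None,
    ins_seq: str | None,
) -> str:
    """Coding-strand spliced sequence of ``intervals`` with an optional edit
    (deletion interval and/or insertion, in plus-strand genomic space)."""
    parts: list[str] = []
    for s, e in sorted(intervals):
        seq = fetch(genome, gene.seq_id, s, e)
        if del_iv is not None:
            ds, de = max(del_iv[0], s), min(del_iv[1], e)
            if ds < de:
                seq = seq[: ds - s] + seq[de - s :]
                if ins_seq and del_iv[0] >= s:
                    seq = seq[: max(del_iv[0], s) - s] + ins_seq + seq[max(del_iv[0], s) - s :]
                    ins_seq = None
            elif ins_seq and del_iv[0] == del_iv[1] and s < del_iv[0] < e:
                j = del_iv[0] - s
                seq = seq[:j] + ins_seq + seq[j:]
                ins_seq = None
        parts.append(seq)
    out = "".join(parts)
    if gene.strand == "-":
        out = str(Seq(out).reverse_complement())
    return out


# ---------------------------------------------------------------------------
# group profiles and allele sharing


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a (sites-only or multi-sample) VCF, splitting multiallelic rows."""
    from cyvcf2 import VCF

    out: list[Variant] = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            out.append(Variant(rec.CHROM, rec.POS, rec.REF, alt))
    return out


def group_effect_profile(
    groups: Mapping[str, Sequence[Variant] | str | Path],
    genes: Sequence[GeneModel],
    genome,
    windows: Windows = Windows(),
    convention: str = "paper",
    dedupe: bool = True,
) -> pd.DataFrame:
    """Per-(group, gene) tallies of variant effects.

    Returns a DataFrame indexed by (group, gene) whose columns are one count
    per effect category plus ``impactful`` and ``neutral`` totals.  Counts
    are per unique variant site (``dedupe=True``); intergenic annotations
    are not counted.  Empty variant sets yield zero-filled rows.
    """
    rows: list[tuple[str, str, EffectCategory, bool]] = []
    for group, variants in groups.items():
        if isinstance(variants, (str, Path)):
            variants = read_vcf(variants)
        seen: set[tuple] = set()
        for v in variants:
            key = (v.seq_id, v.pos, v.ref.upper(), v.alt.upper())
            if dedupe and key in seen:
                continue
            seen.add(key)
            for gene in genes:
                if gene.seq_id != v.seq_id:
                    continue
                ann = annotate_variant(v, gene, genome, windows, convention)
                if ann.category is EffectCategory.INTERGENIC:
                    continue
                rows.append((group, gene.gene_id, ann.category, ann.impactful))

    index = pd.MultiIndex.from_product(
        [list(groups), [g.gene_id for g in genes]], names=["group", "gene"]
    )
    cats = [c.name for c in EffectCategory if c is not EffectCategory.INTERGENIC]
    table = pd.DataFrame(0, index=index, columns=cats + ["impactful", "neutral"])
    for group, gene_id, cat, impactful in rows:
        table.loc[(group, gene_id), cat.name] += 1
        table.loc[(group, gene_id), "impactful" if impactful else "neutral"] += 1
    return table


@dataclass(frozen=True)
class AlleleSharingCall:
    """Which strain group the reference shares one locus's allele with."""

    locus: str
    impactful_counts: Mapping[str, int]
    shared_with: str  # group label, "AMBIGUOUS" or "INCONSISTENT"


@dataclass(frozen=True)
class ReferenceTypeCall:
    locus_a: AlleleSharingCall
    locus_b: AlleleSharingCall
    mating_type: MatingType | None


def assign_reference_type(
    profile: pd.DataFrame,
    group_types: Mapping[str, MatingType],
    locus_a_genes: Sequence[str] = ("HD2",),
    locus_b_genes: Sequence[str] = ("PR1", "PR2"),
) -> ReferenceTypeCall:
    """Infer the reference strain's mating type from group effect profiles.

    At each locus the reference carries the allele of the group with zero
    impactful variants at that locus's determinant genes (the resequenced
    group matching the reference should show no protein-breaking differences
    there).  A locus is AMBIGUOUS when both groups are zero and INCONSISTENT
    when neither is; either voids the combined type.
    """
    if len(group_types) != 2:
        raise ValueError("exactly two strain groups are required")
    (g1, t1), (g2, t2) = group_types.items()
    a_diff, b_diff = t1.differs_at(t2)
    if not (a_diff and b_diff):
        raise ValueError(
            f"group types {t1} and {t2} must be fully opposite at both loci"
        )

    def call(locus: str, genes: Sequence[str]) -> AlleleSharingCall:
        counts = {
            g: int(profile.loc[(g, list(genes)), "impactful"].sum())
            for g in group_types
        }
        zero = [g for g, c in counts.items() if c == 0]
        if len(zero) == 1:
            shared = zero[0]
        elif len(zero) == 2:
            shared = "AMBIGUOUS"
        else:
            shared = "INCONSISTENT"
        return AlleleSharingCall(locus=locus, impactful_counts=counts, shared_with=shared)

    call_a = call("A", locus_a_genes)
    call_b = call("B", locus_b_genes)
    if call_a.shared_with in group_types and call_b.shared_with in group_types:
        mt = MatingType(
            group_types[call_a.shared_with].a_allele,
            group_types[call_b.shared_with].b_allele,
        )
    else:
        mt = None
    return ReferenceTypeCall(locus_a=call_a, locus_b=call_b, mating_type=mt)
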