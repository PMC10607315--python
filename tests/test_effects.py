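"""Variant-effect annotation: region dispatch, coding consequences, the
full-CDS-translation oracle, and the allele-sharing mating-type call."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from matepol.effects import (
    EffectCategory,
    Variant,
    Windows,
    annotate_variant,
    assign_reference_type,
    group_effect_profile,
    normalize_variant,
    read_vcf,
)
from matepol.genemodel import GeneModel, Role
from matepol.types import MatingType

C = EffectCategory


# ---------------------------------------------------------------------------
# independent oracle: apply the edit to the chromosome, re-extract the CDS
# with shifted coordinates, translate both proteins whole, and classify


def _cds_plus(genome, seq_id, cds):
    return "".join(genome[seq_id][s:e] for s, e in cds)


def _oracle_category(gene: GeneModel, genome, v: Variant) -> EffectCategory:
    chrom = genome[gene.seq_id]
    pos0 = v.pos - 1
    mutant_chrom = chrom[:pos0] + v.alt + chrom[pos0 + len(v.ref) :]
    shift = len(v.alt) - len(v.ref)
    edit_end = pos0 + len(v.ref)
    new_cds = [
        (s + shift if s >= edit_end else s, e + shift if e >= edit_end else e)
        for s, e in gene.cds
    ]
    ref_seq = _cds_plus(genome, gene.seq_id, gene.cds)
    mut_seq = "".join(mutant_chrom[s:e] for s, e in new_cds)
    if gene.strand == "-":
        ref_seq = str(Seq(ref_seq).reverse_complement())
        mut_seq = str(Seq(mut_seq).reverse_complement())
    if len(mut_seq) % 3 != 0:
        return C.FRAME_SHIFT
    ref_aa = str(Seq(ref_seq).translate())
    mut_aa = str(Seq(mut_seq).translate())
    if len(mut_seq) > len(ref_seq):
        if "*" in mut_aa[:-1] and "*" not in ref_aa[:-1]:
            return C.STOP_CODON_INSERTION
        return C.CODON_INSERTION
    if len(mut_seq) < len(ref_seq):
        return C.CODON_DELETION
    if mut_aa == ref_aa:
        return C.SYNONYMOUS_CODING
    diffs = [(r, m) for r, m in zip(ref_aa, mut_aa) if r != m]
    if any(m == "*" for _, m in diffs):
        return C.STOP_GAINED
    if any(r == "*" for r, _ in diffs):
        return C.STOP_LOST
    return C.NONSYNONYMOUS_CODING


# ---------------------------------------------------------------------------
# a hand-built micro-gene whose codons are known exactly


@pytest.fixture
def micro():
    pad = "TTTTTTTTTT"
    utr5 = "CATTTC"
    cds1 = "ATGGCTTAC"  # M A Y
    intron = "GTAAAGCAG"
    cds2 = "GATTGGTAA"  # D W *
    utr3 = "CCTCCA"
    chrom = pad + utr5 + cds1 + intron + cds2 + utr3 + pad
    gene = GeneModel(
        "g1",
        "t",
        "+",
        exons=[(10, 25), (34, 49)],
        cds=[(16, 25), (34, 43)],
        role_label=Role.OTHER,
    )
    return gene, {"t": chrom}


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (22, "T", "C", C.SYNONYMOUS_CODING),  # GCT -> GCC, both Ala
        (25, "C", "A", C.STOP_GAINED),  # TAC -> TAA
        (42, "A", "C", C.STOP_LOST),  # TAA -> TCA
        (24, "A", "T", C.NONSYNONYMOUS_CODING),  # TAC -> TTC, Tyr -> Phe
        (20, "G", "GA", C.FRAME_SHIFT),  # 1-bp insertion inside CDS
        (19, "GGCT", "G", C.CODON_DELETION),  # in-frame 3-bp deletion
        (27, "T", "C", C.SPLICE_SITE),  # 2nd intron base
        (30, "A", "C", C.INTRON),
        (13, "T", "G", C.UTR5),
        (14, "T", "G", C.START_GAINED),  # CATTTC -> CATGTC creates ATG
        (47, "C", "G", C.UTR3),
        (6, "T", "A", C.UPSTREAM),
        (52, "T", "A", C.DOWNSTREAM),
    ],
)
def test_micro_gene_categories(micro, pos, ref, alt, expected):
    gene, genome = micro
    ann = annotate_variant(Variant("t", pos, ref, alt), gene, genome)
    assert ann.category is expected


def test_micro_gene_oracle_agreement_on_cds_variants(micro):
    gene, genome = micro
    for pos, ref, alt in [
        (22, "T", "C"), (25, "C", "A"), (42, "A", "C"), (24, "A", "T"),
        (20, "G", "GA"), (19, "GGCT", "G"),
    ]:
        v = Variant("t", pos, ref, alt)
        assert annotate_variant(v, gene, genome).category is _oracle_category(gene, genome, v)


def test_impactful_flag_follows_convention(micro):
    gene, genome = micro
    utr = annotate_variant(Variant("t", 13, "T", "G"), gene, genome)
    assert utr.category is C.UTR5 and utr.impactful  # broad convention
    strict = annotate_variant(Variant("t", 13, "T", "G"), gene, genome, convention="strict")
    assert not strict.impactful
    syn = annotate_variant(Variant("t", 22, "T", "C"), gene, genome)
    assert not syn.impactful


def test_reference_mismatch_and_wrong_replicon_raise(micro):
    gene, genome = micro
    with pytest.raises(ValueError, match="reference mismatch"):
        annotate_variant(Variant("t", 22, "A", "C"), gene, genome)
    with pytest.raises(ValueError, match="cannot be annotated"):
        annotate_variant(Variant("other", 22, "T", "C"), gene, genome)


def test_far_variant_is_intergenic(micro):
    gene, genome = micro
    ann = annotate_variant(
        Variant("t", 2, "T", "A"), gene, genome, Windows(upstream_bp=5, downstream_bp=5)
    )
    assert ann.category is C.INTERGENIC and not ann.impactful


# ---------------------------------------------------------------------------
# toy-genome fixtures: planted intent, oracle equivalence, strand handling


def test_planted_variants_annotate_as_planted(toy):
    by_id = {g.gene_id: g for g in toy.genes}
    for group, entries in toy.planted.items():
        for d in entries:
            v = Variant(d["seq_id"], d["pos"], d["ref"], d["alt"])
            ann = annotate_variant(v, by_id[d["gene"]], toy.genome)
            assert ann.category.name == d["category"], (group, d)


def _random_cds_variants(gene, genome, rng, n):
    chrom = genome[gene.seq_id]
    positions = gene.cds_genomic_positions()
    out = []
    while len(out) < n:
        kind = rng.choice(["snp", "ins", "del"])
        if kind == "snp":
            i = int(rng.integers(0, len(positions)))
            g = positions[i]
            ref = chrom[g]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            out.append(Variant(gene.seq_id, g + 1, ref, alt))
            continue
        L = int(rng.integers(1, 4))
        i = int(rng.integers(9, len(positions) - 9 - L))
        step = -1 if gene.strand == "-" else 1
        if any(positions[i + k] != positions[i] + step * k for k in range(L)):
            continue  # spans an exon boundary
        if kind == "ins":
            if abs(positions[i] - positions[i - 1]) != 1:
                continue  # insertion point must sit strictly inside an exon
            ins = "".join(rng.choice(list("ACGT"), size=L))
            if gene.strand == "+":
                anchor = positions[i] - 1
                ins_plus = ins
            else:
                anchor = positions[i]
                ins_plus = str(Seq(ins).reverse_complement())
            ref = chrom[anchor]
            out.append(Variant(gene.seq_id, anchor + 1, ref, ref + ins_plus))
        else:
            gs = min(positions[i], positions[i + L - 1])
            anchor = gs - 1
            ref = chrom[anchor : gs + L]
            out.append(Variant(gene.seq_id, anchor + 1, ref, ref[0]))
    return out


def test_fast_path_equals_full_translation_oracle(toy):
    # hundreds of random coding variants over every gene, both strands
    rng = np.random.default_rng(2024)
    n_checked = 0
    by_strand = {"+": 0, "-": 0}
    for gene in toy.genes:
        for v in _random_cds_variants(gene, toy.genome, rng, 30):
            fast = annotate_variant(v, gene, toy.genome).category
            assert fast is _oracle_category(gene, toy.genome, v), (gene.gene_id, v)
            n_checked += 1
            by_strand[gene.strand] += 1
    # plus the planted coding variants
    by_id = {g.gene_id: g for g in toy.genes}
    coding = {
        "SYNONYMOUS_CODING", "NONSYNONYMOUS_CODING", "STOP_GAINED", "STOP_LOST",
        "FRAME_SHIFT", "CODON_DELETION", "CODON_INSERTION", "STOP_CODON_INSERTION",
    }
    for entries in toy.planted.values():
        for d in entries:
            if d["category"] not in coding:
                continue
            v = Variant(d["seq_id"], d["pos"], d["ref"], d["alt"])
            gene = by_id[d["gene"]]
            assert annotate_variant(v, gene, toy.genome).category is _oracle_category(
                gene, toy.genome, v
            )
            n_checked += 1
    assert n_checked >= 400
    assert by_strand["+"] > 0 and by_strand["-"] > 0


def test_strand_invariance_of_annotation(toy):
    # annotating against the reverse-complemented genome with flipped models
    # gives the same category for every planted variant
    from matepol.genemodel import reverse_complement_annotation

    lengths = {c: len(s) for c, s in toy.genome.items()}
    rc_genome = {c: str(Seq(s).reverse_complement()) for c, s in toy.genome.items()}
    rc_genes = {
        g.gene_id: g
        for g in reverse_complement_annotation(toy.genes, lengths)
    }
    by_id = {g.gene_id: g for g in toy.genes}
    for entries in toy.planted.values():
        for d in entries:
            v = Variant(d["seq_id"], d["pos"], d["ref"], d["alt"])
            L = lengths[v.seq_id]
            # remap the edited interval onto the reverse complement
            rc_ref = str(Seq(v.ref).reverse_complement())
            rc_alt = str(Seq(v.alt).reverse_complement())
            rc_pos = L - (v.pos - 1 + len(v.ref)) + 1
            rv = normalize_variant(Variant(v.seq_id, rc_pos, rc_ref, rc_alt), rc_genome)
            a1 = annotate_variant(v, by_id[d["gene"]], toy.genome).category
            a2 = annotate_variant(rv, rc_genes[d["gene"]], rc_genome).category
            assert a1 is a2, (d, rv)


def test_left_normalization_never_changes_coding_category(toy):
    # build deliberately right-shifted representations inside homopolymer
    # runs of CDS interiors and check the category is stable
    rng = np.random.default_rng(7)
    checked = 0
    for gene in toy.genes:
        chrom = toy.genome[gene.seq_id]
        for s, e in gene.cds:
            for g in range(s + 6, e - 6):
                if chrom[g] == chrom[g - 1] and checked < 40:
                    dup = Variant(gene.seq_id, g + 1, chrom[g], chrom[g] + chrom[g])
                    norm = normalize_variant(dup, toy.genome)
                    a1 = annotate_variant(dup, gene, toy.genome).category
                    a2 = annotate_variant(norm, gene, toy.genome).category
                    assert a1 is a2 is C.FRAME_SHIFT
                    checked += 1
    assert checked >= 20


def test_normalize_variant_left_aligns_duplication(toy):
    gene = toy.genes[0]
    chrom = toy.genome[gene.seq_id]
    s, e = gene.cds[0]
    g = next(g for g in range(s + 6, e - 6) if chrom[g] == chrom[g - 1])
    dup = Variant(gene.seq_id, g + 1, chrom[g], chrom[g] * 2)
    norm = normalize_variant(dup, toy.genome)
    assert norm.pos < dup.pos
    assert len(norm.alt) - len(norm.ref) == 1


# ---------------------------------------------------------------------------
# group profiles and reference-type assignment


def test_group_profiles_from_vcfs(toy):
    profile = group_effect_profile(toy.vcfs, toy.genes, toy.genome)
    hd2 = profile.loc[("group_A2B2", "HD2")]
    assert hd2["FRAME_SHIFT"] == 7
    assert hd2["STOP_CODON_INSERTION"] == 1
    assert hd2["impactful"] == 8
    # neutral categories tallied separately
    assert hd2["neutral"] == hd2["SYNONYMOUS_CODING"] + hd2["INTRON"]
    # group 1 impactful confined to PR1/PR2; group 2 to HD2
    imp = profile["impactful"]
    assert set(imp.loc["group_A1B1"][imp.loc["group_A1B1"] > 0].index) == {"PR1", "PR2"}
    assert set(imp.loc["group_A2B2"][imp.loc["group_A2B2"] > 0].index) == {"HD2"}


def test_empty_variant_set_yields_zero_filled_profile(toy):
    profile = group_effect_profile({"empty": []}, toy.genes, toy.genome)
    assert (profile.to_numpy() == 0).all()
    assert ("empty", "HD2") in profile.index


def test_duplicate_sites_deduplicated(toy):
    d = toy.planted["group_A2B2"][0]
    v = Variant(d["seq_id"], d["pos"], d["ref"], d["alt"])
    profile = group_effect_profile({"g": [v, v, v]}, toy.genes, toy.genome)
    assert profile["impactful"].sum() == 1
    profile2 = group_effect_profile({"g": [v, v]}, toy.genes, toy.genome, dedupe=False)
    assert profile2["impactful"].sum() == 2


def _profile_from_counts(counts):
    # counts: {(group, gene): impactful}; determinant genes always present
    groups = sorted({g for g, _ in counts} | {"g_a1b1", "g_a2b2"})
    genes = sorted({x for _, x in counts} | {"HD2", "PR1", "PR2"})
    idx = pd.MultiIndex.from_product([groups, genes], names=["group", "gene"])
    df = pd.DataFrame(0, index=idx, columns=["impactful", "neutral"])
    for key, n in counts.items():
        df.loc[key, "impactful"] = n
    return df


GROUPS = {
    "g_a1b1": MatingType("A1", "B1"),
    "g_a2b2": MatingType("A2", "B2"),
}


class TestAssignReferenceType:
    def test_reference_shares_a_with_group1_b_with_group2(self):
        profile = _profile_from_counts(
            {("g_a2b2", "HD2"): 8, ("g_a1b1", "PR1"): 5, ("g_a1b1", "PR2"): 4}
        )
        call = assign_reference_type(profile, GROUPS)
        assert call.locus_a.shared_with == "g_a1b1"
        assert call.locus_b.shared_with == "g_a2b2"
        assert call.mating_type == MatingType("A1", "B2")

    def test_symmetric_case_gives_parental_type(self):
        profile = _profile_from_counts(
            {("g_a2b2", "HD2"): 8, ("g_a2b2", "PR1"): 3, ("g_a2b2", "PR2"): 2}
        )
        call = assign_reference_type(profile, GROUPS)
        assert call.mating_type == MatingType("A1", "B1")

    def test_all_zero_is_ambiguous(self):
        profile = _profile_from_counts({("g_a1b1", "HD2"): 0})
        call = assign_reference_type(profile, GROUPS)
        assert call.locus_a.shared_with == "AMBIGUOUS"
        assert call.locus_b.shared_with == "AMBIGUOUS"
        assert call.mating_type is None

    def test_both_groups_nonzero_is_inconsistent(self):
        profile = _profile_from_counts(
            {("g_a1b1", "HD2"): 2, ("g_a2b2", "HD2"): 3, ("g_a1b1", "PR1"): 1}
        )
        call = assign_reference_type(profile, GROUPS)
        assert call.locus_a.shared_with == "INCONSISTENT"
        assert call.mating_type is None

    def test_non_opposite_groups_rejected(self):
        profile = _profile_from_counts({("x", "HD2"): 1})
        with pytest.raises(ValueError, match="opposite"):
            assign_reference_type(
                profile,
                {"x": MatingType("A1", "B1"), "y": MatingType("A2", "B1")},
            )

    def test_end_to_end_recovers_planted_reference_type(self, toy):
        profile = group_effect_profile(toy.vcfs, toy.genes, toy.genome)
        call = assign_reference_type(profile, toy.group_types)
        assert call.mating_type == toy.reference_type == MatingType("A1", "B2")


def test_vcf_reader_round_trips_planted_variants(toy):
    for group, path in toy.vcfs.items():
        variants = read_vcf(path)
        expected = {
            (d["seq_id"], d["pos"], d["ref"], d["alt"]) for d in toy.planted[group]
        }
        assert {(v.seq_id, v.pos, v.ref, v.alt) for v in variants} == expected
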