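"""Synthetic mating-locus genome fixture.

Builds a small (~60 kb) two-replicon genome whose architecture mirrors a
tetrapolar basidiomycete's mating loci: replicon ``chr1`` carries the HD
(A) locus — beta-fg, HD1, HD2, MIP in that order, with HD1/HD2 divergently
transcribed head-to-head and HD1 sharing MIP's coding direction — and
``chr11`` carries the PR (B) locus of six pheromone-receptor genes
interleaved with five short pheromone-precursor genes whose proteins end in
a C-terminal CAAX motif.  Two per-group VCFs plant variants whose effect
classes reproduce the allele-sharing pattern: the A2B2-like group breaks
only HD2 (seven frameshifts and one stop-codon insertion) and the A1B1-like
group breaks only PR1/PR2, so the reference sequence itself reads out as
A1B2.

Everything is derived from one integer seed; identical seeds give
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .effects import Variant
from .genemodel import GeneModel, Role, extract_cds
from .types import MatingType

__all__ = ["ToyGenomeFixture", "generate_toy_mating_genome"]

_STOPS = ("TAA", "TAG", "TGA")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# standard-code codons per amino acid (translation table 1)
_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _cod = _b1 + _b2 + _b3
            _aa = str(Seq(_cod).translate())
            _CODONS.setdefault(_aa, []).append(_cod)


@dataclass
class ToyGenomeFixture:
    """Paths and in-memory structures of one generated fixture."""

    root: Path
    genome_fasta: Path
    gff3: Path
    proteins_fasta: Path
    vcfs: dict[str, Path]
    manifest_path: Path
    genome: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str]
    group_types: dict[str, MatingType]
    reference_type: MatingType
    planted: dict[str, list[dict]]
    manifest: dict


# ---------------------------------------------------------------------------
# sequence construction


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    body = "".join(rng.choice(list(_AA20), size=n - 1))
    return "M" + body


def _pp_protein(rng: np.random.Generator, n: int, caax: str) -> str:
    """Short precursor: starts M, carries EA and AF, ends in a CAAX box."""
    assert n >= 12
    body = list(rng.choice(list(_AA20), size=n - 5))
    body[2:4] = ["E", "A"]
    body[6:8] = ["A", "F"]
    return "M" + "".join(body) + caax


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _build_cassette(
    rng: np.random.Generator,
    gene_id: str,
    protein: str,
    n_exons: int,
    strand: str,
    role: Role,
    utr5_len: int = 90,
    utr3_len: int = 70,
    intron_len: int = 60,
):
    """One gene as (sequence, relative GeneModel) on the cassette's plus
    strand; for minus-strand genes the cassette is reverse-complemented and
    intervals remapped."""
    cds_seq = _reverse_translate(rng, protein) + str(rng.choice(list(_STOPS)))
    utr5 = _rand_dna(rng, utr5_len)
    utr3 = _rand_dna(rng, utr3_len)
    transcript = utr5 + cds_seq + utr3
    cds_t = (utr5_len, utr5_len + len(cds_seq))  # transcript coords of CDS

    # exon cuts strictly inside the CDS, well away from its ends
    lo, hi = cds_t[0] + 20, cds_t[1] - 20
    while True:
        cuts = sorted(int(x) for x in rng.integers(lo, hi, size=n_exons - 1))
        if len(set(cuts)) == n_exons - 1 and all(
            b - a >= 30 for a, b in zip(cuts, cuts[1:])
        ):
            break
    bounds = [0] + cuts + [len(transcript)]

    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    g = 0
    for i, (t0, t1) in enumerate(zip(bounds, bounds[1:])):
        seq_parts.append(transcript[t0:t1])
        exons.append((g, g + (t1 - t0)))
        cs, ce = max(cds_t[0], t0), min(cds_t[1], t1)
        if cs < ce:
            cds.append((g + cs - t0, g + ce - t0))
        g += t1 - t0
        if i < len(bounds) - 2:
            seq_parts.append("GT" + _rand_dna(rng, intron_len - 4) + "AG")
            g += intron_len
    seq = "".join(seq_parts)

    if strand == "-":
        L = len(seq)
        seq = _revcomp(seq)
        exons = sorted((L - e, L - s) for s, e in exons)
        cds = sorted((L - e, L - s) for s, e in cds)

    model = GeneModel(
        gene_id=gene_id,
        seq_id="",  # filled on placement
        strand=strand,
        exons=exons,
        cds=cds,
        role_label=role,
    )
    return seq, model


def _place(
    rng: np.random.Generator,
    seq_id: str,
    cassettes: list[tuple[str, GeneModel]],
    flank: int = 4000,
    spacer: int = 2000,
) -> tuple[str, list[GeneModel]]:
    parts = [_rand_dna(rng, flank)]
    cursor = flank
    genes: list[GeneModel] = []
    for i, (seq, model) in enumerate(cassettes):
        genes.append(
            GeneModel(
                gene_id=model.gene_id,
                seq_id=seq_id,
                strand=model.strand,
                exons=[(s + cursor, e + cursor) for s, e in model.exons],
                cds=[(s + cursor, e + cursor) for s, e in model.cds],
                role_label=model.role_label,
            )
        )
        parts.append(seq)
        cursor += len(seq)
        gap = spacer if i < len(cassettes) - 1 else flank
        parts.append(_rand_dna(rng, gap))
        cursor += gap
    return "".join(parts), genes


# ---------------------------------------------------------------------------
# variant planting


class _Planter:
    """Plants variants with known effect classes into one strain group.

    Every planted indel is constructed already left-normalised (the base
    preceding the event differs from the event's trailing base), so
    normalisation is the identity on fixture variants.
    """

    def __init__(self, rng: np.random.Generator, genome: dict[str, str]):
        self.rng = rng
        self.genome = genome
        self.used: set[tuple[str, int]] = set()

    def _claim(self, seq_id: str, start: int, end: int) -> bool:
        span = {(seq_id, p) for p in range(start - 1, end + 1)}
        if span & self.used:
            return False
        self.used |= span
        return True

    def _base(self, seq_id: str, g: int) -> str:
        return self.genome[seq_id][g]

    # -- coding SNPs -------------------------------------------------------
    def _snp_at(self, gene: GeneModel, coding_i: int, new_coding: str) -> Variant:
        g = gene.cds_genomic_positions()[coding_i]
        ref = self._base(gene.seq_id, g)
        alt = new_coding if gene.strand == "+" else _revcomp(new_coding)
        return Variant(gene.seq_id, g + 1, ref, alt)

    def cds_snp(self, gene: GeneModel, want: str) -> Variant:
        """want in {synonymous, nonsynonymous, stop_gained, stop_lost}."""
        cds = extract_cds(gene, self.genome)
        n_codons = len(cds) // 3
        codon_order = list(self.rng.permutation(n_codons))
        for c in codon_order:
            codon = cds[3 * c : 3 * c + 3]
            aa = str(Seq(codon).translate())
            if want == "stop_lost":
                if aa != "*":
                    continue
            elif aa == "*" or c == 0:
                continue
            for off in self.rng.permutation(3):
                for nb in self.rng.permutation(list("ACGT")):
                    if nb == codon[off]:
                        continue
                    mut = codon[:off] + nb + codon[off + 1 :]
                    maa = str(Seq(mut).translate())
                    ok = (
                        (want == "synonymous" and maa == aa)
                        or (want == "nonsynonymous" and maa not in (aa, "*") and aa != "*")
                        or (want == "stop_gained" and maa == "*" and aa != "*" and c < n_codons - 1)
                        or (want == "stop_lost" and aa == "*" and maa != "*")
                    )
                    if not ok:
                        continue
                    i = 3 * c + off
                    g = gene.cds_genomic_positions()[i]
                    if self._claim(gene.seq_id, g, g + 1):
                        return self._snp_at(gene, i, nb)
        raise RuntimeError(f"no {want} SNP site found in {gene.gene_id}")

    # -- coding indels -----------------------------------------------------
    def _contiguous(self, positions: list[int], i: int, L: int) -> bool:
        step = 1 if len(positions) > 1 and positions[1] > positions[0] else -1
        return all(
            positions[i + k] == positions[i] + step * k for k in range(L)
        ) if i + L <= len(positions) else False

    def cds_insertion(self, gene: GeneModel, ins_coding: str) -> Variant:
        positions = gene.cds_genomic_positions()
        n = len(positions)
        for i in self.rng.permutation(range(9, n - 9)):
            if len(ins_coding) == 3 and i % 3 != 0:
                continue  # codon-aligned for in-frame insertions
            if abs(positions[i] - positions[i - 1]) != 1:
                continue  # exon boundary
            if gene.strand == "+":
                anchor = positions[i] - 1
                ins_plus = ins_coding
            else:
                anchor = positions[i]  # insert after the genomic base of coding i
                ins_plus = _revcomp(ins_coding)
            ref = self._base(gene.seq_id, anchor)
            if ins_plus[-1] == ref:
                continue  # keep it left-normalised
            if not self._claim(gene.seq_id, anchor, anchor + 1):
                continue
            return Variant(gene.seq_id, anchor + 1, ref, ref + ins_plus)
        raise RuntimeError(f"no insertion site in {gene.gene_id}")

    def cds_deletion(self, gene: GeneModel, length: int, codon_aligned: bool = False) -> Variant:
        positions = gene.cds_genomic_positions()
        n = len(positions)
        for i in self.rng.permutation(range(9, n - 9 - length)):
            if codon_aligned and i % 3 != 0:
                continue
            if not self._contiguous(positions, i, length):
                continue
            gs = min(positions[i], positions[i + length - 1])
            anchor = gs - 1
            ref = self.genome[gene.seq_id][anchor : gs + length]
            if ref[0] == ref[-1]:
                continue  # would left-shift
            if not self._claim(gene.seq_id, anchor, gs + length):
                continue
            return Variant(gene.seq_id, anchor + 1, ref, ref[0])
        raise RuntimeError(f"no deletion site in {gene.gene_id}")

    def frameshift(self, gene: GeneModel, length: int = 1) -> Variant:
        assert length % 3 != 0
        if bool(self.rng.integers(2)):
            ins = _rand_dna(self.rng, length)
            try:
                return self.cds_insertion(gene, ins)
            except RuntimeError:
                pass
        return self.cds_deletion(gene, length)

    def stop_codon_insertion(self, gene: GeneModel) -> Variant:
        for stop in _STOPS:
            try:
                return self.cds_insertion(gene, stop)
            except RuntimeError:
                continue
        raise RuntimeError(f"no stop-insertion site in {gene.gene_id}")

    # -- non-coding --------------------------------------------------------
    def splice_variant(self, gene: GeneModel, indel: bool) -> Variant:
        introns = gene.introns()
        idx = int(self.rng.integers(len(introns)))
        s, _ = introns[idx]
        # second intron base: donor 'T' of the GT dinucleotide
        if not self._claim(gene.seq_id, s, s + 2):
            s, _ = introns[(idx + 1) % len(introns)]
            if not self._claim(gene.seq_id, s, s + 2):
                raise RuntimeError("no free splice site")
        if indel:
            ref = self.genome[gene.seq_id][s : s + 2]  # "GT"
            return Variant(gene.seq_id, s + 1, ref, ref[0])
        base = self._base(gene.seq_id, s + 1)  # 'T'
        return Variant(gene.seq_id, s + 2, base, "C" if base != "C" else "A")

    def _leader_positions(self, gene: GeneModel) -> list[int]:
        pos = [p for s, e in gene.utr5() for p in range(s, e)]
        return pos if gene.strand == "+" else pos[::-1]

    def _leader_seq(self, gene: GeneModel, edits: dict[int, str]) -> str:
        """Coding-strand leader with per-genomic-position substitutions."""
        parts = []
        for s, e in gene.utr5():
            seq = list(self.genome[gene.seq_id][s:e])
            for g, b in edits.items():
                if s <= g < e:
                    seq[g - s] = b
            parts.append("".join(seq))
        out = "".join(parts)
        return out if gene.strand == "+" else _revcomp(out)

    def utr_snp(self, gene: GeneModel, which: str) -> Variant:
        ivs = gene.utr5() if which == "utr5" else gene.utr3()
        pos = [p for s, e in ivs for p in range(s + 2, e - 2)]
        for g in self.rng.permutation(pos):
            ref = self._base(gene.seq_id, g)
            for alt in self.rng.permutation([b for b in "ACGT" if b != ref]):
                if which == "utr5":
                    before = self._leader_seq(gene, {})
                    after = self._leader_seq(gene, {int(g): alt})
                    if after.count("ATG") > before.count("ATG"):
                        continue  # would be a start gain
                if self._claim(gene.seq_id, int(g), int(g) + 1):
                    return Variant(gene.seq_id, int(g) + 1, ref, alt)
        raise RuntimeError(f"no {which} SNP site in {gene.gene_id}")

    def start_gain_snp(self, gene: GeneModel) -> Variant:
        """SNP in the 5' leader creating a new upstream ATG."""
        before = self._leader_seq(gene, {})
        pos = [p for s, e in gene.utr5() for p in range(s + 1, e - 1)]
        for g in self.rng.permutation(pos):
            ref = self._base(gene.seq_id, g)
            for alt in "ACGT":
                if alt == ref:
                    continue
                after = self._leader_seq(gene, {int(g): alt})
                if after.count("ATG") > before.count("ATG"):
                    if self._claim(gene.seq_id, int(g), int(g) + 1):
                        return Variant(gene.seq_id, int(g) + 1, ref, alt)
        raise RuntimeError(f"no start-gain site in {gene.gene_id}")

    def utr5_indel(self, gene: GeneModel) -> Variant:
        pos = [p for s, e in gene.utr5() for p in range(s + 3, e - 3)]
        before = self._leader_seq(gene, {})
        for g in self.rng.permutation(pos):
            g = int(g)
            # 1-bp deletion of the base at g, anchored at g-1
            ref = self.genome[gene.seq_id][g - 1 : g + 1]
            if ref[0] == ref[1]:
                continue
            # must not create a new ATG in the leader
            mut = self._mutant_leader_del(gene, g)
            if mut.count("ATG") > before.count("ATG"):
                continue
            if self._claim(gene.seq_id, g - 1, g + 1):
                return Variant(gene.seq_id, g, ref, ref[0])
        raise RuntimeError(f"no utr5 indel site in {gene.gene_id}")

    def _mutant_leader_del(self, gene: GeneModel, g: int) -> str:
        parts = []
        for s, e in gene.utr5():
            seq = self.genome[gene.seq_id][s:e]
            if s <= g < e:
                seq = seq[: g - s] + seq[g - s + 1 :]
            parts.append(seq)
        out = "".join(parts)
        return out if gene.strand == "+" else _revcomp(out)

    def intron_snp(self, gene: GeneModel) -> Variant:
        introns = gene.introns()
        for idx in self.rng.permutation(len(introns)):
            s, e = introns[idx]
            mid = (s + e) // 2
            if self._claim(gene.seq_id, mid, mid + 1):
                ref = self._base(gene.seq_id, mid)
                alt = "A" if ref != "A" else "G"
                return Variant(gene.seq_id, mid + 1, ref, alt)
        raise RuntimeError("no intron site")

    def flank_indel(self, gene: GeneModel, where: str, offset: int = 300) -> Variant:
        if (gene.strand == "+") == (where == "upstream"):
            g = gene.start - offset
        else:
            g = gene.end + offset
        while self.genome[gene.seq_id][g - 1] == self.genome[gene.seq_id][g]:
            g += 1
        if not self._claim(gene.seq_id, g - 1, g + 1):
            raise RuntimeError("flank site collision")
        ref = self.genome[gene.seq_id][g - 1 : g + 1]
        return Variant(gene.seq_id, g, ref, ref[0])


# ---------------------------------------------------------------------------
# file emission


def _write_fasta(path: Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff3_lines(genes: list[GeneModel]) -> list[str]:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda x: (x.seq_id, x.start)):
        gid = g.gene_id
        role = g.role_label.value
        lines.append(
            "\t".join(
                [
                    g.seq_id, "toy", "gene", str(g.start + 1), str(g.end), ".",
                    g.strand, ".", f"ID={gid};Name={gid};role={role}",
                ]
            )
        )
        mid = f"{gid}.t1"
        lines.append(
            "\t".join(
                [
                    g.seq_id, "toy", "mRNA", str(g.start + 1), str(g.end), ".",
                    g.strand, ".", f"ID={mid};Parent={gid}",
                ]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [
                        g.seq_id, "toy", "exon", str(s + 1), str(e), ".",
                        g.strand, ".", f"ID={mid}.exon{i};Parent={mid}",
                    ]
                )
            )
        cds_coding = g.cds if g.strand == "+" else g.cds[::-1]
        cum = 0
        phases = {}
        for s, e in cds_coding:
            phases[(s, e)] = (3 - cum % 3) % 3
            cum += e - s
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append(
                "\t".join(
                    [
                        g.seq_id, "toy", "CDS", str(s + 1), str(e), ".",
                        g.strand, str(phases[(s, e)]), f"ID={mid}.cds;Parent={mid}",
                    ]
                )
            )
        for ivs, kind in ((g.utr5(), "five_prime_UTR"), (g.utr3(), "three_prime_UTR")):
            for s, e in ivs:
                lines.append(
                    "\t".join(
                        [
                            g.seq_id, "toy", kind, str(s + 1), str(e), ".",
                            g.strand, ".", f"Parent={mid}",
                        ]
                    )
                )
    return lines


def _write_vcf(path: Path, variants: list[Variant], contigs: dict[str, int]) -> None:
    order = {c: i for i, c in enumerate(contigs)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (order[v.seq_id], v.pos)):
            fh.write(f"{v.seq_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# the generator


def generate_toy_mating_genome(out_dir: str | Path, seed: int = 0) -> ToyGenomeFixture:
    """Generate the full molecular fixture under ``out_dir``.

    Emits genome FASTA, GFF3 gene models, protein FASTA (including decoys
    for precursor-scan specificity), one sites-only VCF per strain group and
    a JSON manifest recording locus spans, planted variant effects and the
    planted reference mating type.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 0x6D617465])

    # -- proteins ----------------------------------------------------------
    proteins: dict[str, str] = {}
    proteins["beta-fg"] = _rand_protein(rng, 250)
    proteins["HD1"] = _rand_protein(rng, 220)
    proteins["HD2"] = _rand_protein(rng, 240)
    proteins["MIP"] = _rand_protein(rng, 300)
    pr_lens = {"PR1": 350, "PR2": 380, "PR3": 330, "PR4": 310, "PR5": 345, "PR6": 360}
    for name, L in pr_lens.items():
        p = _rand_protein(rng, L)
        while p[-4] == "C":  # receptors must not look like CAAX precursors
            p = _rand_protein(rng, L)
        proteins[name] = p
    pp_caax = {"PP1": "CVIA", "PP2": "CLIS", "PP3": "CAVM", "PP4": "CIGE", "PP5": "CVLC"}
    pp_lens = {"PP1": 45, "PP2": 70, "PP3": 52, "PP4": 60, "PP5": 48}
    for name in pp_caax:
        proteins[name] = _pp_protein(rng, pp_lens[name], pp_caax[name])

    # -- gene layout -------------------------------------------------------
    chr1_layout = [
        ("beta-fg", 6, "+", Role.BETA_FG),
        ("HD1", 4, "-", Role.HD1),
        ("HD2", 4, "+", Role.HD2),
        ("MIP", 4, "-", Role.MIP),
    ]
    chr11_layout = [
        ("PP1", 2, "+", Role.PP),
        ("PR1", 7, "+", Role.PR),
        ("PR2", 5, "-", Role.PR),
        ("PP2", 5, "-", Role.PP),
        ("PR3", 6, "+", Role.PR),
        ("PP3", 3, "+", Role.PP),
        ("PR4", 7, "-", Role.PR),
        ("PR5", 5, "+", Role.PR),
        ("PP4", 4, "+", Role.PP),
        ("PR6", 6, "-", Role.PR),
        ("PP5", 2, "+", Role.PP),
    ]
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    for seq_id, layout in (("chr1", chr1_layout), ("chr11", chr11_layout)):
        cassettes = [
            _build_cassette(rng, gid, proteins[gid], n_ex, strand, role)
            for gid, n_ex, strand, role in layout
        ]
        seq, placed = _place(rng, seq_id, cassettes)
        genome[seq_id] = seq
        genes.extend(placed)
    by_id = {g.gene_id: g for g in genes}

    # -- planted variants --------------------------------------------------
    group_types = {
        "group_A1B1": MatingType("A1", "B1"),
        "group_A2B2": MatingType("A2", "B2"),
    }
    planter = _Planter(rng, genome)
    planted: dict[str, list[dict]] = {g: [] for g in group_types}

    def plant(group: str, gene_id: str, category: str, v: Variant) -> None:
        planted[group].append(
            {
                "seq_id": v.seq_id, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": gene_id, "category": category,
            }
        )

    hd2, pr1, pr2 = by_id["HD2"], by_id["PR1"], by_id["PR2"]

    # group_A2B2: the HD2 allele differs from the reference — 7 frameshifts
    # plus 1 stop-codon insertion, everything else neutral.
    for length in (1, 1, 2, 2, 4, 1, 5):
        plant("group_A2B2", "HD2", "FRAME_SHIFT", planter.frameshift(hd2, length))
    plant("group_A2B2", "HD2", "STOP_CODON_INSERTION", planter.stop_codon_insertion(hd2))
    plant("group_A2B2", "HD2", "SYNONYMOUS_CODING", planter.cds_snp(hd2, "synonymous"))
    plant("group_A2B2", "HD2", "INTRON", planter.intron_snp(hd2))
    plant("group_A2B2", "MIP", "UPSTREAM", planter.flank_indel(by_id["MIP"], "upstream"))
    plant("group_A2B2", "HD1", "DOWNSTREAM", planter.flank_indel(by_id["HD1"], "downstream"))
    plant("group_A2B2", "beta-fg", "UPSTREAM", planter.flank_indel(by_id["beta-fg"], "upstream"))
    plant("group_A2B2", "PR1", "SYNONYMOUS_CODING", planter.cds_snp(pr1, "synonymous"))
    plant("group_A2B2", "PR2", "SYNONYMOUS_CODING", planter.cds_snp(pr2, "synonymous"))
    plant("group_A2B2", "PR3", "INTRON", planter.intron_snp(by_id["PR3"]))

    # group_A1B1: the PR1/PR2 (B) alleles differ from the reference.
    plant("group_A1B1", "PR1", "NONSYNONYMOUS_CODING", planter.cds_snp(pr1, "nonsynonymous"))
    plant("group_A1B1", "PR1", "NONSYNONYMOUS_CODING", planter.cds_snp(pr1, "nonsynonymous"))
    plant("group_A1B1", "PR1", "STOP_GAINED", planter.cds_snp(pr1, "stop_gained"))
    plant("group_A1B1", "PR1", "STOP_LOST", planter.cds_snp(pr1, "stop_lost"))
    plant("group_A1B1", "PR1", "SPLICE_SITE", planter.splice_variant(pr1, indel=True))
    for _ in range(4):
        plant("group_A1B1", "PR1", "UTR5", planter.utr5_indel(pr1))
    plant("group_A1B1", "PR1", "START_GAINED", planter.start_gain_snp(pr1))
    plant("group_A1B1", "PR1", "UTR3", planter.utr_snp(pr1, "utr3"))
    plant("group_A1B1", "PR2", "FRAME_SHIFT", planter.frameshift(pr2, 1))
    plant("group_A1B1", "PR2", "FRAME_SHIFT", planter.frameshift(pr2, 2))
    plant("group_A1B1", "PR2", "CODON_DELETION", planter.cds_deletion(pr2, 3, codon_aligned=True))
    plant("group_A1B1", "PR2", "STOP_CODON_INSERTION", planter.stop_codon_insertion(pr2))
    for _ in range(3):
        plant("group_A1B1", "PR2", "NONSYNONYMOUS_CODING", planter.cds_snp(pr2, "nonsynonymous"))
    plant("group_A1B1", "HD2", "SYNONYMOUS_CODING", planter.cds_snp(hd2, "synonymous"))
    plant("group_A1B1", "HD1", "SYNONYMOUS_CODING", planter.cds_snp(by_id["HD1"], "synonymous"))
    plant("group_A1B1", "MIP", "DOWNSTREAM", planter.flank_indel(by_id["MIP"], "downstream"))
    plant("group_A1B1", "beta-fg", "DOWNSTREAM", planter.flank_indel(by_id["beta-fg"], "downstream"))
    plant("group_A1B1", "PR4", "INTRON", planter.intron_snp(by_id["PR4"]))

    # -- emission ----------------------------------------------------------
    decoys = {
        "decoy1": _rand_protein(rng, 80),  # short, no CAAX
        "decoy2": "M" + "".join(rng.choice(list(_AA20), size=60)) + "CRKE",  # bad a/X
        "decoy3": _rand_protein(rng, 200)[:-4] + "CVIA",  # CAAX but too long
    }
    while decoys["decoy1"][-4] == "C":
        decoys["decoy1"] = _rand_protein(rng, 80)
    all_proteins = {**proteins, **decoys}

    genome_fasta = out_dir / "genome.fa"
    gff3 = out_dir / "annotation.gff3"
    proteins_fasta = out_dir / "proteins.faa"
    _write_fasta(genome_fasta, genome)
    _write_fasta(proteins_fasta, all_proteins)
    gff3.write_text("\n".join(_gff3_lines(genes)) + "\n")

    contigs = {c: len(s) for c, s in genome.items()}
    vcfs: dict[str, Path] = {}
    for group in group_types:
        path = out_dir / f"{group}.vcf"
        variants = [
            Variant(d["seq_id"], d["pos"], d["ref"], d["alt"]) for d in planted[group]
        ]
        _write_vcf(path, variants, contigs)
        vcfs[group] = path

    pp_genes = [g for g in genes if g.role_label is Role.PP]
    pr_genes = [g for g in genes if g.role_label is Role.PR]
    locus_b_genes = sorted(pp_genes + pr_genes, key=lambda g: g.start)
    locus_a_genes = sorted(
        (g for g in genes if g.seq_id == "chr1"), key=lambda g: g.start
    )
    manifest = {
        "seed": seed,
        "chromosomes": contigs,
        "genes": {
            g.gene_id: {
                "seq_id": g.seq_id,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "role": g.role_label.value,
                "n_exons": len(g.exons),
            }
            for g in genes
        },
        "locus_A": {
            "genes": [g.gene_id for g in locus_a_genes],
            "span_bp": locus_a_genes[-1].end - locus_a_genes[0].start,
        },
        "locus_B": {
            "genes": [g.gene_id for g in locus_b_genes],
            "span_bp": locus_b_genes[-1].end - locus_b_genes[0].start,
            "first_gene": locus_b_genes[0].gene_id,
            "last_gene": locus_b_genes[-1].gene_id,
        },
        "groups": {
            group: {
                "mating_type": str(mt),
                "vcf": vcfs[group].name,
                "planted": planted[group],
            }
            for group, mt in group_types.items()
        },
        "reference_type": "A1B2",
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return ToyGenomeFixture(
        root=out_dir,
        genome_fasta=genome_fasta,
        gff3=gff3,
        proteins_fasta=proteins_fasta,
        vcfs=vcfs,
        manifest_path=manifest_path,
        genome=genome,
        genes=genes,
        proteins=all_proteins,
        group_types=group_types,
        reference_type=MatingType("A1", "B2"),
        planted=planted,
        manifest=manifest,
    )
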