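# matepol

Mating-system inference for tetrapolar basidiomycete fungi.

In Agaricomycetes, whether two haploid strains (monokaryons) can mate is
controlled by incompatibility loci.  Under **tetrapolar** control two
unlinked loci decide: the homeodomain locus *A* (a divergently transcribed
*HD1*/*HD2* gene pair flanked by *β-fg* and *MIP*) and the pheromone/receptor
locus *B* (pheromone receptor *PR* and short pheromone precursor *PP*
genes).  A strain's mating type is its allele pair, written `A1B1`, `A2B2`,
`A1B2`, `A2B1`; a cross succeeds — scored by clamp connections on the
hyphae — only when the two strains differ at **both** loci.  Crosses
differing only at *A* (common-B) abort late and leave clamp-like
"pseudo-clamp" appendages, a notorious false-positive.

`matepol` implements the full inference chain used to establish such a
mating system, for people doing mushroom genetics and breeding:

- **Simulation** — meiotic basidiospore populations segregating at two loci
  with configurable recombination fraction *r*, per-type viability weights
  (germination/growth distortion), and assay error; protoplast-derived
  monokaryons (parental nuclear types only); pairwise compatibility
  matrices.
- **Classification** — the single-tester *test cross* and the *three-round*
  procedure that reads a full mating grid back into mating types, with a
  consistency cross-check against the tetrapolar rule and a polarity call
  (`TETRAPOLAR`, `TWO_TYPES_UNDETERMINED`, `INCONSISTENT`).
- **Segregation testing** — chi-squared goodness-of-fit of observed type
  counts against Mendelian ratios, `χ² = Σ (Oᵢ−Eᵢ)²/Eᵢ` with
  `Eᵢ = n·ratioᵢ/Σratio`, no continuity correction, `df = k−1`, decided
  against the upper-α critical value.
- **Locus annotation** — locating the *A* locus (head-to-head HD pair with
  its β-fg/MIP flanks) and the *B* locus (minimal window of all PR/PP
  genes) in a GFF3 annotation; pheromone-precursor detection by the
  C-terminal **CAAX** prenylation box (C, two aliphatic residues, then a
  permissive X) with EA/AF dipeptides as auxiliary evidence.
- **Variant typing** — SNP/indel consequence annotation against gene models
  (frameshift, stop-codon insertion, synonymous/nonsynonymous, splice, UTR,
  …, validated against a whole-CDS translation oracle) and the
  allele-sharing rule: the reference strain carries, at each locus, the
  allele of the strain group showing **zero** protein-breaking variants at
  that locus's determinant genes (*HD2* for locus A, *PR1*/*PR2* for
  locus B).
- **Synthetic data** — a seeded toy-genome generator (FASTA + GFF3 +
  per-group VCFs + protein FASTA + JSON manifest) with the full mating-locus
  architecture and planted variant effects, so the whole chain is testable
  without any external data.

## Worked example

```python
from matepol import (
    CrossParameters, MatingType, build_compatibility_matrix,
    segregation_chi_square, simulate_meiosis, three_round_classify,
)

params = CrossParameters(recombination_fraction=0.5, seed=42)
spores = simulate_meiosis(MatingType("A1", "B1"), MatingType("A2", "B2"), 246, params)
matrix = build_compatibility_matrix(spores, params)
call = three_round_classify(matrix)
print(call.class_sizes())          # {'A1B1': 47, 'A2B1': 61, 'A1B2': 69, 'A2B2': 69}
print(call.polarity_call.value)    # TETRAPOLAR

print(segregation_chi_square((45, 32), (1, 1)))
# chi2=2.195 (df=1, crit_0.05=3.84) vs 1:1 -> accept
print(segregation_chi_square((97, 111, 13, 25), (1, 1, 1, 1)))
# chi2=120.244 (df=3, crit_0.05=7.81) vs 1:1:1:1 -> reject
```

All four spore classes occur and every pairwise outcome is consistent with
two unlinked loci, so the polarity call is `TETRAPOLAR`.  The 45:32
protoplast table fits 1:1 (χ² = 2.195 < 3.84), while 97:111:13:25 is far
from 1:1:1:1 (χ² = 120.24 > 7.81) — segregation distortion.

The molecular side, on the built-in toy genome:

```python
import tempfile
from matepol import assign_reference_type, generate_toy_mating_genome, group_effect_profile

with tempfile.TemporaryDirectory() as tmp:
    fx = generate_toy_mating_genome(tmp, seed=0)
    profile = group_effect_profile(fx.vcfs, fx.genes, fx.genome)
    call = assign_reference_type(profile, fx.group_types)
print(dict(call.locus_a.impactful_counts))  # {'group_A1B1': 0, 'group_A2B2': 8}
print(call.mating_type)                     # A1B2
```

The A2B2-like group breaks *HD2* (7 frameshifts + 1 stop-codon insertion)
while the A1B1-like group breaks only *PR1*/*PR2*, so the reference shares
its A allele with the first group and its B allele with the second:
mating type **A1B2**.

More narrative scripts live under `examples/` (one per capability); a thin
CLI mirrors the library:

```bash
matepol chisq --counts 45,32 --ratio 1,1
matepol simulate --n 100 --seed 1 --out grid.tsv && matepol classify --matrix grid.tsv
matepol find-loci --gff annotation.gff3
matepol run --seed 1 --out-dir demo_run   # full pipeline, JSON report
```

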