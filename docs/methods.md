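# Methods

This note documents the models, conventions and numerical choices behind
`matepol`, and what its synthetic data do and do not establish about real
populations.

## The incompatibility model

A mating type is an ordered allele pair (Aᵢ, Bⱼ) at two loci.  The pairing
rule (`tetrapolar_outcome`) is:

| pair differs at | outcome |
|---|---|
| both loci | `CLAMP` (true dikaryon) |
| A only (common-B) | `PSEUDO_CLAMP` |
| B only (common-A), or neither | `NONE` |

Self-crosses are `NONE`.  Within any one simulated cross both loci are
biallelic — the progeny of a dikaryon carry at most the four combinations of
the two parental alleles per locus.  Multiallelic series (as exist in many
Agaricomycete populations at large) are out of scope.

## Meiosis and distortion

`simulate_meiosis` draws each spore's type from the gamete distribution
{each parental type with probability (1−r)/2, each recombinant with r/2},
where the recombination fraction r ∈ [0, 0.5] is 0.5 for unlinked loci
(the tetrapolar case) and 0 for complete linkage (effectively bipolar
segregation).  Viability distortion — the biological reading is reduced
germination or growth of some spore classes, not distorted meiosis — is
applied *after* segregation as rejection sampling: a spore of type i
survives with probability wᵢ/max(w).  The resulting type frequencies have
the closed form

    p(type i) = base_i · w_i / Z,   base = (1−r)/2 or r/2,

which the test suite checks against simulation at 3σ.  Defaults are r = 0.5
and equal weights; the distorted regimes exercised in tests use the weight
vectors matching the observed count tables (97:111:13:25 and 83:40).

`simulate_protoplasting` models monokaryon regeneration from a dikaryon's
protoplasts: only the two parental nuclear types can appear.  Whether
recovery is 1:1 a priori is not asserted; the `bias` parameter (default
0.5) is the probability of recovering nucleus 1.

Randomness: one integer seed per operation.  Sub-streams are derived per
spore index and per unordered strain pair, so spore i is independent of how
many spores follow and a compatibility matrix is invariant under reordering
of its strains.  Identical seeds reproduce byte-identical outputs.

## Assay error

Errors are injected at matrix read-out, never into the truth: a `NONE` cell
flips to `CLAMP` with probability `assay_false_positive`, and a
`PSEUDO_CLAMP` cell with probability `pseudo_clamp_misread` (pseudo-clamps
are morphologically hard to distinguish from true clamps).  Both default
to 0.  Classification treats pseudo-clamps as incompatible by default —
they are false positives — with `score_pseudo_as="COMPATIBLE"` available to
reproduce the failure mode.

## Three-round classification

The algorithmic reconstruction of the gridded-chart bench protocol:

1. **Tester 1** is the lexicographically smallest strain showing at least
   one positive mating (a strain with no mate anywhere could be a
   recombinant whose opposite class is absent and would anchor nothing).
   It is declared `A1B1`; its CLAMP partners are `A2B2`.
2. **Tester 2**, the smallest `A2B2` strain, confirms and extends the
   `A1B1` class through its own CLAMP partners.
3. **Tester 3**: if any still-unassigned strain clamps another unassigned
   strain, the smallest such strain is labelled `A2B1` (a convention — the
   A/B orientation of the recombinant classes is not identifiable from
   compatibility data) and its partners `A1B2`.  Leftovers observed against
   both parental classes but mating with neither are typed by exclusion as
   tester 3's own class: a strain incompatible with two fully opposite
   types must be a recombinant, and mutually compatible leftovers form one
   class.

If no positive mating exists anywhere, the grid is at most two classes and
only the pseudo-clamp pattern can separate them: strains pseudo-clamping
tester 1 get `A2B1`, the rest (with any observed data) share tester 1's
label.  Strains with no observed outcomes are never guessed and stay
unassigned.

**Consistency cross-check.**  Every assigned pair is compared with the
rule, orientation-free because of the labelling convention: an observed
`CLAMP` requires the inferred types to differ at both loci; an observed
`PSEUDO_CLAMP` requires a difference at exactly one locus; an observed
`NONE` forbids a difference at both.  Any violation makes the polarity call
`INCONSISTENT`.

**Polarity.**  `TETRAPOLAR` when more than two consistent classes occur —
a class incompatible with both fully opposite parental classes cannot
exist under single-locus control, so three classes already prove two loci.
`TWO_TYPES_UNDETERMINED` when at most two classes occur: two mutually
compatible classes are consistent with both a tetrapolar system whose
recombinants went unsampled and a bipolar one.

**Identifiability.**  The assay has one blind spot: classes sharing their A
allele (e.g. a population containing only `A1B1` and `A1B2`) produce `NONE`
in every cell — a matrix identical to a single class's, so no procedure
can split them.  Classes sharing the B allele remain separable through the
pseudo-clamp pattern.  `assay_identifiable_partition` states this limit
precisely (truth partition, except mutually common-A-only compositions
merge into one block); the classifier provably attains it on error-free
matrices in the test suite, over populations of 8–200 strains across six
distortion regimes.

## Segregation tests

`segregation_chi_square` is the plain Pearson goodness-of-fit statistic,
without Yates continuity correction — the convention in Mendelian
segregation tables (with correction, the 45:32 table would give 1.87
instead of the expected 2.195).  `df = k − 1`; the decision compares the
statistic against the upper-α quantile (`chi_square_critical`, from the
chi-squared inverse CDF; α default 0.05).  Expected counts of zero (a zero
ratio weight) are an error.  Calibration: on undistorted four-type
populations of n = 123 the 1:1:1:1 test rejects at a rate statistically
consistent with α = 0.05 (2000 replicates, 99% binomial interval).

## Toy genome

The generator emits a two-replicon genome of about 60 kb designed so every
structural and variant-typing rule has something to find, at a scale where
the whole suite runs in seconds:

- `chr1`: *β-fg* (6 exons), *HD1*, *HD2*, *MIP* (4 exons each) in that
  order; *HD1*/*HD2* divergently transcribed head-to-head; *HD1* and *MIP*
  on the same strand.
- `chr11`: six *PR* genes (5–7 exons, 310–380 aa receptors) interleaved
  with five *PP* genes (2–5 exons, 45–70 aa precursors ending in a CAAX
  box and carrying EA/AF dipeptides).  Locus B runs from *PP1* to *PP5*.
- Genes are built coding-strand-first from random proteins
  (reverse-translated with uniformly chosen codons), split by introns
  (60 bp, canonical GT..AG), and placed with fixed 2 kb spacers and 4 kb
  flanks so locus spans are reproducible; the manifest records them.
- Per-group sites-only VCFs plant variants with known effects.  The
  A2B2-like group carries, at *HD2*, 7 frameshift indels (lengths 1, 1, 2,
  2, 4, 1, 5) and one in-frame stop-codon insertion — 8 impactful variants
  — plus only neutral variation elsewhere; the A1B1-like group carries
  impactful variants only at *PR1* (nonsynonymous, stop gain, stop loss,
  start gain, splice, 5′/3′-UTR) and *PR2* (frameshifts, codon deletion,
  stop-codon insertion, nonsynonymous).  The reference sequence therefore
  reads out as A1B2.  All planted indels are constructed already
  left-normalised.

What the fixture does **not** emulate: real intergenic structure, repeat
content, sequencing error, strain-to-strain variation within a group
(VCFs are per-group site lists), multiallelic loci, and realistic gene
lengths for the receptors.  Passing tests therefore demonstrate the
correctness of the inference logic, not performance on noisy real
resequencing data.

## Variant annotation

Coordinates are 1-based inclusive in files (GFF3, VCF) and 0-based
half-open in memory.  A variant's affected region is resolved in priority
order splice > CDS > UTR > intron > upstream > downstream > intergenic,
with windows of 1000 bp up/downstream and a splice region of 2 bp into each
intron end (all configurable; chosen as common annotation-tool defaults).

Within the CDS: an indel whose net length is not a multiple of 3 is a
`FRAME_SHIFT`; in-frame insertions are `CODON_INSERTION`
(`STOP_CODON_INSERTION` when the insertion brings an in-frame stop, checked
on the local reading-frame window); in-frame deletions are
`CODON_DELETION`.  SNPs are classified by rebuilding the affected codon on
the coding strand (synonymous / nonsynonymous / stop gained / stop lost,
standard codon table, genes assumed complete).  A 5′-leader variant that
increases the number of upstream ATGs is a `START_GAINED` — the
operationalisation chosen for "start codon gain", flagged as an
interpretation.  This per-codon fast path is verified in the tests against
an independent oracle that applies the edit to the chromosome, re-extracts
and translates the whole CDS, and compares proteins; the two agree on every
planted and random coding variant, both strands.

"Impactful" follows the broad convention used when deciding allele sharing:
protein-altering plus splice **and** 5′/3′-UTR variants.  A strict
protein-coding-only definition is available (`convention="strict"`).
Multiallelic records are split on reading; per-group counts are per unique
site (variants shared by many strains of a group count once), the reading
consistent with sites-only group VCFs.

## Allele sharing and the reference type

For each locus, `assign_reference_type` compares the impactful-variant
counts of the two (fully opposite) strain groups at the locus's determinant
genes — defaults *HD2* for locus A and *PR1*+*PR2* for locus B, the genes
where allelic variation concentrates.  The reference shares the allele of
the group with zero impactful variants; both groups zero is `AMBIGUOUS`,
neither zero `INCONSISTENT`, and either voids the combined call.

## Known limitations

- Biallelic loci per cross; no multiallelic mating-type series.
- The three-round labelling is conventional: recovered partitions match
  truth, labels match only up to the documented permutation (and the
  recombinant A/B orientation is inherently arbitrary).
- The assay cannot split common-A class mixtures (see Identifiability).
- Variant annotation assumes complete gene models (ATG start, terminal
  stop) and non-overlapping genes; edits spanning exon–intron junctions
  take the splice-region category rather than a compound one.
- Pipeline problem sizes (246 spores, 77 protoplasts, 200 evaluation
  populations, 2000 calibration replicates) are the package's defaults,
  chosen to mirror the motivating experimental design while keeping any
  run comfortably fast.
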