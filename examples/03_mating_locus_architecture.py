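"""Identify the HD (A) and PR (B) mating loci in a gene annotation.

The toy genome carries the canonical architecture: beta-fg, HD1, HD2, MIP
on one replicon with the homeodomain genes transcribed head-to-head, and
six pheromone receptors interleaved with five pheromone precursors on
another.  The precursors are found by their C-terminal CAAX box rather
than homology.
"""

import tempfile

from matepol import generate_toy_mating_genome, identify_locus_A, identify_locus_B, scan_precursors

with tempfile.TemporaryDirectory() as tmp:
    fixture = generate_toy_mating_genome(tmp, seed=0)

    locus_a = identify_locus_A(fixture.genes)
    print("locus A:", " > ".join(locus_a.gene_order), f"({locus_a.span_bp} bp)")

    locus_b = identify_locus_B(fixture.genes)
    print(
        "locus B:", " > ".join(locus_b.gene_order),
        f"({locus_b.span_bp} bp, {locus_b.notes['n_pr']} PRs, {locus_b.notes['n_pp']} PPs)",
    )

    hits = scan_precursors(fixture.proteins_fasta, max_len=120)
    for h in hits:
        if h.is_candidate:
            print(f"precursor candidate {h.protein_id}: CAAX at {h.caax_position}, "
                  f"{len(h.aux_motifs)} EA/AF motifs")
# The locus-A window is the head-to-head HD pair with its beta-fg and MIP
# flanks; the locus-B span runs from the first precursor gene to the last.
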