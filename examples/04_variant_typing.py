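"""Assign a reference strain's mating type from resequencing variants.

Two groups of strains with opposite mating types were aligned to the
reference genome.  Wherever the reference shares an allele with a group,
that group shows no protein-breaking variants at the locus's determinant
genes; the group carrying the other allele shows frameshifts, stop gains
and the like.  Reading both loci gives the reference's combined type.
"""

import tempfile

from matepol import assign_reference_type, generate_toy_mating_genome, group_effect_profile

with tempfile.TemporaryDirectory() as tmp:
    fixture = generate_toy_mating_genome(tmp, seed=0)
    profile = group_effect_profile(fixture.vcfs, fixture.genes, fixture.genome)

    print(profile.loc[("group_A2B2", "HD2")][["FRAME_SHIFT", "STOP_CODON_INSERTION", "impactful"]])
    print()
    print(profile["impactful"].unstack().to_string())
    print()

    call = assign_reference_type(
        profile, fixture.group_types, locus_a_genes=("HD2",), locus_b_genes=("PR1", "PR2")
    )
    print("locus A allele shared with:", call.locus_a.shared_with)
    print("locus B allele shared with:", call.locus_b.shared_with)
    print("reference mating type:     ", call.mating_type)
# The A2B2-like group breaks HD2 (7 frameshifts + 1 stop-codon insertion),
# so the reference shares its A allele with the A1B1 group; the A1B1-like
# group breaks PR1/PR2, so the reference shares its B allele with the A2B2
# group.  Combined: the reference is A1B2.
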