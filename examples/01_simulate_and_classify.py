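"""Simulate a basidiospore population and recover its mating types.

A dikaryon heterozygous at both incompatibility loci (A1B1 x A2B2) sheds
spores of up to four mating types.  We simulate 246 germinated spores with
unlinked loci (recombination fraction 0.5), record the full pairwise mating
grid, and run the three-round classification that reads mating types back
off the grid.
"""

from matepol import (
    CrossParameters,
    MatingType,
    build_compatibility_matrix,
    simulate_meiosis,
    three_round_classify,
)

params = CrossParameters(recombination_fraction=0.5, seed=42)
spores = simulate_meiosis(MatingType("A1", "B1"), MatingType("A2", "B2"), 246, params)
matrix = build_compatibility_matrix(spores, params)
call = three_round_classify(matrix)

print("testers used:", call.tester_ids)
print("class sizes: ", call.class_sizes())
print("polarity:    ", call.polarity_call.value)
# All four classes present and mutually consistent -> TETRAPOLAR: two
# unlinked loci control compatibility.  The class labels are conventional
# (the first tester is declared A1B1); the partition itself matches truth.
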