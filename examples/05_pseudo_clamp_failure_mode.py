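"""The pseudo-clamp false-positive phenomenon.

Common-B pairings (A alleles differ, B alleles identical) abort after
nuclear pairing but leave clamp-like appendages that are easy to misread as
true clamps.  Scoring pseudo-clamps as compatible — or misreading a
fraction of them at the bench — corrupts the inferred types; the classifier
surfaces the corruption as INCONSISTENT rather than silently mistyping.
"""

from matepol import (
    CrossParameters,
    MatingType,
    build_compatibility_matrix,
    simulate_meiosis,
    three_round_classify,
)

p1, p2 = MatingType("A1", "B1"), MatingType("A2", "B2")
spores = simulate_meiosis(p1, p2, 100, CrossParameters(seed=7))

clean = build_compatibility_matrix(spores, CrossParameters(seed=7))
print("error-free:        ", three_round_classify(clean).polarity_call.value)

print(
    "pseudo=COMPATIBLE:  ",
    three_round_classify(clean, score_pseudo_as="COMPATIBLE").polarity_call.value,
)

misread = build_compatibility_matrix(
    spores, CrossParameters(pseudo_clamp_misread=0.3, seed=7)
)
print("30% misread:       ", three_round_classify(misread).polarity_call.value)
# Treating pseudo-clamps as positive matings (or misreading them) merges
# common-B classes and contradicts the tetrapolar rule, so the polarity
# call degrades to INCONSISTENT instead of returning a wrong partition.
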