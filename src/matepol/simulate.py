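"""Simulation of monokaryon populations and mating assays.

Generates basidiospore progeny of a dikaryotic parent segregating at the two
mating loci, protoplast-derived monokaryons (parental nuclear types only),
and the pairwise compatibility matrix an experimenter would record —
optionally corrupted by assay error and pseudo-clamp misreads.

Randomness: every operation takes a single integer seed.  Sub-streams are
derived per spore index (meiosis) or per unordered strain pair (matrix
build) so that outputs are stable under reordering of the inputs.
"""

from __future__ import annotations

import zlib

import numpy as np

from .inference import tetrapolar_outcome
from .types import (
    CompatibilityMatrix,
    CrossParameters,
    MatingType,
    Monokaryon,
    Origin,
    Outcome,
)

__all__ = [
    "simulate_meiosis",
    "simulate_protoplasting",
    "build_compatibility_matrix",
    "meiotic_type_probabilities",
    "assay_identifiable_partition",
]


def _check_parents(p1: MatingType, p2: MatingType) -> None:
    a_diff, b_diff = p1.differs_at(p2)
    if not (a_diff and b_diff):
        raise ValueError(
            f"invalid cross: parental types {p1} and {p2} must differ at both loci"
        )


def _gamete_types(p1: MatingType, p2: MatingType) -> tuple[list[MatingType], list[MatingType]]:
    """(parental, recombinant) gamete mating types of the dikaryon p1 x p2."""
    parental = [p1, p2]
    recombinant = [
        MatingType(p1.a_allele, p2.b_allele),
        MatingType(p2.a_allele, p1.b_allele),
    ]
    return parental, recombinant


def meiotic_type_probabilities(
    parent_type_1: MatingType,
    parent_type_2: MatingType,
    params: CrossParameters,
) -> dict[MatingType, float]:
    """Closed-form post-selection type frequencies.

    Each parental type has meiotic probability (1-r)/2 and each recombinant
    r/2; differential spore viability then reweights these by w_i, i.e.
    ``p_i = base_i * w_i / Z``.  This is the distribution the rejection
    sampler in :func:`simulate_meiosis` targets.
    """
    _check_parents(parent_type_1, parent_type_2)
    r = params.recombination_fraction
    parental, recombinant = _gamete_types(parent_type_1, parent_type_2)
    base = {t: (1.0 - r) / 2.0 for t in parental}
    base.update({t: r / 2.0 for t in recombinant})
    weights = params.viability_weights or {}
    raw = {t: p * weights.get(t, 1.0) for t, p in base.items()}
    z = sum(raw.values())
    if z <= 0:
        raise ValueError("viability weights eliminate every producible type")
    return {t: p / z for t, p in raw.items()}


def simulate_meiosis(
    parent_type_1: MatingType,
    parent_type_2: MatingType,
    n: int,
    params: CrossParameters,
    id_prefix: str = "S",
) -> list[Monokaryon]:
    """Simulate ``n`` germinated basidiospore monokaryons of a dikaryon.

    Meiosis draws each spore's type from {parental pair at (1-r)/2 each,
    recombinant pair at r/2 each}; viability distortion is then applied as
    rejection sampling (a spore of type i germinates with probability
    ``w_i / max(w)``), modelling differential germination/growth rather
    than distorted segregation itself.  Deterministic given ``params.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_parents(parent_type_1, parent_type_2)

    r = params.recombination_fraction
    parental, recombinant = _gamete_types(parent_type_1, parent_type_2)
    pool = parental + recombinant
    base = np.array([(1.0 - r) / 2.0] * 2 + [r / 2.0] * 2)
    weights = params.viability_weights or {}
    w = np.array([weights.get(t, 1.0) for t in pool], dtype=float)
    if (base * w).sum() <= 0:
        raise ValueError("viability weights eliminate every producible type")
    w_accept = w / w.max() if w.max() > 0 else w

    spores: list[Monokaryon] = []
    for i in range(n):
        rng = np.random.default_rng([params.seed, i])
        while True:
            k = rng.choice(4, p=base)
            if rng.random() <= w_accept[k]:
                break
        spores.append(
            Monokaryon(
                strain_id=f"{id_prefix}{i + 1:04d}",
                mating_type=pool[k],
                origin=Origin.BASIDIOSPORE,
            )
        )
    return spores


def simulate_protoplasting(
    parent_type_1: MatingType,
    parent_type_2: MatingType,
    n: int,
    bias: float = 0.5,
    seed: int = 0,
    id_prefix: str = "P-",
) -> list[Monokaryon]:
    """Simulate ``n`` monokaryons regenerated from a dikaryon's protoplasts.

    Protoplast monokaryotization can only recover the dikaryon's two
    parental nuclei, so every strain is one of the two parental types;
    ``bias`` is the probability of recovering nucleus 1 (no 1:1 null is
    assumed a priori).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < bias < 1.0 and bias not in (0.0, 1.0):
        raise ValueError("bias must lie in [0, 1]")
    _check_parents(parent_type_1, parent_type_2)
    strains = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        mt = parent_type_1 if rng.random() < bias else parent_type_2
        strains.append(
            Monokaryon(
                strain_id=f"{id_prefix}{i + 1}",
                mating_type=mt,
                origin=Origin.PROTOPLAST,
            )
        )
    return strains


def assay_identifiable_partition(strains: list[Monokaryon]) -> frozenset[frozenset[str]]:
    """The finest strain partition a mating assay can recover.

    Usually this is the true partition by mating type.  The one blind spot
    of the assay: classes sharing their A allele (common-A) produce NONE
    against each other and against nothing else informative, so a population
    consisting *only* of mutually common-A classes (or a single class) is
    one indistinguishable block — its matrix is identical to a single
    class's.  Classes sharing the B allele remain separable through the
    pseudo-clamp pattern.
    """
    groups: dict[MatingType, set[str]] = {}
    for s in strains:
        groups.setdefault(s.mating_type, set()).add(s.strain_id)
    types = list(groups)
    all_none = all(
        tetrapolar_outcome(t1, t2) is Outcome.NONE
        for i, t1 in enumerate(types)
        for t2 in types[i + 1 :]
    )
    if all_none and len(types) > 1:
        return frozenset({frozenset(s.strain_id for s in strains)})
    return frozenset(frozenset(v) for v in groups.values())


def _pair_rng(seed: int, id1: str, id2: str) -> np.random.Generator:
    # keyed on the unordered pair so the matrix stays symmetric and stable
    # under reordering of the strain list
    k1, k2 = sorted((zlib.crc32(id1.encode()), zlib.crc32(id2.encode())))
    return np.random.default_rng([seed, k1, k2])


def build_compatibility_matrix(
    strains: list[Monokaryon],
    params: CrossParameters | None = None,
) -> CompatibilityMatrix:
    """Pairwise mating grid of a strain collection, with optional assay error.

    Each off-diagonal cell is the tetrapolar outcome of the pair's true
    types, then perturbed: a NONE may be misread CLAMP with probability
    ``assay_false_positive``, a PSEUDO_CLAMP with probability
    ``pseudo_clamp_misread`` (pseudo-clamps are morphologically hard to
    tell apart from true clamps).  The diagonal is NONE (self-cross).
    Errors are injected at read-out; the strains' true types are untouched.
    """
    params = params or CrossParameters()
    ids = [s.strain_id for s in strains]
    matrix = CompatibilityMatrix(ids)  # raises on duplicate ids
    types = {s.strain_id: s.mating_type for s in strains}
    noisy = params.assay_false_positive > 0 or params.pseudo_clamp_misread > 0
    for i, s1 in enumerate(ids):
        for s2 in ids[i + 1 :]:
            outcome = tetrapolar_outcome(types[s1], types[s2])
            if noisy:
                rng = _pair_rng(params.seed, s1, s2)
                u = rng.random()
                if outcome is Outcome.NONE and u < params.assay_false_positive:
                    outcome = Outcome.CLAMP
                elif (
                    outcome is Outcome.PSEUDO_CLAMP
                    and u < params.pseudo_clamp_misread
                ):
                    outcome = Outcome.CLAMP
            matrix.set(s1, s2, outcome)
    return matrix
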