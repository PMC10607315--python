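"""Mating-type classification and segregation testing.

Implements the incompatibility rule of a tetrapolar mating system, the
test-cross and three-round classification procedures run on a pairwise
compatibility matrix, and the chi-squared goodness-of-fit test used on
segregation ratios.
"""

from __future__ import annotations

from typing import Literal

from scipy import stats

from .types import (
    UNASSIGNED,
    CompatibilityMatrix,
    MatingType,
    Outcome,
    Polarity,
    SegregationTestResult,
    TypeAssignment,
)

__all__ = [
    "tetrapolar_outcome",
    "test_cross_classify",
    "three_round_classify",
    "segregation_chi_square",
    "chi_square_critical",
]

PseudoPolicy = Literal["COMPATIBLE", "INCOMPATIBLE"]


def tetrapolar_outcome(t1: MatingType, t2: MatingType) -> Outcome:
    """Outcome of pairing two monokaryons under tetrapolar incompatibility.

    A true dikaryon (CLAMP) forms only when the pair differs at both the A
    (HD) and B (PR) loci.  A common-B pairing — A differs, B identical —
    aborts after nuclear pairing and leaves a clamp-like appendage
    (PSEUDO_CLAMP).  Every other combination (identical types, or common-A)
    yields no clamps (NONE).  Symmetric in its arguments.
    """
    a_diff, b_diff = t1.differs_at(t2)
    if a_diff and b_diff:
        return Outcome.CLAMP
    if a_diff and not b_diff:
        return Outcome.PSEUDO_CLAMP
    return Outcome.NONE


def _opposite(mt: MatingType, alleles_a: tuple[str, str], alleles_b: tuple[str, str]) -> MatingType:
    a = alleles_a[1] if mt.a_allele == alleles_a[0] else alleles_a[0]
    b = alleles_b[1] if mt.b_allele == alleles_b[0] else alleles_b[0]
    return MatingType(a, b)


def _positive(outcome: Outcome, pseudo: PseudoPolicy) -> bool:
    if outcome is Outcome.CLAMP:
        return True
    return outcome is Outcome.PSEUDO_CLAMP and pseudo == "COMPATIBLE"


def test_cross_classify(
    matrix: CompatibilityMatrix,
    tester_id: str,
    tester_type: MatingType = MatingType("A1", "B1"),
    score_pseudo_as: PseudoPolicy = "INCOMPATIBLE",
) -> TypeAssignment:
    """Classify by crossing every strain against one tester of known type.

    Strains fully compatible with the tester receive the fully opposite
    type (both alleles flipped); everything else stays unassigned.  The
    tester itself keeps its putative type.  Pseudo-clamps count as positive
    matings only under ``score_pseudo_as="COMPATIBLE"`` (they are false
    positives; the default scores them incompatible).
    """
    if tester_id not in matrix:
        raise KeyError(f"tester {tester_id!r} not in matrix")
    row = [matrix.get(tester_id, s) for s in matrix.strain_ids if s != tester_id]
    if row and all(o is Outcome.UNTESTED for o in row):
        raise ValueError(f"tester {tester_id!r} was never crossed against any strain")

    alleles_a = (tester_type.a_allele, _flip_label(tester_type.a_allele))
    alleles_b = (tester_type.b_allele, _flip_label(tester_type.b_allele))
    opposite = _opposite(tester_type, alleles_a, alleles_b)

    assignments: dict[str, MatingType | None] = {s: UNASSIGNED for s in matrix.strain_ids}
    rounds: dict[str, int] = {}
    assignments[tester_id] = tester_type
    rounds[tester_id] = 0
    for s in matrix.strain_ids:
        if s == tester_id:
            continue
        if _positive(matrix.get(tester_id, s), score_pseudo_as):
            assignments[s] = opposite
            rounds[s] = 1

    two_classes = len({str(mt) for mt in assignments.values() if mt is not None}) == 2
    polarity = Polarity.TWO_TYPES_UNDETERMINED if two_classes else Polarity.TETRAPOLAR
    return TypeAssignment(
        assignments=assignments,
        tester_ids=[tester_id],
        polarity_call=polarity,
        round_assigned=rounds,
    )


test_cross_classify.__test__ = False  # keep pytest from collecting the API name


def _flip_label(allele: str) -> str:
    # A1 <-> A2, B1 <-> B2; arbitrary other labels get a "'" suffix
    if allele.endswith("1"):
        return allele[:-1] + "2"
    if allele.endswith("2"):
        return allele[:-1] + "1"
    return allele + "'"


def three_round_classify(
    matrix: CompatibilityMatrix,
    score_pseudo_as: PseudoPolicy = "INCOMPATIBLE",
    tester_ids: tuple[str | None, str | None, str | None] = (None, None, None),
) -> TypeAssignment:
    """Reconstruct mating types from a full pairwise compatibility grid.

    Algorithmic version of the bench protocol in which three successive
    tester strains are mated against the population:

    1. The first tester — the smallest strain id showing at least one
       positive mating, unless overridden — is declared A1B1; its CLAMP
       partners are the fully opposite type A2B2.  (A tester without a
       single mate could be a recombinant whose opposite class is missing
       and would anchor nothing.)  If no strain mates with anything, the
       grid is a single compatibility class: every strain with observed
       data gets the tester's label.
    2. The smallest A2B2 strain becomes tester two; its CLAMP partners are
       confirmed (or newly assigned) A1B1.
    3. If any still-unassigned strain shows a CLAMP to another unassigned
       strain, the smallest such strain becomes tester three and is labelled
       A2B1 by convention; its CLAMP partners among the unassigned are A1B2.
       Finally, leftovers that were observed against both parental classes
       yet mated with neither are typed by exclusion as tester three's own
       class (a strain incompatible with both fully opposite parental types
       must be a recombinant, and mutually compatible leftovers clamping
       neither parental class form a single class).

    Finally every assigned pair is cross-checked against the tetrapolar
    rule.  Because the A/B locus orientation of the recombinant classes is
    not identifiable from clamp data alone, the check is orientation-free:
    an observed CLAMP requires the inferred types to differ at both loci, an
    observed PSEUDO_CLAMP requires a difference at exactly one locus, and an
    observed NONE forbids a difference at both.

    The polarity call is TETRAPOLAR when all four types occur and every
    check passes, TWO_TYPES_UNDETERMINED when only the two mutually
    compatible parental classes occur, and INCONSISTENT on any
    contradiction.
    """
    if len(matrix) < 2:
        raise ValueError("three-round classification needs at least 2 strains")

    A1B1, A2B2 = MatingType("A1", "B1"), MatingType("A2", "B2")
    A2B1, A1B2 = MatingType("A2", "B1"), MatingType("A1", "B2")

    assignments: dict[str, MatingType | None] = {s: UNASSIGNED for s in matrix.strain_ids}
    rounds: dict[str, int] = {}
    testers: list[str] = []

    # Round 1
    tester1 = tester_ids[0]
    if tester1 is None:
        for s in sorted(matrix.strain_ids):
            if any(
                _positive(matrix.get(s, t), score_pseudo_as)
                for t in matrix.strain_ids
                if t != s
            ):
                tester1 = s
                break
    if tester1 is None:
        # no positive mating anywhere: at most two classes, separable only
        # by the pseudo-clamp (common-B) pattern against the tester
        tester1 = min(matrix.strain_ids)
        testers.append(tester1)
        assignments[tester1] = A1B1
        rounds[tester1] = 1
        for s in matrix.strain_ids:
            if s == tester1:
                continue
            if matrix.get(tester1, s) is Outcome.PSEUDO_CLAMP:
                assignments[s] = A2B1  # differs at one locus; A by convention
                rounds[s] = 1
            elif any(
                matrix.get(s, t) is not Outcome.UNTESTED
                for t in matrix.strain_ids
                if t != s
            ):
                assignments[s] = A1B1
                rounds[s] = 1
    else:
        if tester1 not in matrix:
            raise KeyError(f"tester {tester1!r} not in matrix")
        testers.append(tester1)
        assignments[tester1] = A1B1
        rounds[tester1] = 1
        for s in matrix.strain_ids:
            if s != tester1 and _positive(matrix.get(tester1, s), score_pseudo_as):
                assignments[s] = A2B2
                rounds[s] = 1

    # Round 2
    opposite_pool = sorted(s for s, mt in assignments.items() if mt == A2B2)
    if opposite_pool:
        tester2 = tester_ids[1] if tester_ids[1] is not None else opposite_pool[0]
        testers.append(tester2)
        for s in matrix.strain_ids:
            if s == tester2:
                continue
            if _positive(matrix.get(tester2, s), score_pseudo_as):
                if assignments[s] is UNASSIGNED:
                    assignments[s] = A1B1
                    rounds[s] = 2

    # Round 3: only with positive evidence among the leftovers
    unassigned = sorted(s for s, mt in assignments.items() if mt is UNASSIGNED)
    tester3 = tester_ids[2]
    if tester3 is None:
        for s in unassigned:
            if any(
                _positive(matrix.get(s, t), score_pseudo_as)
                for t in unassigned
                if t != s
            ):
                tester3 = s
                break
    if tester3 is not None:
        testers.append(tester3)
        assignments[tester3] = A2B1  # convention: smallest recombinant is A2B1
        rounds[tester3] = 3
        for s in unassigned:
            if s != tester3 and _positive(matrix.get(tester3, s), score_pseudo_as):
                assignments[s] = A1B2
                rounds[s] = 3

    # exclusion step: leftovers observed against both parental classes but
    # mating with neither are recombinants of tester three's own class
    class_a1b1 = [s for s, mt in assignments.items() if mt == A1B1]
    class_a2b2 = [s for s, mt in assignments.items() if mt == A2B2]
    for s in sorted(s for s, mt in assignments.items() if mt is UNASSIGNED):
        obs1 = [matrix.get(s, t) for t in class_a1b1]
        obs2 = [matrix.get(s, t) for t in class_a2b2]
        seen1 = any(o is not Outcome.UNTESTED for o in obs1)
        seen2 = any(o is not Outcome.UNTESTED for o in obs2)
        mates_parental = any(_positive(o, score_pseudo_as) for o in obs1 + obs2)
        if seen1 and seen2 and not mates_parental:
            assignments[s] = A2B1
            rounds[s] = 3

    inconsistent = _cross_check(matrix, assignments)

    n_classes = len({str(mt) for mt in assignments.values() if mt is not None})
    if inconsistent:
        polarity = Polarity.INCONSISTENT
    elif n_classes > 2:
        # a class incompatible with both fully opposite parental classes
        # cannot exist under single-locus control
        polarity = Polarity.TETRAPOLAR
    else:
        polarity = Polarity.TWO_TYPES_UNDETERMINED

    return TypeAssignment(
        assignments=assignments,
        tester_ids=testers,
        polarity_call=polarity,
        round_assigned=rounds,
    )


def _cross_check(
    matrix: CompatibilityMatrix, assignments: dict[str, MatingType | None]
) -> bool:
    """True if any observed outcome contradicts the inferred types."""
    assigned = [s for s, mt in assignments.items() if mt is not None]
    for i, s1 in enumerate(assigned):
        for s2 in assigned[i + 1 :]:
            obs = matrix.get(s1, s2)
            if obs is Outcome.UNTESTED:
                continue
            mt1, mt2 = assignments[s1], assignments[s2]
            assert mt1 is not None and mt2 is not None
            a_diff, b_diff = mt1.differs_at(mt2)
            n_diff = int(a_diff) + int(b_diff)
            if obs is Outcome.CLAMP and n_diff != 2:
                return True
            if obs is Outcome.PSEUDO_CLAMP and n_diff != 1:
                return True
            if obs is Outcome.NONE and n_diff == 2:
                return True
    return False


def segregation_chi_square(
    counts: list[int] | tuple[int, ...],
    expected_ratio: list[int] | tuple[int, ...] = None,
    alpha: float = 0.05,
) -> SegregationTestResult:
    """Chi-squared goodness-of-fit test of observed class counts vs a ratio.

    ``chi2 = sum((obs_i - exp_i)^2 / exp_i)`` with ``exp_i = total *
    ratio_i / sum(ratio)``; no continuity correction; ``df = classes - 1``.
    The decision compares the statistic against the upper-alpha critical
    value (``reject`` iff ``chi2 > critical``), the convention used for
    Mendelian segregation tables.
    """
    counts = tuple(int(c) for c in counts)
    if expected_ratio is None:
        expected_ratio = (1,) * len(counts)
    expected_ratio = tuple(int(r) for r in expected_ratio)
    if len(counts) != len(expected_ratio) or len(counts) < 2:
        raise ValueError("counts and ratio must have equal length >= 2")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(r <= 0 for r in expected_ratio):
        raise ValueError("every ratio weight must be positive (expected count 0)")

    ratio_sum = sum(expected_ratio)
    expected = [total * r / ratio_sum for r in expected_ratio]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    df = len(counts) - 1
    crit = chi_square_critical(alpha, df)
    return SegregationTestResult(
        counts=counts,
        expected_ratio=expected_ratio,
        chi2=chi2,
        df=df,
        critical_value=crit,
        alpha=alpha,
        reject=chi2 > crit,
    )


def chi_square_critical(alpha: float, df: int) -> float:
    """Upper-``alpha`` quantile of the chi-squared distribution with ``df`` df."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.ppf(1.0 - alpha, df))
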