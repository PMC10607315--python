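"""Core domain types for mating-system inference.

A tetrapolar basidiomycete's mating type is the pair of alleles it carries at
the two unlinked incompatibility loci: the homeodomain (HD, "A") locus and the
pheromone/receptor (PR, "B") locus.  Two monokaryons form a true dikaryon —
scored by clamp connections — only when they differ at *both* loci.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "MatingType",
    "Origin",
    "Monokaryon",
    "Outcome",
    "CrossParameters",
    "CompatibilityMatrix",
    "Polarity",
    "TypeAssignment",
    "SegregationTestResult",
    "UNASSIGNED",
]

_MT_RE = re.compile(r"^(A\w+?)(B\w+)$")


@dataclass(frozen=True, order=True)
class MatingType:
    """An (A-allele, B-allele) label pair, e.g. ``MatingType("A1", "B2")``.

    The string form is the concatenation ``"A1B2"`` and round-trips through
    :meth:`parse`.
    """

    a_allele: str
    b_allele: str

    def __post_init__(self) -> None:
        if not self.a_allele.startswith("A") or not self.b_allele.startswith("B"):
            raise ValueError(
                f"allele labels must start with 'A'/'B': {self.a_allele!r}, {self.b_allele!r}"
            )

    def __str__(self) -> str:
        return f"{self.a_allele}{self.b_allele}"

    @classmethod
    def parse(cls, label: str) -> "MatingType":
        m = _MT_RE.match(label)
        if m is None:
            raise ValueError(f"not a mating-type label: {label!r}")
        return cls(m.group(1), m.group(2))

    def differs_at(self, other: "MatingType") -> tuple[bool, bool]:
        """(A-locus differs, B-locus differs) relative to ``other``."""
        return (self.a_allele != other.a_allele, self.b_allele != other.b_allele)


class Origin(enum.Enum):
    """How a monokaryon was obtained."""

    BASIDIOSPORE = "basidiospore"
    PROTOPLAST = "protoplast"


@dataclass(frozen=True)
class Monokaryon:
    """A haploid strain with a (ground-truth) mating type.

    The ``mating_type`` is simulation truth; inference code never reads it —
    it sees only the compatibility matrix.
    """

    strain_id: str
    mating_type: MatingType
    origin: Origin = Origin.BASIDIOSPORE


class Outcome(enum.Enum):
    """Observed result of pairing two monokaryons on a plate.

    ``CLAMP`` is the positive criterion (true dikaryon).  ``PSEUDO_CLAMP`` is
    the clamp-like appendage of a common-B pairing (A differs, B identical) —
    a known false-positive risk.  ``UNTESTED`` marks pairings never plated.
    """

    CLAMP = "CLAMP"
    PSEUDO_CLAMP = "PSEUDO"
    NONE = "NONE"
    UNTESTED = "NA"

    @classmethod
    def from_cell(cls, text: str) -> "Outcome":
        text = text.strip().upper()
        for o in cls:
            if o.value == text or o.name == text:
                return o
        raise ValueError(f"not a mating outcome: {text!r}")


@dataclass(frozen=True)
class CrossParameters:
    """Parameters of a simulated cross and its assay.

    recombination_fraction
        Probability of an A/B recombinant gamete; 0.5 models two unlinked
        loci (the tetrapolar case, loci on separate chromosomes).
    viability_weights
        One non-negative relative viability per mating type (renormalised
        internally); models differential germination / growth of spores.
    assay_false_positive
        Probability that a truly incompatible (NONE) pairing is misread as
        CLAMP.
    pseudo_clamp_misread
        Probability that a common-B pairing (PSEUDO_CLAMP) is misread as
        CLAMP — the pseudo-clamp false-positive phenomenon.
    """

    recombination_fraction: float = 0.5
    viability_weights: dict[MatingType, float] | None = None
    assay_false_positive: float = 0.0
    pseudo_clamp_misread: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.recombination_fraction <= 0.5:
            raise ValueError("recombination_fraction must lie in [0, 0.5]")
        for name in ("assay_false_positive", "pseudo_clamp_misread"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.viability_weights is not None:
            if any(w < 0 for w in self.viability_weights.values()):
                raise ValueError("viability weights must be non-negative")
            if sum(self.viability_weights.values()) <= 0:
                raise ValueError("viability weights must not all be zero")


class CompatibilityMatrix:
    """Symmetric strain-by-strain table of observed mating outcomes."""

    def __init__(self, strain_ids: list[str]):
        if len(set(strain_ids)) != len(strain_ids):
            raise ValueError("duplicate strain ids in compatibility matrix")
        self.strain_ids: list[str] = list(strain_ids)
        self._index = {s: i for i, s in enumerate(self.strain_ids)}
        n = len(strain_ids)
        self._cells: list[list[Outcome]] = [
            [Outcome.UNTESTED] * n for _ in range(n)
        ]
        for i in range(n):
            self._cells[i][i] = Outcome.NONE  # self-cross is incompatible

    def __len__(self) -> int:
        return len(self.strain_ids)

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self._index

    def get(self, s1: str, s2: str) -> Outcome:
        return self._cells[self._index[s1]][self._index[s2]]

    def set(self, s1: str, s2: str, outcome: Outcome) -> None:
        i, j = self._index[s1], self._index[s2]
        self._cells[i][j] = outcome
        self._cells[j][i] = outcome

    def partners(self, strain_id: str, outcome: Outcome) -> list[str]:
        """Strains whose pairing with ``strain_id`` was scored ``outcome``."""
        i = self._index[strain_id]
        return [
            s
            for j, s in enumerate(self.strain_ids)
            if j != i and self._cells[i][j] is outcome
        ]

    def is_symmetric(self) -> bool:
        n = len(self)
        return all(
            self._cells[i][j] is self._cells[j][i]
            for i in range(n)
            for j in range(i + 1, n)
        )


UNASSIGNED = None  # sentinel for strains the classifier could not type


class Polarity(enum.Enum):
    """Conclusion about the mating system drawn from a classification."""

    TETRAPOLAR = "TETRAPOLAR"
    TWO_TYPES_UNDETERMINED = "TWO_TYPES_UNDETERMINED"
    INCONSISTENT = "INCONSISTENT"


@dataclass
class TypeAssignment:
    """Result of classifying a compatibility matrix.

    ``assignments`` maps strain id to a :class:`MatingType` or ``None``
    (unassigned); ``round_assigned`` records in which round each strain was
    typed; ``tester_ids`` the tester strain used in each round.
    """

    assignments: dict[str, MatingType | None]
    tester_ids: list[str]
    polarity_call: Polarity
    round_assigned: dict[str, int] = field(default_factory=dict)

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for mt in self.assignments.values():
            if mt is not None:
                sizes[str(mt)] = sizes.get(str(mt), 0) + 1
        return sizes

    def partition(self) -> frozenset[frozenset[str]]:
        """The assigned strains grouped by type, as a label-free partition."""
        groups: dict[MatingType, set[str]] = {}
        for sid, mt in self.assignments.items():
            if mt is not None:
                groups.setdefault(mt, set()).add(sid)
        return frozenset(frozenset(g) for g in groups.values())


@dataclass(frozen=True)
class SegregationTestResult:
    """A chi-squared goodness-of-fit test of segregation counts vs a ratio."""

    counts: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi2: float
    df: int
    critical_value: float
    alpha: float
    reject: bool

    def __str__(self) -> str:
        verdict = "reject" if self.reject else "accept"
        ratio = ":".join(str(r) for r in self.expected_ratio)
        return (
            f"chi2={self.chi2:.3f} (df={self.df}, "
            f"crit_{self.alpha}={self.critical_value:.2f}) vs {ratio} -> {verdict}"
        )
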