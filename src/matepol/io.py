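"""Readers and writers shared by all stages, and the run configuration.

Matrix TSV layout: header row and first column are strain ids; cells are
CLAMP / PSEUDO / NONE / NA.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .effects import Windows
from .types import CompatibilityMatrix, Outcome, TypeAssignment

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_assignment_tsv",
    "RunConfig",
]


def write_matrix_tsv(matrix: CompatibilityMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(matrix.strain_ids) + "\n")
        for s1 in matrix.strain_ids:
            cells = [matrix.get(s1, s2).value for s2 in matrix.strain_ids]
            fh.write(s1 + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path) -> CompatibilityMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].rstrip("\n").split("\t")
    ids = header[1:]
    matrix = CompatibilityMatrix(ids)
    if len(lines) - 1 != len(ids):
        raise ValueError(
            f"{path}: {len(ids)} strains in header but {len(lines) - 1} data rows"
        )
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(ids) + 1:
            raise ValueError(f"{path}, line {ln}: expected {len(ids) + 1} columns")
        s1 = cells[0]
        for s2, cell in zip(ids, cells[1:]):
            try:
                outcome = Outcome.from_cell(cell)
            except ValueError as exc:
                raise ValueError(f"{path}, line {ln}: {exc}") from exc
            if s1 != s2:
                matrix.set(s1, s2, outcome)
    if not matrix.is_symmetric():
        raise ValueError(f"{path}: matrix is not symmetric")
    return matrix


def write_assignment_tsv(assignment: TypeAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\ttype\tround_assigned\n")
        for sid in sorted(assignment.assignments):
            mt = assignment.assignments[sid]
            fh.write(
                f"{sid}\t{mt if mt is not None else 'UNASSIGNED'}\t"
                f"{assignment.round_assigned.get(sid, '')}\n"
            )


@dataclass
class RunConfig:
    """Configuration of one pipeline run; JSON round-trippable."""

    seed: int = 0
    alpha: float = 0.05
    pseudo_policy: str = "INCOMPATIBLE"
    n_basidiospores: int = 246
    n_protoplasts: int = 77
    recombination_fraction: float = 0.5
    protoplast_bias: float = 0.5
    assay_false_positive: float = 0.0
    pseudo_clamp_misread: float = 0.0
    windows: Windows = field(default_factory=Windows)
    out_dir: str = "matepol_run"
    molecular: bool = True

    def __post_init__(self) -> None:
        if self.n_basidiospores < 1 or self.n_protoplasts < 1:
            raise ValueError("population sizes must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pseudo_policy not in ("COMPATIBLE", "INCOMPATIBLE"):
            raise ValueError("pseudo_policy must be COMPATIBLE or INCOMPATIBLE")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "windows" in d and isinstance(d["windows"], dict):
            d["windows"] = Windows(**d["windows"])
        return cls(**d)
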