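"""Pheromone-precursor candidate detection by motif rules.

Precursor genes are too divergent for homology search; candidates are short
proteins ending in a prenylation CAAX box — C, two aliphatic residues, then
a permissive X — with EA and AF dipeptides reported as auxiliary (never
required) evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = ["PrecursorHit", "scan_precursors", "DEFAULT_ALIPHATIC", "DEFAULT_X_SET"]

#: Aliphatic residues allowed at the two "A" positions of the CAAX box.
DEFAULT_ALIPHATIC = frozenset("AVLIG")
#: Residues allowed at the X position (the motif's X is open-ended; this set
#: covers the commonly reported ones and is configurable).
DEFAULT_X_SET = frozenset("ASMECQTN")

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PrecursorHit:
    """Motif-scan result for one protein."""

    protein_id: str
    length: int
    caax_position: int | None  # index of the C of a C-terminal CAAX box
    aux_motifs: tuple[tuple[str, int], ...] = field(default_factory=tuple)
    is_candidate: bool = False


def _iter_proteins(proteins) -> Iterable[tuple[str, str]]:
    if isinstance(proteins, (str, Path)):
        for rec in SeqIO.parse(str(proteins), "fasta"):
            yield rec.id, str(rec.seq)
    elif isinstance(proteins, Mapping):
        yield from proteins.items()
    else:  # sequence of SeqRecords or (id, seq) pairs
        for item in proteins:
            if hasattr(item, "id") and hasattr(item, "seq"):
                yield item.id, str(item.seq)
            else:
                yield item


def scan_precursors(
    proteins,
    max_len: int = 120,
    aliphatic: frozenset[str] | str = DEFAULT_ALIPHATIC,
    x_set: frozenset[str] | str = DEFAULT_X_SET,
) -> list[PrecursorHit]:
    """Scan proteins for pheromone-precursor candidates.

    A protein is a candidate iff its length is at most ``max_len`` and its
    C-terminal four residues match C-a-a-X with ``a`` in ``aliphatic`` and
    ``X`` in ``x_set``.  EA and AF dipeptide positions are recorded as
    auxiliary evidence only.  ``proteins`` may be a FASTA path, a mapping
    id -> sequence, or an iterable of SeqRecords / (id, seq) pairs;
    trailing stop characters are stripped.
    """
    aliphatic = frozenset(aliphatic)
    x_set = frozenset(x_set)
    hits: list[PrecursorHit] = []
    for pid, seq in _iter_proteins(proteins):
        seq = str(seq).upper().rstrip("*")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {pid!r} has non-amino-acid characters: {sorted(bad)}"
            )
        aux = tuple(
            (motif, i)
            for motif in ("EA", "AF")
            for i in range(len(seq) - 1)
            if seq[i : i + 2] == motif
        )
        caax_pos: int | None = None
        if len(seq) >= 4:
            c, a1, a2, x = seq[-4:]
            if c == "C" and a1 in aliphatic and a2 in aliphatic and x in x_set:
                caax_pos = len(seq) - 4
        hits.append(
            PrecursorHit(
                protein_id=pid,
                length=len(seq),
                caax_position=caax_pos,
                aux_motifs=aux,
                is_candidate=caax_pos is not None and len(seq) <= max_len,
            )
        )
    return hits
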