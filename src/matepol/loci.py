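"""Mating-locus architecture from gene annotations.

The HD (A) locus is recognised as a divergently transcribed, head-to-head
HD1/HD2 gene pair flanked by beta-fg on the HD1 side and MIP on the HD2
side, with HD1 and MIP sharing a coding direction.  The PR (B) locus is the
minimal window holding every pheromone-receptor (PR) and pheromone-precursor
(PP) gene of one replicon; its span runs from the first gene's start to the
last gene's end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genemodel import GeneModel, Role

__all__ = ["LocusModel", "identify_locus_A", "identify_locus_B"]


@dataclass
class LocusModel:
    """An identified mating locus: its genes in genomic order and its span."""

    locus_name: str  # "A" or "B"
    genes: list[GeneModel]
    span_bp: int
    notes: dict = field(default_factory=dict)

    @property
    def gene_order(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def _five_prime(g: GeneModel) -> int:
    return g.start if g.strand == "+" else g.end


def identify_locus_A(annotation: list[GeneModel]) -> LocusModel:
    """Locate the HD locus from role-labelled gene models.

    Requires a unique adjacent HD1/HD2 pair transcribed head-to-head
    (divergently: their 5' ends face each other and transcription runs
    outward), with beta-fg next to HD1, MIP next to HD2, and HD1/MIP on the
    same strand.  Multiple candidate windows are an error, reported rather
    than silently resolved.
    """
    by_seq: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_seq.setdefault(g.seq_id, []).append(g)

    candidates: list[list[GeneModel]] = []
    problems: list[str] = []
    saw_pair = False
    for seq_id, genes in by_seq.items():
        genes = sorted(genes, key=lambda g: g.start)
        for i in range(len(genes) - 1):
            left, right = genes[i], genes[i + 1]
            roles = {left.role_label, right.role_label}
            if roles != {Role.HD1, Role.HD2}:
                continue
            saw_pair = True
            if left.strand == right.strand:
                problems.append(
                    f"{seq_id}: HD pair {left.gene_id}/{right.gene_id} on the "
                    "same strand (head-to-head violation)"
                )
                continue
            # divergent transcription: both 5' ends in the middle
            if not (left.strand == "-" and right.strand == "+"):
                problems.append(
                    f"{seq_id}: HD pair {left.gene_id}/{right.gene_id} is "
                    "convergent, not head-to-head"
                )
                continue
            hd1, hd2 = (left, right) if left.role_label is Role.HD1 else (right, left)
            before = genes[i - 1] if i - 1 >= 0 else None
            after = genes[i + 2] if i + 2 < len(genes) else None
            hd1_side = before if hd1 is left else after
            hd2_side = before if hd2 is left else after
            if hd1_side is None or hd1_side.role_label is not Role.BETA_FG:
                problems.append(f"{seq_id}: flank incomplete — no beta-fg beside {hd1.gene_id}")
                continue
            if hd2_side is None or hd2_side.role_label is not Role.MIP:
                problems.append(f"{seq_id}: flank incomplete — no MIP beside {hd2.gene_id}")
                continue
            if hd1.strand != hd2_side.strand:
                # MIP must share HD1's coding direction
                problems.append(
                    f"{seq_id}: HD1 ({hd1.strand}) and MIP ({hd2_side.strand}) "
                    "do not share a coding direction"
                )
                continue
            window = sorted([hd1_side, hd1, hd2, hd2_side], key=lambda g: g.start)
            candidates.append(window)

    if not candidates:
        if problems:
            raise ValueError("no valid HD locus: " + "; ".join(problems))
        raise ValueError(
            "no adjacent HD1/HD2 pair found" if not saw_pair else "no HD locus found"
        )
    if len(candidates) > 1:
        descr = ", ".join("[" + ">".join(g.gene_id for g in w) + "]" for w in candidates)
        raise ValueError(f"multiple candidate HD-locus windows: {descr}")

    window = candidates[0]
    return LocusModel(
        locus_name="A",
        genes=window,
        span_bp=window[-1].end - window[0].start,
    )


def identify_locus_B(annotation: list[GeneModel]) -> LocusModel:
    """Locate the PR locus: the minimal window of all PR and PP genes.

    All PR and PP genes must lie on one replicon.  The span runs from the
    first gene's start to the last gene's end; the gap between the PR gene
    block (the PR "sublocus") and the first and last PP genes is reported in
    ``notes`` as a descriptive quantity.
    """
    prs = [g for g in annotation if g.role_label is Role.PR]
    pps = [g for g in annotation if g.role_label is Role.PP]
    if not prs or not pps:
        raise ValueError("locus B needs at least one PR and one PP gene")
    replicons = {g.seq_id for g in prs + pps}
    if len(replicons) > 1:
        raise ValueError(
            f"PR and PP genes on different replicons: {sorted(replicons)}"
        )
    genes = sorted(prs + pps, key=lambda g: g.start)
    pr_start = min(g.start for g in prs)
    pr_end = max(g.end for g in prs)
    first, last = genes[0], genes[-1]
    return LocusModel(
        locus_name="B",
        genes=genes,
        span_bp=last.end - first.start,
        notes={
            "n_pr": len(prs),
            "n_pp": len(pps),
            "pr_sublocus": (pr_start, pr_end),
            "pr_sublocus_to_first_pp_bp": pr_start - min(g.start for g in pps),
            "pr_sublocus_to_last_pp_bp": max(g.end for g in pps) - pr_end,
        },
    )
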