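"""End-to-end demonstration pipeline.

Simulates basidiospore and protoplast populations, classifies them from
their compatibility matrices, runs the segregation chi-squared tests
(including the in-study count tables), and — on the toy genome — annotates
the per-group variants and assigns the reference strain's mating type.
All results are collected into one JSON report.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

from . import __version__
from .effects import assign_reference_type, group_effect_profile
from .genome import generate_toy_mating_genome
from .inference import segregation_chi_square, test_cross_classify, three_round_classify
from .io import RunConfig, write_assignment_tsv, write_matrix_tsv
from .simulate import build_compatibility_matrix, simulate_meiosis, simulate_protoplasting
from .types import CrossParameters, MatingType, Polarity

__all__ = ["run_pipeline"]

# segregation count tables observed in the study this package models
TESTCROSS_COUNTS = (45, 32)
THREE_ROUND_COUNTS = {
    "four_type_97_111_13_25": (97, 111, 13, 25),
    "two_type_83_40": (83, 40, 0, 0),
}


def _chisq_entry(result) -> dict:
    return {
        "counts": list(result.counts),
        "ratio": list(result.expected_ratio),
        "chi2": round(result.chi2, 4),
        "df": result.df,
        "critical_value": round(result.critical_value, 4),
        "reject": result.reject,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> classify -> chisq -> annotate -> assign-type.

    Writes matrices, assignments and a single ``report.json`` under
    ``config.out_dir`` and returns the report dict.  The report's
    ``exit_status`` is nonzero when any classification is INCONSISTENT.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    a1b1, a2b2 = MatingType("A1", "B1"), MatingType("A2", "B2")
    params = CrossParameters(
        recombination_fraction=config.recombination_fraction,
        assay_false_positive=config.assay_false_positive,
        pseudo_clamp_misread=config.pseudo_clamp_misread,
        seed=config.seed,
    )

    # basidiospore population (four types expected at r = 0.5)
    spores = simulate_meiosis(a1b1, a2b2, config.n_basidiospores, params, id_prefix="Q-")
    spore_matrix = build_compatibility_matrix(spores, params)
    write_matrix_tsv(spore_matrix, out / "basidiospore_matrix.tsv")
    spore_call = three_round_classify(spore_matrix, config.pseudo_policy)
    write_assignment_tsv(spore_call, out / "basidiospore_types.tsv")
    counts = spore_call.class_sizes()
    report["basidiospore"] = {
        "n": config.n_basidiospores,
        "class_sizes": counts,
        "polarity": spore_call.polarity_call.value,
        "testers": spore_call.tester_ids,
        "chisq_1111": _chisq_entry(
            segregation_chi_square(
                [counts.get(t, 0) for t in ("A1B1", "A2B2", "A2B1", "A1B2")],
                (1, 1, 1, 1),
                config.alpha,
            )
        ),
    }

    # protoplast population (parental types only)
    protoplasts = simulate_protoplasting(
        a1b1, a2b2, config.n_protoplasts, config.protoplast_bias, seed=config.seed
    )
    proto_matrix = build_compatibility_matrix(protoplasts, params)
    write_matrix_tsv(proto_matrix, out / "protoplast_matrix.tsv")
    tester = protoplasts[0].strain_id
    proto_call = test_cross_classify(
        proto_matrix, tester, a1b1, config.pseudo_policy
    )
    write_assignment_tsv(proto_call, out / "protoplast_types.tsv")
    proto_sizes = proto_call.class_sizes()
    report["protoplast"] = {
        "n": config.n_protoplasts,
        "tester": tester,
        "class_sizes": proto_sizes,
        "chisq_11": _chisq_entry(
            segregation_chi_square(
                [proto_sizes.get("A1B1", 0), proto_sizes.get("A2B2", 0)],
                (1, 1),
                config.alpha,
            )
        ),
    }

    # the study's own count tables
    report["reference_tables"] = {
        "testcross_45_32": _chisq_entry(
            segregation_chi_square(TESTCROSS_COUNTS, (1, 1), config.alpha)
        ),
        **{
            name: _chisq_entry(segregation_chi_square(c, (1, 1, 1, 1), config.alpha))
            for name, c in THREE_ROUND_COUNTS.items()
        },
    }

    if config.molecular:
        fixture = generate_toy_mating_genome(out / "toy_genome", seed=config.seed)
        profile = group_effect_profile(
            fixture.vcfs, fixture.genes, fixture.genome, config.windows
        )
        call = assign_reference_type(profile, fixture.group_types)
        report["molecular"] = {
            "locus_A_counts": dict(call.locus_a.impactful_counts),
            "locus_B_counts": dict(call.locus_b.impactful_counts),
            "locus_A_shared_with": call.locus_a.shared_with,
            "locus_B_shared_with": call.locus_b.shared_with,
            "reference_type": str(call.mating_type) if call.mating_type else None,
            "planted_reference_type": str(fixture.reference_type),
        }

    inconsistent = spore_call.polarity_call is Polarity.INCONSISTENT
    report["exit_status"] = 1 if inconsistent else 0
    (out / "config.json").write_text(config.to_json() + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def main(config: RunConfig) -> int:
    report = run_pipeline(config)
    json.dump(report, sys.stdout, indent=2, sort_keys=True)
    sys.stdout.write("\n")
    return int(report["exit_status"])
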