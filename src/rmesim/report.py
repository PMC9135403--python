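"""Built-in reproduction suite: closed-form worked examples re-derived by
simulation, plus the core model invariants, assembled into a pass/fail
report.  Used by the ``repro`` CLI subcommand."""

from __future__ import annotations

import math
from typing import Any

import numpy as np

from . import inference, model, simulate

__all__ = ["run_reproduction_suite"]


def _check(name: str, value: float, expected: float, tol: float) -> dict[str, Any]:
    return {
        "check": name,
        "value": value,
        "expected": expected,
        "tolerance": tol,
        "pass": bool(abs(value - expected) <= tol),
    }


def _hemizygote_genotype(p: float) -> model.GenotypeConfig:
    gene = model.GeneModel(
        gene_id="Klrk1",
        alleles=(
            model.AlleleModel("Klrk1.func", p),
            model.AlleleModel("Klrk1.null", 0.0, allele_class="knockout"),
        ),
    )
    return model.GenotypeConfig(genes=(gene,), label="hemizygote")


def run_reproduction_suite(seed: int = 0) -> dict[str, Any]:
    """Run the bundled worked-example and invariant checks.

    Deterministic given ``seed``.  Returns a JSON-ready report; overall
    ``pass`` is the conjunction of all checks.
    """
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    checks: list[dict[str, Any]] = []

    # square-root rule: 67% homozygote-positive predicts ~43% in the hemizygote
    p_hemi = inference.expected_hemizygote_fraction(0.67)
    checks.append(_check("hemizygote_expected_percent_from_67", round(100 * p_hemi), 43, 0))

    # per-allele failure rate 2.5% -> 0.0625% double-negative
    q, dbl = inference.failure_rate_from_het(0.025)
    checks.append(_check("double_failure_percent_from_2p5", 100 * dbl, 0.0625, 1e-12))

    # cis-hypomorph scaling: complement of s = 0.477 is 0.523
    checks.append(_check("hypomorph_scaling_complement", 1.0 - 0.477, 0.523, 1e-12))

    # simulation twin of the square-root rule at n = 200,000
    p = model.allele_prob_from_homozygote(0.67)
    pop = simulate.simulate_population(_hemizygote_genotype(p), 200_000, seed=rng_seed)
    frac = float(pop.gene_positive_mask("Klrk1").mean())
    checks.append(_check("hemizygote_simulated_percent", 100 * frac, 100 * p, 0.5))

    # product rule ties closed form to simulation
    g1 = model.GeneModel(
        "A", (model.AlleleModel("A.1", 0.4255), model.AlleleModel("A.2", 0.4255))
    )
    g2 = model.GeneModel(
        "B", (model.AlleleModel("B.1", 0.2254), model.AlleleModel("B.2", 0.2254))
    )
    gt = model.GenotypeConfig(genes=(g1, g2), label="two_gene")
    pop2 = simulate.simulate_population(gt, 200_000, seed=rng_seed + 1)
    co = simulate.coexpression_fraction(pop2, ["A", "B"])
    exp_co = inference.product_rule_expected(
        [model.gene_positive_fraction(g1), model.gene_positive_fraction(g2)]
    )
    se = math.sqrt(exp_co * (1 - exp_co) / pop2.n_cells)
    checks.append(_check("product_rule_coexpression", co, exp_co, 3 * se))

    # mitotic stability: zero-switch-rate expansion preserves every state
    sorted_pos = simulate.gate_population(pop, "Klrk1", mode="positive")
    expanded = simulate.expand_clones(
        sorted_pos.subset(np.arange(min(1000, sorted_pos.n_cells))),
        simulate.ExpansionParams(generations=5),
    )
    retention = float(expanded.gene_positive_mask("Klrk1").mean())
    checks.append(_check("expansion_phenotype_retention", retention, 1.0, 0.0))

    report = {
        "seed": seed,
        "checks": checks,
        "pass": all(c["pass"] for c in checks),
    }
    return report
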