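"""Stochastic single-cell engine for binary allelic activation.

Generates populations of cells whose allelic ON/OFF states are drawn
independently Bernoulli(p) per allele, then emulates the downstream
experimental manipulations: FACS gating on expression phenotype (with
imperfect sort purity) and clonal expansion with optional per-division
state switching (default zero — mitotically stable inheritance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GenotypeConfig, QuadrantFrequencies

__all__ = [
    "CellPopulation",
    "ExpansionParams",
    "simulate_population",
    "gate_population",
    "expand_clones",
    "empirical_quadrants",
    "coexpression_fraction",
    "fold_to_generations",
    "save_population",
]

#: hard guard against runaway expansion (cells, not matrix entries)
DEFAULT_CELL_CAP = 50_000_000

GATE_MODES = ("positive", "negative", "quadrant")
QUADRANT_NAMES = ("neither", "first_only", "second_only", "both")


@dataclass
class CellPopulation:
    """Cells x alleles binary state matrix with genotype metadata.

    ``states[i, j] == 1`` iff allele ``j`` is ON in cell ``i``;
    ``allele_index[j]`` is the ``(gene_id, allele_id)`` pair for column
    ``j``.  ``lineage_id`` (optional) labels each cell's founding clone
    through gating/expansion.
    """

    states: np.ndarray
    allele_index: tuple[tuple[str, str], ...]
    genotype: GenotypeConfig | None = None
    seed: int | None = None
    lineage_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D cells x alleles matrix")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states entries must be 0 or 1")
        self.allele_index = tuple((str(g), str(a)) for g, a in self.allele_index)
        if self.states.shape[1] != len(self.allele_index):
            raise ValueError("states columns must match allele_index")
        if self.lineage_id is not None:
            self.lineage_id = np.asarray(self.lineage_id)
            if len(self.lineage_id) != self.n_cells:
                raise ValueError("lineage_id length must match n_cells")

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    def gene_columns(self, gene_id: str) -> list[int]:
        cols = [j for j, (g, _) in enumerate(self.allele_index) if g == gene_id]
        if not cols:
            known = sorted({g for g, _ in self.allele_index})
            raise KeyError(f"gene {gene_id!r} not in population (has {known})")
        return cols

    def gene_positive_mask(self, gene_id: str) -> np.ndarray:
        """Boolean mask of cells expressing >= 1 allele of ``gene_id``."""
        return self.states[:, self.gene_columns(gene_id)].any(axis=1)

    def subset(self, index: np.ndarray) -> "CellPopulation":
        return CellPopulation(
            states=self.states[index],
            allele_index=self.allele_index,
            genotype=self.genotype,
            seed=self.seed,
            lineage_id=None if self.lineage_id is None else self.lineage_id[index],
        )


@dataclass(frozen=True)
class ExpansionParams:
    """Clonal-expansion settings.

    ``generations`` synchronous doublings; per division each allele may
    flip ON->OFF or OFF->ON with the given probabilities.  Both default to
    0: expression phenotypes observed after sort-and-expand experiments
    are stable through extensive proliferation.
    """

    generations: int
    switch_on_to_off: float = 0.0
    switch_off_to_on: float = 0.0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("switch_on_to_off", "switch_off_to_on"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v:g} must lie in [0, 1]")


def fold_to_generations(fold: float) -> int:
    """Convert a reported fold-expansion to doubling generations (ceil log2)."""
    if fold < 1:
        raise ValueError("fold expansion must be >= 1")
    return math.ceil(math.log2(fold)) if fold > 1 else 0


def simulate_population(
    genotype: GenotypeConfig, n_cells: int, seed: int
) -> CellPopulation:
    """Draw a population of cells from a genotype's activation probabilities.

    Each allele of each cell is an independent Bernoulli(p) draw; identical
    (genotype, n_cells, seed) reproduces the matrix bit-exactly.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [a.activation_probability for g in genotype.genes for a in g.alleles]
    )
    allele_index = tuple(
        (g.gene_id, a.allele_id) for g in genotype.genes for a in g.alleles
    )
    states = (rng.random((n_cells, len(probs))) < probs).astype(np.uint8)
    return CellPopulation(
        states=states,
        allele_index=allele_index,
        genotype=genotype,
        seed=seed,
        lineage_id=np.arange(n_cells),
    )


def _gate_mask(
    pop: CellPopulation, gene_id: str, mode: str, quadrant: str | None
) -> np.ndarray:
    if mode == "positive":
        return pop.gene_positive_mask(gene_id)
    if mode == "negative":
        return ~pop.gene_positive_mask(gene_id)
    if mode == "quadrant":
        cols = pop.gene_columns(gene_id)
        if len(cols) != 2:
            raise ValueError(f"quadrant gate needs a two-allele gene, {gene_id!r} has {len(cols)}")
        if quadrant not in QUADRANT_NAMES:
            raise ValueError(f"quadrant must be one of {QUADRANT_NAMES}, got {quadrant!r}")
        a1 = pop.states[:, cols[0]].astype(bool)
        a2 = pop.states[:, cols[1]].astype(bool)
        return {
            "neither": ~a1 & ~a2,
            "first_only": a1 & ~a2,
            "second_only": ~a1 & a2,
            "both": a1 & a2,
        }[quadrant]
    raise ValueError(f"mode must be one of {GATE_MODES}, got {mode!r}")


def gate_population(
    pop: CellPopulation,
    gene: str,
    mode: str = "positive",
    purity: float = 1.0,
    seed: int | None = None,
    quadrant: str | None = None,
) -> CellPopulation:
    """FACS-style sort on an expression phenotype.

    Returns the cells matching the gate; with ``purity < 1`` a binomial
    fraction ``1 - purity`` of the returned cells is replaced by uniform
    draws (with replacement) from the complementary population, modelling
    post-sort contamination.
    """
    if not (0.5 < purity <= 1.0):
        raise ValueError(f"purity={purity:g} must lie in (0.5, 1]")
    mask = _gate_mask(pop, gene, mode, quadrant)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        gate = mode if mode != "quadrant" else f"quadrant={quadrant}"
        raise ValueError(f"gate '{gene}:{gate}' matches no cells in the source population")
    out = pop.subset(idx)
    if purity < 1.0:
        comp = np.flatnonzero(~mask)
        if comp.size:
            rng = np.random.default_rng(seed)
            n_contam = rng.binomial(out.n_cells, 1.0 - purity)
            if n_contam:
                positions = rng.choice(out.n_cells, size=n_contam, replace=False)
                donors = rng.choice(comp, size=n_contam, replace=True)
                out.states[positions] = pop.states[donors]
                if out.lineage_id is not None and pop.lineage_id is not None:
                    out.lineage_id[positions] = pop.lineage_id[donors]
    return out


def expand_clones(
    pop: CellPopulation,
    params: ExpansionParams,
    seed: int | None = None,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> CellPopulation:
    """Clonally expand by synchronous doubling with optional state switching.

    Output size is ``n_cells * 2**generations``.  With both switch rates
    zero every descendant inherits its ancestor's allelic states exactly
    (no RNG consumed), reproducing the mitotic stability seen when sorted
    positive/negative populations are re-expanded.
    """
    final = pop.n_cells * (2 ** params.generations)
    if final > cell_cap:
        raise ValueError(
            f"expansion to {final} cells exceeds cap {cell_cap}; "
            "raise cell_cap explicitly if intended"
        )
    states = pop.states
    lineage = pop.lineage_id
    switching = params.switch_on_to_off > 0 or params.switch_off_to_on > 0
    rng = np.random.default_rng(seed) if switching else None
    for _ in range(params.generations):
        states = np.repeat(states, 2, axis=0)
        if lineage is not None:
            lineage = np.repeat(lineage, 2)
        if switching:
            u = rng.random(states.shape)
            on = states == 1
            flip = np.where(u < np.where(on, params.switch_on_to_off,
                                         params.switch_off_to_on), 1, 0)
            states = states ^ flip.astype(np.uint8)
    return CellPopulation(
        states=states,
        allele_index=pop.allele_index,
        genotype=pop.genotype,
        seed=pop.seed,
        lineage_id=lineage,
    )


def empirical_quadrants(
    pop: CellPopulation, gene: str
) -> tuple[QuadrantFrequencies, tuple[int, int, int, int]]:
    """Observed quadrant frequencies and counts for a two-allele gene."""
    if pop.n_cells == 0:
        raise ValueError("cannot compute quadrants of an empty population")
    cols = pop.gene_columns(gene)
    if len(cols) != 2:
        raise ValueError(f"gene {gene!r} has {len(cols)} alleles in this population, need 2")
    a1 = pop.states[:, cols[0]].astype(bool)
    a2 = pop.states[:, cols[1]].astype(bool)
    counts = (
        int((~a1 & ~a2).sum()),
        int((a1 & ~a2).sum()),
        int((~a1 & a2).sum()),
        int((a1 & a2).sum()),
    )
    n = pop.n_cells
    freqs = QuadrantFrequencies(*(c / n for c in counts))
    return freqs, counts


def coexpression_fraction(pop: CellPopulation, genes: Sequence[str]) -> float:
    """Fraction of cells positive for every listed gene (>= 2 genes)."""
    if len(genes) < 2:
        raise ValueError("co-expression requires at least two genes")
    if pop.n_cells == 0:
        raise ValueError("empty population")
    mask = np.ones(pop.n_cells, dtype=bool)
    for g in genes:
        mask &= pop.gene_positive_mask(g)
    return float(mask.mean())


def save_population(pop: CellPopulation, outdir: str | Path) -> None:
    """Serialise to ``population.tsv`` plus a ``population.json`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = {f"{g}.{a}": pop.states[:, j] for j, (g, a) in enumerate(pop.allele_index)}
    df = pd.DataFrame({"cell_id": np.arange(pop.n_cells), **cols})
    if pop.lineage_id is not None:
        df["lineage_id"] = pop.lineage_id
    df.to_csv(outdir / "population.tsv", sep="\t", index=False)
    meta = {
        "n_cells": pop.n_cells,
        "seed": pop.seed,
        "allele_index": [list(pair) for pair in pop.allele_index],
        "genotype_label": pop.genotype.label if pop.genotype else None,
        "activation_probabilities": (
            {
                f"{g.gene_id}.{a.allele_id}": a.activation_probability
                for g in pop.genotype.genes
                for a in g.alleles
            }
            if pop.genotype
            else None
        ),
    }
    (outdir / "population.json").write_text(json.dumps(meta, indent=2))
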