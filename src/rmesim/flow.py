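"""Synthetic flow cytometry: render allelic states as staining intensities.

Turns binary cell populations into flow-cytometry-like event tables so the
whole inference pipeline can be exercised without any measured data.  Each
marker (an antibody) maps either to a single allele (allele-specific
clone) or to a gene's allele union (pan clone); per-cell intensities are
log-normal, with the negative and positive components separated on the
log scale and biallelic cells brighter by a configurable factor, mirroring
the modest MFI shift of cells expressing both alleles.  Gating recovers
calls and quadrant frequencies from thresholds, as in quadrant analysis of
two-colour allele-specific stains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, GenotypeConfig, QuadrantFrequencies
from .simulate import CellPopulation, empirical_quadrants, simulate_population

__all__ = [
    "MarkerParams",
    "StainingModel",
    "allele_staining_model",
    "render_events",
    "gate_events",
    "generate_cohort",
]


@dataclass(frozen=True)
class MarkerParams:
    """Staining behaviour of one antibody.

    ``gene`` plus ``allele_id`` target a single allele (allele-specific
    clone); ``allele_id=None`` targets the gene union (pan clone).
    Intensities are log-normal: log-intensity is drawn Normal(mu, log_sd)
    with ``mu = negative_log_mean`` when no targeted allele is ON and
    ``positive_log_mean`` otherwise; cells with two targeted alleles ON
    are brighter by ``allele_count_scaling`` (multiplicative on intensity,
    i.e. additive log(scaling) on the log scale).
    """

    gene: str
    allele_id: str | None = None
    negative_log_mean: float = 4.0
    positive_log_mean: float = 8.0
    log_sd: float = 0.5
    allele_count_scaling: float = 2.0

    def __post_init__(self) -> None:
        if self.positive_log_mean <= self.negative_log_mean:
            raise ValueError("positive_log_mean must exceed negative_log_mean")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.allele_count_scaling < 1:
            raise ValueError("allele_count_scaling must be >= 1")

    @property
    def default_threshold(self) -> float:
        """Midpoint threshold on the intensity scale (geometric mean of
        the two component medians)."""
        return math.exp(0.5 * (self.negative_log_mean + self.positive_log_mean))


@dataclass(frozen=True)
class StainingModel:
    """Named markers with their staining parameters."""

    markers: Mapping[str, MarkerParams]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", dict(self.markers))
        if not self.markers:
            raise ValueError("staining model needs at least one marker")


def allele_staining_model(gene: GeneModel, **params) -> StainingModel:
    """One allele-specific marker per allele of ``gene`` (two-colour stain)."""
    return StainingModel(
        {
            f"{gene.gene_id}.{a.allele_id}": MarkerParams(
                gene=gene.gene_id, allele_id=a.allele_id, **params
            )
            for a in gene.alleles
        }
    )


def _target_columns(pop: CellPopulation, params: MarkerParams) -> list[int]:
    if params.allele_id is None:
        return pop.gene_columns(params.gene)
    cols = [
        j
        for j, (g, a) in enumerate(pop.allele_index)
        if g == params.gene and a == params.allele_id
    ]
    if not cols:
        raise KeyError(
            f"marker target {params.gene}.{params.allele_id} not in population"
        )
    return cols


def render_events(
    pop: CellPopulation,
    model: StainingModel,
    seed: int | None = None,
    keep_truth: bool = True,
) -> pd.DataFrame:
    """Render a population into a flow-event table.

    One row per cell: ``cell_id``, an intensity column per marker, and
    (unless ``keep_truth=False``) a hidden ``truth_<marker>`` column with
    the number of targeted alleles that are ON — retained for testing and
    stripped when emulating blinded data.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {"cell_id": np.arange(pop.n_cells)}
    truth_cols: dict[str, np.ndarray] = {}
    for name, params in model.markers.items():
        cols = _target_columns(pop, params)
        active = pop.states[:, cols].sum(axis=1).astype(np.int64)
        mu = np.where(active == 0, params.negative_log_mean, params.positive_log_mean)
        mu = mu + np.where(active >= 2, math.log(params.allele_count_scaling), 0.0)
        out[name] = np.exp(rng.normal(mu, params.log_sd))
        truth_cols[f"truth_{name}"] = active
    if keep_truth:
        out.update(truth_cols)
    return pd.DataFrame(out)


def gate_events(
    events: pd.DataFrame,
    thresholds: Mapping[str, float],
    quadrant_markers: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, QuadrantFrequencies]:
    """Threshold-gate an event table.

    A cell is called positive for a marker when its intensity exceeds the
    marker's threshold.  Quadrant frequencies are computed from the two
    allele-specific markers given in ``quadrant_markers`` (first/second
    allele order); defaults to the two thresholded markers when exactly
    two are supplied.
    """
    for m, t in thresholds.items():
        if m not in events.columns:
            raise KeyError(f"marker {m!r} missing from event table")
        if t <= 0:
            raise ValueError(f"threshold for {m!r} must be positive")
    calls = events[["cell_id"]].copy()
    for m, t in thresholds.items():
        calls[f"call_{m}"] = (events[m].to_numpy() > t).astype(np.uint8)
    if quadrant_markers is None:
        if len(thresholds) != 2:
            raise ValueError(
                "quadrant_markers must be given unless exactly two markers are gated"
            )
        quadrant_markers = tuple(thresholds)  # type: ignore[assignment]
    m1, m2 = quadrant_markers
    a1 = calls[f"call_{m1}"].to_numpy().astype(bool)
    a2 = calls[f"call_{m2}"].to_numpy().astype(bool)
    n = len(calls)
    if n == 0:
        raise ValueError("empty event table")
    quads = QuadrantFrequencies(
        neither=float((~a1 & ~a2).mean()),
        first_only=float((a1 & ~a2).mean()),
        second_only=float((~a1 & a2).mean()),
        both=float((a1 & a2).mean()),
    )
    return calls, quads


def _jittered_genotype(
    genotype: GenotypeConfig, jitter_sd: float, rng: np.random.Generator
) -> GenotypeConfig:
    """Per-mouse biological variation: logit-normal jitter on each allele's p.

    Degenerate probabilities (0 or 1) are left untouched — a null allele
    stays null in every animal.
    """
    from dataclasses import replace

    genes = []
    for gene in genotype.genes:
        alleles = []
        for a in gene.alleles:
            p = a.activation_probability
            if jitter_sd > 0 and 0.0 < p < 1.0:
                logit = math.log(p / (1.0 - p)) + rng.normal(0.0, jitter_sd)
                p = 1.0 / (1.0 + math.exp(-logit))
            alleles.append(replace(a, activation_probability=p))
        genes.append(GeneModel(gene_id=gene.gene_id, alleles=(alleles[0], alleles[1])))
    return GenotypeConfig(genes=tuple(genes), label=genotype.label)


def generate_cohort(
    genotypes: Sequence[GenotypeConfig],
    mice_per_genotype: int,
    n_cells: int,
    seed: int,
    jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate a littermate cohort; one inference-ready row per mouse per gene.

    Columns match the frequency-table schema: ``sample_id, genotype, gene,
    neither, first_only, second_only, both, n_cells``.  ``jitter_sd``
    (logit-scale SD, default 0) adds mouse-to-mouse variation in p.
    """
    if mice_per_genotype < 0 or n_cells <= 0:
        raise ValueError("need mice_per_genotype >= 0 and n_cells > 0")
    seeds = np.random.SeedSequence(seed).spawn(max(len(genotypes) * mice_per_genotype, 1))
    rows = []
    k = 0
    for genotype in genotypes:
        for mouse in range(mice_per_genotype):
            ss = seeds[k]
            k += 1
            rng = np.random.default_rng(ss)
            gt = _jittered_genotype(genotype, jitter_sd, rng)
            pop = simulate_population(
                gt, n_cells, seed=int(ss.generate_state(1)[0] % (2**31))
            )
            for gene in gt.genes:
                freqs, _ = empirical_quadrants(pop, gene.gene_id)
                rows.append(
                    {
                        "sample_id": f"{genotype.label or 'gt'}_{mouse + 1}",
                        "genotype": genotype.label,
                        "gene": gene.gene_id,
                        "neither": freqs.neither,
                        "first_only": freqs.first_only,
                        "second_only": freqs.second_only,
                        "both": freqs.both,
                        "n_cells": n_cells,
                    }
                )
    columns = [
        "sample_id", "genotype", "gene",
        "neither", "first_only", "second_only", "both", "n_cells",
    ]
    return pd.DataFrame(rows, columns=columns)
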