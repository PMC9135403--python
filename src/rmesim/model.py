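"""Binary, independent, cis-acting model of allelic gene activation.

Random monoallelic expression (RME) of NK-cell receptor genes is modelled
as a per-allele Bernoulli event: each allele of a gene is stably switched
ON with probability ``p`` (set in cis by its enhancer complement and in
trans by genetic background), independently of the other allele and of all
other genes.  A cell population is then characterised by four quadrant
fractions — cells expressing neither allele, only the first, only the
second, or both — which under independence are products of the per-allele
probabilities.  The complement ``q = 1 - p`` is the allelic failure rate.

This module holds the domain types and the closed-form probability
calculus; stochastic realisations live in :mod:`rmesim.simulate`.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "AlleleClass",
    "AlleleModel",
    "GeneModel",
    "GenotypeConfig",
    "QuadrantFrequencies",
    "FrequencyEstimate",
    "gene_positive_fraction",
    "allele_prob_from_homozygote",
    "double_failure_fraction",
    "quadrant_expected",
    "allele_probs_from_quadrants",
    "activation_from_enhancers",
    "read_genotype_config",
    "write_genotype_config",
]

#: inputs within this distance outside [0,1] are treated as measurement
#: noise and clipped (with a warning); anything further out is an error.
CLIP_TOLERANCE = 0.01


def as_proportion(x: float, name: str = "value", clip_tol: float = CLIP_TOLERANCE) -> float:
    """Validate a proportion, clipping marginal out-of-range noise.

    Values in ``[-clip_tol, 1 + clip_tol]`` are clipped into [0, 1] with a
    warning; values further outside raise :class:`ValueError`.
    """
    x = float(x)
    if 0.0 <= x <= 1.0:
        return x
    if -clip_tol <= x <= 1.0 + clip_tol:
        clipped = min(max(x, 0.0), 1.0)
        warnings.warn(
            f"{name}={x:g} marginally outside [0, 1]; clipped to {clipped:g}",
            stacklevel=3,
        )
        return clipped
    raise ValueError(f"{name}={x:g} is outside [0, 1] beyond tolerance {clip_tol}")


class AlleleClass(str, enum.Enum):
    """Functional class of a gene copy."""

    WILDTYPE = "wildtype"
    ENHANCER_HYPOMORPH = "enhancer_hypomorph"
    KNOCKOUT = "knockout"


@dataclass(frozen=True)
class AlleleModel:
    """One gene copy with a stable activation probability.

    Parameters
    ----------
    allele_id
        Label, e.g. ``"Klrk1.B6"``.
    allele_class
        ``wildtype``, ``enhancer_hypomorph`` (attenuated cis element) or
        ``knockout`` (null; forces ``p = 0``).
    activation_probability
        Probability that the allele is ON in a randomly chosen cell.
        The allelic failure rate is ``q = 1 - p``.
    context
        Genetic-background label (e.g. ``"B6_inbred"``, ``"F1_B6xBALB"``).
        The same allele can carry different ``p`` in different contexts
        (trans effects), so probabilities are never shared across contexts.
    """

    allele_id: str
    activation_probability: float
    allele_class: AlleleClass = AlleleClass.WILDTYPE
    context: str = "default"

    def __post_init__(self) -> None:
        p = as_proportion(self.activation_probability, f"p({self.allele_id})")
        object.__setattr__(self, "activation_probability", p)
        object.__setattr__(self, "allele_class", AlleleClass(self.allele_class))
        if self.allele_class is AlleleClass.KNOCKOUT and p != 0.0:
            raise ValueError(
                f"knockout allele {self.allele_id!r} must have p = 0, got {p:g}"
            )

    @property
    def failure_rate(self) -> float:
        """Allelic failure rate ``q = 1 - p``."""
        return 1.0 - self.activation_probability


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered pair of independently regulated alleles.

    The first slot is the "B6-like" allele by convention; mutant-genotype
    transforms in :mod:`rmesim.inference` always act on the first slot.
    """

    gene_id: str
    alleles: tuple[AlleleModel, AlleleModel]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError(f"gene {self.gene_id!r} must have exactly two alleles")
        object.__setattr__(self, "alleles", tuple(self.alleles))

    @property
    def p1(self) -> float:
        return self.alleles[0].activation_probability

    @property
    def p2(self) -> float:
        return self.alleles[1].activation_probability


@dataclass(frozen=True)
class GenotypeConfig:
    """A multi-gene genotype; all alleles of all genes are independent."""

    genes: tuple[GeneModel, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene_ids in genotype {self.label!r}: {ids}")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not in genotype {self.label!r}")


@dataclass(frozen=True)
class QuadrantFrequencies:
    """The four allelic-expression population fractions.

    ``neither`` / ``first_only`` / ``second_only`` / ``both`` — the four
    quadrants of a two-colour allele-specific stain.  Must sum to 1.
    """

    neither: float
    first_only: float
    second_only: float
    both: float

    #: tolerance on the sum: model-derived quadrants are exact to 1e-9,
    #: empirical (renormalised) tables to 1e-6.
    SUM_TOL_MODEL = 1e-9
    SUM_TOL_EMPIRICAL = 1e-6

    def __post_init__(self) -> None:
        for name in ("neither", "first_only", "second_only", "both"):
            object.__setattr__(self, name, as_proportion(getattr(self, name), name))
        total = self.neither + self.first_only + self.second_only + self.both
        if abs(total - 1.0) > self.SUM_TOL_EMPIRICAL:
            raise ValueError(f"quadrant frequencies sum to {total:.9g}, expected 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.neither, self.first_only, self.second_only, self.both)

    @property
    def first_positive(self) -> float:
        """Total fraction expressing the first allele (alone or with the second)."""
        return self.first_only + self.both

    @property
    def second_positive(self) -> float:
        return self.second_only + self.both

    @property
    def any_positive(self) -> float:
        return 1.0 - self.neither


@dataclass(frozen=True)
class FrequencyEstimate:
    """An observed proportion with its sample size and confidence interval."""

    proportion: float
    n_cells: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.proportion <= self.ci_high <= 1.0):
            raise ValueError(
                f"require 0 <= ci_low <= proportion <= ci_high <= 1, got "
                f"({self.ci_low:g}, {self.proportion:g}, {self.ci_high:g})"
            )
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


# ---------------------------------------------------------------------------
# Closed-form probability calculus
# ---------------------------------------------------------------------------

def gene_positive_fraction(gene: GeneModel) -> float:
    """Probability a cell expresses at least one allele of ``gene``.

    Under allelic independence ``F = 1 - (1 - p1)(1 - p2)``.
    """
    return 1.0 - (1.0 - gene.p1) * (1.0 - gene.p2)


def allele_prob_from_homozygote(F_hom: float) -> float:
    """Per-allele activation probability from a homozygote's positive fraction.

    In a homozygote with two identical, independent alleles the fraction of
    cells lacking a given allele is the square root of the fraction
    expressing neither allele, so ``p = 1 - sqrt(1 - F_hom)``.

    Round-trips through :func:`gene_positive_fraction`.
    """
    F = as_proportion(F_hom, "F_hom")
    return 1.0 - math.sqrt(1.0 - F)


def double_failure_fraction(q: float) -> float:
    """Fraction of cells expressing neither of two independent alleles.

    Each allele fails with rate ``q``; under independence the
    double-negative fraction is ``q**2`` (e.g. a 2.5% per-allele failure
    rate yields 0.0625% double-negative cells).
    """
    q = as_proportion(q, "q")
    return q * q


def quadrant_expected(p1: float, p2: float) -> QuadrantFrequencies:
    """Expected quadrant fractions for independent alleles with probs p1, p2."""
    p1 = as_proportion(p1, "p1")
    p2 = as_proportion(p2, "p2")
    return QuadrantFrequencies(
        neither=(1.0 - p1) * (1.0 - p2),
        first_only=p1 * (1.0 - p2),
        second_only=(1.0 - p1) * p2,
        both=p1 * p2,
    )


def allele_probs_from_quadrants(obs: QuadrantFrequencies) -> tuple[float, float, float]:
    """Marginal allele frequencies and the departure from independence.

    Returns ``(p1, p2, independence_gap)`` where ``p1 = first_only + both``,
    ``p2 = second_only + both`` and ``independence_gap = both - p1 * p2``
    (zero iff the observed quadrants are exactly product-form; positive for
    correlated alleles).
    """
    p1 = obs.first_positive
    p2 = obs.second_positive
    return p1, p2, obs.both - p1 * p2


def activation_from_enhancers(enhancer_strengths: Iterable[float]) -> float:
    """Compose an activation probability from independent enhancer strengths.

    Model extension (not a measured relationship): if each enhancer ``j``
    independently activates the allele with probability ``e_j``, the allele
    is ON when at least one succeeds: ``p = 1 - prod_j (1 - e_j)``.
    """
    p_off = 1.0
    for j, e in enumerate(enhancer_strengths):
        p_off *= 1.0 - as_proportion(e, f"enhancer_strengths[{j}]")
    return 1.0 - p_off


# ---------------------------------------------------------------------------
# Configuration I/O: flat key/value records, one allele per record
# ---------------------------------------------------------------------------

def read_genotype_config(path: str | Path) -> GenotypeConfig:
    """Read a genotype from a flat YAML config.

    Schema::

        label: wt_f1
        alleles:
          - {gene: Klrc1, allele_id: Klrc1.B6, class: wildtype,
             context: F1_B6xBALB, p: 0.31}
          - {gene: Klrc1, allele_id: Klrc1.BALB, class: wildtype,
             context: F1_B6xBALB, p: 0.31}

    Each gene must appear in exactly two records; record order within a
    gene fixes the first/second allele slots.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "alleles" not in raw:
        raise ValueError(f"{path}: expected a mapping with an 'alleles' list")
    by_gene: dict[str, list[AlleleModel]] = {}
    for i, rec in enumerate(raw["alleles"]):
        try:
            allele = AlleleModel(
                allele_id=str(rec["allele_id"]),
                activation_probability=float(rec["p"]),
                allele_class=rec.get("class", "wildtype"),
                context=str(rec.get("context", "default")),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: allele record {i}: {exc}") from exc
        by_gene.setdefault(str(rec["gene"]), []).append(allele)
    genes = []
    for gene_id, alleles in by_gene.items():
        if len(alleles) != 2:
            raise ValueError(
                f"{path}: gene {gene_id!r} has {len(alleles)} allele records, need 2"
            )
        genes.append(GeneModel(gene_id=gene_id, alleles=(alleles[0], alleles[1])))
    return GenotypeConfig(genes=tuple(genes), label=str(raw.get("label", "")))


def write_genotype_config(config: GenotypeConfig, path: str | Path) -> None:
    """Write a genotype config in the flat YAML record format."""
    records = [
        {
            "gene": g.gene_id,
            "allele_id": a.allele_id,
            "class": a.allele_class.value,
            "context": a.context,
            "p": a.activation_probability,
        }
        for g in config.genes
        for a in g.alleles
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"label": config.label, "alleles": records}, fh, sort_keys=False)
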