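"""Expectation rules for mutant genotypes and independence tests.

Implements the enumerated prediction rules used to compare observed
allele-specific receptor frequencies in enhancer-deletion and knockout
mice against expectations under the independent binary-allele model:

* hemizygote expectation from a homozygote frequency (square-root rule),
* cis knockout and cis hypomorph quadrant transforms (the mutated allele
  always occupies the *first* quadrant slot),
* the product rule for multi-receptor co-expression,
* allelic failure rates from heterozygote negatives,
* chi-square / exact-multinomial goodness of fit and Wilson intervals.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from .model import (
    QuadrantFrequencies,
    allele_prob_from_homozygote,
    as_proportion,
)

__all__ = [
    "expected_hemizygote_fraction",
    "cis_knockout_expected",
    "cis_hypomorph_expected",
    "product_rule_expected",
    "failure_rate_from_het",
    "goodness_of_fit",
    "wilson_ci",
    "GofResult",
    "read_frequency_table",
    "augment_with_expected",
    "cohort_summary",
]

QUADRANT_COLUMNS = ["neither", "first_only", "second_only", "both"]


def expected_hemizygote_fraction(F_hom: float) -> float:
    """Expected positive fraction in a hemizygote given the homozygote's.

    With one functional allele the positive fraction equals the per-allele
    activation probability ``p = 1 - sqrt(1 - F_hom)``; e.g. a 67%
    homozygote frequency predicts ~43% in the hemizygote.
    """
    return allele_prob_from_homozygote(F_hom)


def cis_knockout_expected(wt: QuadrantFrequencies) -> QuadrantFrequencies:
    """Expected quadrants after knocking out the first allele.

    cis action leaves the second allele's probability untouched, so cells
    that expressed only the first allele become double-negative and cells
    that expressed both become second-only::

        neither'     = neither + first_only
        second_only' = second_only + both
        first_only'  = both' = 0
    """
    return QuadrantFrequencies(
        neither=wt.neither + wt.first_only,
        first_only=0.0,
        second_only=wt.second_only + wt.both,
        both=0.0,
    )


def cis_hypomorph_expected(wt: QuadrantFrequencies, s: float) -> QuadrantFrequencies:
    """Expected quadrants when the first allele's expression scales by ``s``.

    ``s`` is the measured ratio of overall first-allele-positive fractions
    (mutant / wild type), e.g. 0.477 for the Ly49G2 enhancer hypomorph.
    The first-allele-positive quadrants scale by ``s``; the displaced mass
    moves to the corresponding first-allele-negative quadrant::

        first_only'  = s * first_only
        both'        = s * both
        neither'     = neither + (1 - s) * first_only
        second_only' = second_only + (1 - s) * both
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"scaling factor s={s:g} must lie in [0, 1]")
    return QuadrantFrequencies(
        neither=wt.neither + (1.0 - s) * wt.first_only,
        first_only=s * wt.first_only,
        second_only=wt.second_only + (1.0 - s) * wt.both,
        both=s * wt.both,
    )


def product_rule_expected(fractions: Sequence[float]) -> float:
    """Expected co-expression fraction of independently regulated receptors.

    The product of the individual positive fractions, per mouse.
    """
    if len(fractions) == 0:
        raise ValueError("product rule needs at least one receptor fraction")
    out = 1.0
    for i, f in enumerate(fractions):
        out *= as_proportion(f, f"fractions[{i}]")
    return out


def failure_rate_from_het(F_neg_het: float) -> tuple[float, float]:
    """Allelic failure rate from the negative fraction of a hemizygote.

    With a single functional allele the negative fraction *is* the
    per-allele failure rate ``q``; returns ``(q, q**2)`` where ``q**2`` is
    the predicted double-negative fraction in a two-functional-allele
    animal (2.5% -> 0.0625%).
    """
    q = as_proportion(F_neg_het, "F_neg_het")
    return q, q * q


class GofResult(NamedTuple):
    """Goodness-of-fit outcome for observed counts vs expected proportions."""

    statistic: float
    p_value: float
    df: int
    method: str
    #: set when a zero-expectation category holds observed cells — the
    #: model is then contradicted outright and the statistic is infinite.
    impossible_category: bool = False


def _compositions(n: int, k: int) -> "np.ndarray":
    """All length-``k`` non-negative integer tuples summing to ``n``."""
    if k == 1:
        return np.array([[n]], dtype=np.int64)
    if k == 2:
        i = np.arange(n + 1, dtype=np.int64)
        return np.stack([i, n - i], axis=1)
    if k == 3:
        g = np.arange(n + 1, dtype=np.int64)
        i, j = np.meshgrid(g, g, indexing="ij")
        mask = i + j <= n
        return np.stack([i[mask], j[mask], n - i[mask] - j[mask]], axis=1)
    blocks = [
        np.column_stack(
            [np.full(len(rest), first, dtype=np.int64), rest]
        )
        for first in range(n + 1)
        for rest in (_compositions(n - first, k - 1),)
    ]
    return np.vstack(blocks)


def _exact_multinomial_pvalue(observed: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial test: total probability of outcomes no more likely
    than the observed one (two-sided by probability ordering)."""
    n = int(observed.sum())
    k = len(probs)
    lfact = gammaln(np.arange(n + 2, dtype=np.float64))  # lfact[x+1] = log x!
    with np.errstate(divide="ignore"):
        logp = np.log(probs)

    def logpmf(counts: np.ndarray) -> np.ndarray:
        return lfact[n + 1] - lfact[counts + 1].sum(axis=1) + counts @ logp

    lp_obs = float(logpmf(observed[None, :])[0])
    counts = _compositions(n, k)
    lp = logpmf(counts)
    return float(min(np.exp(lp[lp <= lp_obs + 1e-9]).sum(), 1.0))


#: exact enumeration is offered up to this total count
EXACT_MAX_TOTAL = 500


def goodness_of_fit(
    observed_counts: Sequence[float],
    expected: QuadrantFrequencies | Sequence[float],
    method: str = "auto",
) -> GofResult:
    """Test observed category counts against expected proportions.

    Categories with zero expectation are excluded from the statistic; an
    observed cell in such a category contradicts the model outright and is
    reported as an infinite statistic with ``impossible_category=True``.

    ``method``: ``"chi2"``, ``"exact"`` (full multinomial enumeration,
    total <= 500), or ``"auto"`` (exact when any expected count < 5 and
    the total permits, else chi-square without continuity correction).
    """
    obs = np.asarray(observed_counts, dtype=np.float64)
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    if isinstance(expected, QuadrantFrequencies):
        exp_p = np.array(expected.as_tuple(), dtype=np.float64)
    else:
        exp_p = np.asarray(expected, dtype=np.float64)
    if len(exp_p) != len(obs):
        raise ValueError("observed and expected lengths differ")
    if abs(exp_p.sum() - 1.0) > 1e-6:
        raise ValueError("expected proportions must sum to 1")

    zero = exp_p <= 0.0
    if np.any(obs[zero] > 0):
        return GofResult(math.inf, 0.0, 0, "impossible", impossible_category=True)
    obs = obs[~zero]
    exp_p = exp_p[~zero]
    exp_p = exp_p / exp_p.sum()
    df = len(obs) - 1
    if df == 0:
        return GofResult(0.0, 1.0, 0, "degenerate")

    exp_counts = exp_p * total
    if method == "auto":
        method = (
            "exact"
            if (exp_counts.min() < 5.0 and total <= EXACT_MAX_TOTAL
                and float(total).is_integer())
            else "chi2"
        )
    if method == "exact":
        if total > EXACT_MAX_TOTAL or not float(total).is_integer():
            raise ValueError(
                f"exact multinomial requires integer total <= {EXACT_MAX_TOTAL}"
            )
        stat = float(((obs - exp_counts) ** 2 / exp_counts).sum())
        pval = _exact_multinomial_pvalue(obs.astype(np.int64), exp_p)
        return GofResult(stat, pval, df, "exact")
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    stat, pval = stats.chisquare(obs, exp_counts)
    return GofResult(float(stat), float(pval), df, "chi2")


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"require 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Cohort tables: one row per mouse
# ---------------------------------------------------------------------------

def read_frequency_table(path: str | Path) -> pd.DataFrame:
    """Read a per-mouse quadrant-frequency table (TSV/CSV with header).

    Required columns: ``sample_id, genotype, neither, first_only,
    second_only, both``; optional ``n_cells``.  Quadrants are proportions
    and must sum to 1 within 1e-6 per row (renormalised to machine
    precision on read).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"sample_id", "genotype", *QUADRANT_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    totals = df[QUADRANT_COLUMNS].sum(axis=1)
    bad = ~np.isclose(totals, 1.0, atol=QuadrantFrequencies.SUM_TOL_EMPIRICAL)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(f"{path}: quadrants do not sum to 1 in rows {rows}")
    df[QUADRANT_COLUMNS] = df[QUADRANT_COLUMNS].div(totals, axis=0)
    return df


def _row_quadrants(row: pd.Series) -> QuadrantFrequencies:
    return QuadrantFrequencies(*(float(row[c]) for c in QUADRANT_COLUMNS))


def augment_with_expected(
    wt_table: pd.DataFrame, rule: str, s: float | None = None
) -> pd.DataFrame:
    """Attach per-mouse mutant expectations derived from each mouse's own
    wild-type quadrants (``expected_*`` columns).

    ``rule``: ``"cis_knockout"`` or ``"cis_hypomorph"`` (requires the
    measured scaling factor ``s``).  The mutated allele is the first slot.
    """
    if rule == "cis_knockout":
        transform = cis_knockout_expected
    elif rule == "cis_hypomorph":
        if s is None:
            raise ValueError("cis_hypomorph rule requires the scaling factor s")
        transform = lambda q: cis_hypomorph_expected(q, s)  # noqa: E731
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out = wt_table.copy()
    expected = wt_table.apply(
        lambda row: pd.Series(
            transform(_row_quadrants(row)).as_tuple(),
            index=[f"expected_{c}" for c in QUADRANT_COLUMNS],
        ),
        axis=1,
    )
    return pd.concat([out, expected], axis=1)


def cohort_summary(
    observed: pd.DataFrame, expected: pd.DataFrame, n_cells_col: str = "n_cells"
) -> dict:
    """Per-mouse goodness of fit of observed vs expected quadrant tables.

    ``observed`` rows (mutant mice) are matched to ``expected`` rows
    (``expected_*`` columns from :func:`augment_with_expected`) by
    position; returns a JSON-ready summary with per-sample statistics and
    cohort means.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected tables must have equal length")
    samples = []
    for (_, obs_row), (_, exp_row) in zip(observed.iterrows(), expected.iterrows()):
        n = int(obs_row[n_cells_col])
        counts = [round(float(obs_row[c]) * n) for c in QUADRANT_COLUMNS]
        exp_q = QuadrantFrequencies(
            *(float(exp_row[f"expected_{c}"]) for c in QUADRANT_COLUMNS)
        )
        res = goodness_of_fit(counts, exp_q)
        samples.append(
            {
                "sample_id": str(obs_row["sample_id"]),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "df": res.df,
                "method": res.method,
            }
        )
    obs_mean = observed[QUADRANT_COLUMNS].mean()
    exp_mean = expected[[f"expected_{c}" for c in QUADRANT_COLUMNS]].mean()
    return {
        "n_samples": len(samples),
        "samples": samples,
        "mean_observed": {c: float(obs_mean[c]) for c in QUADRANT_COLUMNS},
        "mean_expected": {
            c: float(exp_mean[f"expected_{c}"]) for c in QUADRANT_COLUMNS
        },
    }
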