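"""Mutant-genotype expectation rules, independence tests and fit statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmesim import (
    QuadrantFrequencies,
    augment_with_expected,
    cis_hypomorph_expected,
    cis_knockout_expected,
    cohort_summary,
    expected_hemizygote_fraction,
    failure_rate_from_het,
    goodness_of_fit,
    product_rule_expected,
    quadrant_expected,
    read_frequency_table,
    wilson_ci,
)


def random_quadrants(draw_tuple):
    """Normalize four non-negative draws into quadrant frequencies."""
    a = np.asarray(draw_tuple, dtype=float)
    a = a / a.sum()
    return QuadrantFrequencies(*a)


quadrant_strategy = st.tuples(
    *[st.floats(1e-3, 1.0, allow_nan=False) for _ in range(4)]
).map(random_quadrants)


class TestHemizygoteExpectation:
    @pytest.mark.parametrize(
        "F_hom,expected",
        [(1.0, 1.0), (0.36, 0.2), (0.67, 1 - math.sqrt(0.33))],
    )
    def test_square_root_rule(self, F_hom, expected):
        assert expected_hemizygote_fraction(F_hom) == pytest.approx(expected)

    def test_worked_example_rounds_to_43(self):
        assert round(100 * expected_hemizygote_fraction(0.67)) == 43


class TestCisKnockout:
    def test_mass_moves_to_first_negative_quadrants(self):
        wt = QuadrantFrequencies(0.4, 0.1, 0.2, 0.3)
        mut = cis_knockout_expected(wt)
        assert mut.as_tuple() == pytest.approx((0.5, 0.0, 0.5, 0.0))

    def test_all_negative_is_fixed_point(self):
        wt = QuadrantFrequencies(1.0, 0.0, 0.0, 0.0)
        assert cis_knockout_expected(wt).as_tuple() == (1.0, 0.0, 0.0, 0.0)

    def test_closed_form_identity_with_p1_zero(self):
        """Knocking out the first allele of (p1, p2) yields the (0, p2) model."""
        mut = cis_knockout_expected(quadrant_expected(0.3, 0.6))
        ref = quadrant_expected(0.0, 0.6)
        assert mut.as_tuple() == pytest.approx(ref.as_tuple(), abs=1e-12)

    @given(wt=quadrant_strategy)
    @settings(max_examples=200, derandomize=True)
    def test_conserves_mass(self, wt):
        assert sum(cis_knockout_expected(wt).as_tuple()) == pytest.approx(1.0, abs=1e-12)


class TestCisHypomorph:
    def test_identity_at_s_one(self):
        wt = QuadrantFrequencies(0.4, 0.1, 0.2, 0.3)
        assert cis_hypomorph_expected(wt, 1.0).as_tuple() == pytest.approx(
            wt.as_tuple(), abs=1e-15
        )

    def test_knockout_limit_at_s_zero(self):
        wt = QuadrantFrequencies(0.4, 0.1, 0.2, 0.3)
        assert cis_hypomorph_expected(wt, 0.0).as_tuple() == pytest.approx(
            cis_knockout_expected(wt).as_tuple(), abs=1e-15
        )

    def test_measured_scaling_worked_arithmetic(self):
        """s = 0.477: first-allele quadrants scale, complement 52.3% moves over."""
        wt = QuadrantFrequencies(0.55, 0.10, 0.26, 0.09)
        mut = cis_hypomorph_expected(wt, 0.477)
        assert mut.as_tuple() == pytest.approx((0.6023, 0.0477, 0.30707, 0.042930))

    def test_first_allele_positive_scales_exactly(self):
        wt = QuadrantFrequencies(0.3, 0.25, 0.25, 0.2)
        for s in (0.1, 0.477, 0.9):
            mut = cis_hypomorph_expected(wt, s)
            assert mut.first_positive == pytest.approx(s * wt.first_positive, abs=1e-12)

    def test_s_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            cis_hypomorph_expected(QuadrantFrequencies(0.25, 0.25, 0.25, 0.25), 1.2)

    @given(wt=quadrant_strategy, s=st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_conserves_mass(self, wt, s):
        assert sum(cis_hypomorph_expected(wt, s).as_tuple()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_and_continuous_in_s(self):
        wt = QuadrantFrequencies(0.4, 0.1, 0.2, 0.3)
        grid = np.linspace(0.0, 1.0, 101)
        outs = np.array([cis_hypomorph_expected(wt, s).as_tuple() for s in grid])
        diffs = np.diff(outs, axis=0)
        # each component moves monotonically; steps are small (continuity)
        assert ((diffs >= -1e-12).all(axis=0) | (diffs <= 1e-12).all(axis=0)).all()
        assert np.abs(diffs).max() < 0.01


class TestProductRule:
    @pytest.mark.parametrize(
        "fracs,expected",
        [([0.65, 0.40], 0.26), ([0.7], 0.7), ([0.5, 0.5, 0.5], 0.125)],
    )
    def test_products(self, fracs, expected):
        assert product_rule_expected(fracs) == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            product_rule_expected([])


def test_failure_rate_from_het():
    assert failure_rate_from_het(0.025) == pytest.approx((0.025, 0.000625))
    assert failure_rate_from_het(0.0) == (0.0, 0.0)
    assert failure_rate_from_het(0.05) == pytest.approx((0.05, 0.0025))


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        res = goodness_of_fit([25, 25, 25, 25], QuadrantFrequencies(0.25, 0.25, 0.25, 0.25))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_category_hand_value(self):
        res = goodness_of_fit([60, 40], [0.5, 0.5], method="chi2")
        assert res.statistic == pytest.approx(4.0)  # (10^2 + 10^2)/50
        assert res.df == 1

    def test_zero_expectation_category_with_observations_is_impossible(self):
        res = goodness_of_fit([10, 5, 0, 1], QuadrantFrequencies(0.5, 0.5, 0.0, 0.0))
        assert math.isinf(res.statistic)
        assert res.impossible_category
        assert res.p_value == 0.0

    def test_zero_expectation_category_excluded(self):
        res = goodness_of_fit([50, 50, 0, 0], QuadrantFrequencies(0.5, 0.5, 0.0, 0.0))
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_exact_matches_chi2_asymptotics_moderate_n(self):
        obs = [30, 10, 8, 2]
        exp = [0.5, 0.25, 0.15, 0.1]
        exact = goodness_of_fit(obs, exp, method="exact")
        chi2 = goodness_of_fit(obs, exp, method="chi2")
        assert exact.method == "exact"
        assert abs(exact.p_value - chi2.p_value) < 0.1

    def test_exact_binomial_case_against_closed_form(self):
        """Two categories: exact multinomial equals the binomial point-mass sum."""
        from scipy.stats import binom

        obs = [8, 2]
        res = goodness_of_fit(obs, [0.5, 0.5], method="exact")
        pmf = binom.pmf(np.arange(11), 10, 0.5)
        expected_p = pmf[pmf <= pmf[8] + 1e-12].sum()
        assert res.p_value == pytest.approx(expected_p, abs=1e-10)

    def test_auto_selects_exact_for_small_expected_counts(self):
        res = goodness_of_fit([9, 1], [0.7, 0.3])
        assert res.method == "exact" if 0.3 * 10 < 5 else "chi2"
        res_big = goodness_of_fit([700, 300], [0.7, 0.3])
        assert res_big.method == "chi2"

    def test_type_one_error_calibrated(self, rng):
        """Reject rate at alpha over multinomial draws from the null."""
        probs = np.array(quadrant_expected(0.4, 0.3).as_tuple())
        n_rep, n, alpha = 1000, 1000, 0.05
        counts = rng.multinomial(n, probs, size=n_rep)
        rejects = 0
        for c in counts:
            if goodness_of_fit(c, probs, method="chi2").p_value < alpha:
                rejects += 1
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejects / n_rep <= alpha + 2 * se


class TestWilsonCI:
    def test_bounds_at_extremes(self):
        assert wilson_ci(0, 100)[0] == pytest.approx(0.0)
        assert wilson_ci(100, 100)[1] == pytest.approx(1.0)

    def test_closed_form_half(self):
        low, high = wilson_ci(50, 100, 0.95)
        assert (low, high) == pytest.approx((0.40383, 0.59617), abs=5e-4)

    def test_contains_point_estimate(self):
        for k, n in [(3, 10), (17, 40), (250, 500)]:
            low, high = wilson_ci(k, n)
            assert low <= k / n <= high

    def test_domain_error(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestCohortTables:
    @pytest.fixture
    def wt_table(self, tmp_path):
        df = pd.DataFrame(
            {
                "sample_id": ["m1", "m2"],
                "genotype": ["wt", "wt"],
                "neither": [0.55, 0.4],
                "first_only": [0.10, 0.1],
                "second_only": [0.26, 0.2],
                "both": [0.09, 0.3],
                "n_cells": [10000, 10000],
            }
        )
        path = tmp_path / "wt.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_read_validates_and_renormalizes(self, wt_table):
        df = read_frequency_table(wt_table)
        assert np.allclose(
            df[["neither", "first_only", "second_only", "both"]].sum(axis=1), 1.0
        )

    def test_read_rejects_bad_sums(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tgenotype\tneither\tfirst_only\tsecond_only\tboth\n"
            "m1\twt\t0.5\t0.5\t0.5\t0.5\n"
        )
        with pytest.raises(ValueError, match="sum"):
            read_frequency_table(path)

    def test_per_mouse_expectations_and_summary(self, wt_table):
        df = read_frequency_table(wt_table)
        exp = augment_with_expected(df, "cis_hypomorph", s=0.477)
        assert exp.loc[0, "expected_neither"] == pytest.approx(0.6023)
        # observed equal to expected -> statistic ~ 0 per mouse
        obs = exp.copy()
        for c in ["neither", "first_only", "second_only", "both"]:
            obs[c] = exp[f"expected_{c}"]
        summary = cohort_summary(obs, exp)
        assert summary["n_samples"] == 2
        for s in summary["samples"]:
            assert s["statistic"] < 0.01

    def test_hypomorph_rule_requires_s(self, wt_table):
        with pytest.raises(ValueError, match="scaling"):
            augment_with_expected(read_frequency_table(wt_table), "cis_hypomorph")
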