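"""Closed-form CI and SE machinery, checked against independent oracles.

The F-quantile oracle inverts a brute-force CDF (numerical integration of
the density written out from the beta-function form) with bisection, fully
independent of scipy.stats.f.ppf.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from jumpcount import (
    ConfidenceInterval,
    InsufficientDataError,
    InsufficientTransitions,
    ThermalContext,
    TransitionCounts,
    ci_of_K,
    ci_of_dG,
    f_quantile,
    free_energy_from_counts,
    make_lookup_table,
    se_of_dG,
)


def f_pdf_explicit(x, d1, d2):
    if x <= 0:
        return 0.0
    log_b = (
        math.lgamma(d1 / 2) + math.lgamma(d2 / 2) - math.lgamma((d1 + d2) / 2)
    )
    log_pdf = (
        0.5 * d1 * math.log(d1 / d2)
        + (d1 / 2 - 1) * math.log(x)
        - ((d1 + d2) / 2) * math.log(1 + d1 * x / d2)
        - log_b
    )
    return math.exp(log_pdf)


def f_quantile_bruteforce(p, d1, d2):
    """Invert the integrated F density by bisection."""
    cdf = lambda x: quad(f_pdf_explicit, 0, x, args=(d1, d2), limit=200)[0]
    hi = 1.0
    while cdf(hi) < p:
        hi *= 2.0
    return brentq(lambda x: cdf(x) - p, 1e-12, hi, xtol=1e-12, rtol=1e-12)


class TestFQuantile:
    @pytest.mark.parametrize(
        "p, d1, d2",
        [(0.975, 2, 2), (0.025, 2, 2), (0.975, 4, 4), (0.95, 2, 4), (0.5, 6, 2)],
    )
    def test_matches_bruteforce_cdf_inversion(self, p, d1, d2):
        assert f_quantile(p, d1, d2) == pytest.approx(
            f_quantile_bruteforce(p, d1, d2), rel=1e-8
        )

    def test_known_value_f22(self):
        # qF_{2,2}(0.975) = 0.975/0.025 = 39 in closed form
        assert f_quantile(0.975, 2, 2) == pytest.approx(39.0, rel=1e-10)
        assert f_quantile(0.025, 2, 2) == pytest.approx(1.0 / 39.0, rel=1e-10)

    @pytest.mark.parametrize("d", [1, 2, 8, 40])
    def test_median_of_symmetric_f_is_one(self, d):
        assert f_quantile(0.5, d, d) == pytest.approx(1.0, rel=1e-10)

    @given(
        p=st.floats(0.01, 0.99),
        d1=st.integers(1, 40),
        d2=st.integers(1, 40),
    )
    def test_reciprocal_identity(self, p, d1, d2):
        assert f_quantile(p, d1, d2) == pytest.approx(
            1.0 / f_quantile(1.0 - p, d2, d1), rel=1e-9
        )

    @pytest.mark.parametrize("p, d1, d2", [(0.0, 2, 2), (1.0, 2, 2), (0.5, 0, 2), (0.5, 2, 2.5), (0.5, -4, 2)])
    def test_rejects_invalid_arguments(self, p, d1, d2):
        with pytest.raises(ValueError):
            f_quantile(p, d1, d2)


class TestTransitionCounts:
    def test_degrees_of_freedom_orientation(self):
        c = TransitionCounts(n_A=3, n_B=5)
        assert (c.d1, c.d2) == (10, 6)

    @pytest.mark.parametrize("n_A, n_B", [(0, 1), (1, 0), (-2, 3)])
    def test_requires_at_least_one_transition_each_way(self, n_A, n_B):
        with pytest.raises(InsufficientDataError):
            TransitionCounts(n_A=n_A, n_B=n_B)

    def test_rejects_non_integer_counts(self):
        with pytest.raises(TypeError):
            TransitionCounts(n_A=1.5, n_B=2)


class TestCiOfK:
    def test_single_transition_interval(self):
        ci = ci_of_K(1.0, TransitionCounts(1, 1))
        assert ci.lower == pytest.approx(1.0 / 39.0, rel=1e-9)
        assert ci.upper == pytest.approx(39.0, rel=1e-9)

    @pytest.mark.parametrize("K_hat, n", [(0.5, 2), (7.3, 5), (1000.0, 1)])
    def test_multiplicative_symmetry_for_equal_counts(self, K_hat, n):
        ci = ci_of_K(K_hat, TransitionCounts(n, n))
        assert ci.upper / K_hat == pytest.approx(K_hat / ci.lower, rel=1e-9)

    def test_rejects_nonpositive_estimate(self):
        with pytest.raises(ValueError):
            ci_of_K(0.0, TransitionCounts(1, 1))

    @pytest.mark.parametrize("n", [1, 2, 5, 10, 20])
    @pytest.mark.parametrize("K", [1.0, 10.0, 100.0, 1000.0])
    def test_coverage_pins_df_orientation(self, n, K, rng):
        """Empirical type-I error of the interval sits at 5% (binomial noise).

        This is the oracle that fixes the (d1, d2) = (2 n_B, 2 n_A)
        orientation: the transposed orientation fails badly for n_A != n_B
        designs and the inverted interval fails everywhere.
        """
        reps = 10_000
        sum_tA = rng.gamma(n, 1.0 / K, size=reps)
        sum_tB = rng.gamma(n, 1.0, size=reps)
        K_hat = n * sum_tB / (n * sum_tA)
        miss = 0
        # vectorised check against the same bounds ci_of_K would produce
        ci = ci_of_K(1.0, TransitionCounts(n, n))
        lo_f, hi_f = 1.0 / ci.upper, 1.0 / ci.lower  # F quantiles
        ratio = K_hat / K
        miss = np.mean((ratio < lo_f) | (ratio > hi_f))
        tol = 3 * math.sqrt(0.05 * 0.95 / reps)
        assert abs(miss - 0.05) < tol

    def test_coverage_asymmetric_counts(self, rng):
        """df orientation also holds for n_A = n_B + 1."""
        n_A, n_B, K, reps = 3, 2, 50.0, 20_000
        K_hat = (n_A * rng.gamma(n_B, 1.0, reps)) / (n_B * rng.gamma(n_A, 1.0 / K, reps))
        covered = np.array(
            [ci_of_K(kh, TransitionCounts(n_A, n_B)).contains(K) for kh in K_hat[:5000]]
        )
        tol = 3 * math.sqrt(0.05 * 0.95 / 5000)
        assert abs(1 - covered.mean() - 0.05) < tol


class TestCiOfDG:
    @pytest.mark.parametrize(
        "n, expected",
        [(1, 2.18), (2, 1.35)],
        ids=["one-transition", "two-transitions"],
    )
    def test_published_half_widths_at_300K(self, thermal300, n, expected):
        ci = ci_of_dG(TransitionCounts(n, n), thermal300)
        assert ci.half_width == pytest.approx(expected, abs=0.005)

    def test_four_transitions_meet_one_kcal_threshold(self, thermal300):
        ci = ci_of_dG(TransitionCounts(4, 4), thermal300)
        assert ci.half_width <= 1.0
        assert ci.half_width == pytest.approx(0.888, abs=0.005)

    def test_centres_on_estimate(self, thermal300):
        ci = ci_of_dG(TransitionCounts(3, 3), thermal300, dG_hat=-1.7)
        assert ci.lower + ci.upper == pytest.approx(2 * -1.7, abs=1e-9)

    def test_asymmetric_for_unbalanced_counts(self, thermal300):
        ci = ci_of_dG(TransitionCounts(2, 1), thermal300)
        assert abs(ci.lower) != pytest.approx(abs(ci.upper), rel=1e-6)

    @given(n=st.integers(1, 30))
    def test_width_shrinks_with_more_transitions(self, n):
        t = ThermalContext()
        w_n = ci_of_dG(TransitionCounts(n, n), t).width
        w_n1 = ci_of_dG(TransitionCounts(n + 1, n + 1), t).width
        assert w_n1 < w_n

    @given(n_A=st.integers(1, 20), n_B=st.integers(1, 20))
    def test_swap_antisymmetry(self, n_A, n_B):
        t = ThermalContext()
        ci = ci_of_dG(TransitionCounts(n_A, n_B), t)
        ci_sw = ci_of_dG(TransitionCounts(n_B, n_A), t)
        assert ci_sw.lower == pytest.approx(-ci.upper, rel=1e-9, abs=1e-12)
        assert ci_sw.upper == pytest.approx(-ci.lower, rel=1e-9, abs=1e-12)

    @given(scale=st.floats(0.5, 4.0))
    def test_width_linear_in_temperature(self, scale):
        base = ci_of_dG(TransitionCounts(2, 2), ThermalContext(300.0))
        hot = ci_of_dG(TransitionCounts(2, 2), ThermalContext(300.0 * scale))
        assert hot.width == pytest.approx(base.width * scale, rel=1e-9)

    def test_higher_level_strictly_contains_lower(self, thermal300):
        c95 = ci_of_dG(TransitionCounts(3, 3), thermal300, level=0.95)
        c99 = ci_of_dG(TransitionCounts(3, 3), thermal300, level=0.99)
        assert c99.lower < c95.lower and c99.upper > c95.upper


class TestSeOfDG:
    def test_closed_form_single_transition(self, thermal300):
        # psi1(1) = pi^2/6, so SE = kT * pi / sqrt(3)
        expected = thermal300.kT * math.pi / math.sqrt(3)
        assert se_of_dG(TransitionCounts(1, 1), thermal300) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.08, abs=0.005)

    @given(n_A=st.integers(1, 50), n_B=st.integers(1, 50))
    def test_strictly_decreasing_in_each_count(self, n_A, n_B):
        t = ThermalContext()
        se = se_of_dG(TransitionCounts(n_A, n_B), t)
        assert se_of_dG(TransitionCounts(n_A + 1, n_B), t) < se
        assert se_of_dG(TransitionCounts(n_A, n_B + 1), t) < se

    def test_linear_in_temperature(self):
        se300 = se_of_dG(TransitionCounts(4, 3), ThermalContext(300.0))
        se600 = se_of_dG(TransitionCounts(4, 3), ThermalContext(600.0))
        assert se600 == pytest.approx(2 * se300, rel=1e-12)


class TestThermalContext:
    def test_kT_at_300K_kcal(self, thermal300):
        assert thermal300.kT == pytest.approx(0.59616123, rel=1e-6)

    def test_unit_conversion_round_trips(self, thermal300):
        kj = thermal300.to("kJ/mol")
        assert kj.kT / thermal300.kT == pytest.approx(4.184, rel=1e-3)
        assert kj.to("kcal/mol").kT == pytest.approx(thermal300.kT, rel=1e-12)

    def test_dimensionless_kT_unit(self):
        assert ThermalContext(350.0, "kT").kT == pytest.approx(1.0, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ThermalContext(-10.0)
        with pytest.raises(ValueError):
            ThermalContext(300.0, "eV")


class TestLookupTableAndResults:
    def test_table_matches_pointwise_functions(self, thermal300):
        df = make_lookup_table(4, thermal300)
        row11 = df[(df.n_A == 1) & (df.n_B == 1)].iloc[0]
        assert row11.dG_upper_offset == pytest.approx(2.18, abs=0.005)
        row22 = df[(df.n_A == 2) & (df.n_B == 2)].iloc[0]
        assert -row22.dG_lower_offset == pytest.approx(1.35, abs=0.005)
        for _, row in df.iterrows():
            c = TransitionCounts(int(row.n_A), int(row.n_B))
            assert row.se == pytest.approx(se_of_dG(c, thermal300), rel=1e-12)

    def test_table_contains_asymmetric_rows(self, thermal300):
        df = make_lookup_table(3, thermal300)
        asym = df[df.n_A == df.n_B + 1]
        assert len(asym) == 3
        assert (asym.dG_lower_offset.abs() != asym.dG_upper_offset.abs()).all()

    def test_zero_counts_give_structured_result(self, thermal300):
        res = free_energy_from_counts(0, 3, thermal300)
        assert isinstance(res, InsufficientTransitions)
        assert res.n_A == 0

    def test_result_invariant_estimate_inside_ci(self, thermal300):
        res = free_energy_from_counts(5, 4, thermal300, dG_hat=-0.8)
        assert res.ci.contains(res.estimate)
        assert res.metadata.get("asymmetric_ci") is True

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            ConfidenceInterval(lower=1.0, upper=0.0)
        with pytest.raises(ValueError):
            ConfidenceInterval(lower=0.0, upper=1.0, level=1.5)
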