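"""Tests for the synthetic oncology generators and their analytic laws."""

from fractions import Fraction

import numpy as np
import pytest
import sympy

import relsom as rs
from relsom.errors import InvalidConfigError, InvalidInputError
from relsom.oncology import PKParams


class TestGrowthCurve:
    def test_cubic_law_arithmetic(self):
        spec = rs.GrowthSpec(law="cubic", params={"scale": 1.0})
        assert rs.growth_law_value(spec, 2.0) == pytest.approx(8.0)

    def test_even_stamp_counting_without_jitter(self):
        spec = rs.GrowthSpec(law="cubic", horizon=5.0, sampling_rate=2.0, jitter=0.0)
        series = rs.growth_curve(spec)
        assert len(series) == 10
        assert np.allclose(series.times, 0.5 * np.arange(1, 11))

    def test_logistic_saturates_at_carrying_capacity(self):
        spec = rs.GrowthSpec(law="logistic")
        r = spec.params["rate"]
        assert rs.growth_law_value(spec, 10.0 / r * 10.0) == pytest.approx(
            spec.params["capacity"], abs=1e-6
        )

    def test_jitter_keeps_times_strictly_increasing(self):
        spec = rs.GrowthSpec(law="gompertz", horizon=30.0, sampling_rate=3.0, jitter=0.45, seed=9)
        assert np.all(np.diff(rs.growth_curve(spec).times) > 0)

    @pytest.mark.parametrize("points,rate", [(7, 2.0), (23, 7.0), (5, 1.0), (10, 3.0)])
    def test_clinical_follow_up_shapes(self, points, rate):
        # series lengths and frequencies matching published follow-up datasets
        spec = rs.GrowthSpec(law="gompertz", horizon=points / rate, sampling_rate=rate)
        assert len(rs.growth_curve(spec)) == points

    def test_unknown_law_rejected(self):
        with pytest.raises(InvalidConfigError):
            rs.GrowthSpec(law="quartic")

    def test_seeded_reproducibility(self):
        spec = rs.GrowthSpec(law="power", seed=4)
        s1, s2 = rs.growth_curve(spec), rs.growth_curve(spec)
        assert np.array_equal(s1.times, s2.times)
        assert np.array_equal(s1.series_b, s2.series_b)


class TestDcisLaw:
    def test_high_precision_values(self):
        coth = sympy.coth
        expected_eq = float(3 * (coth(sympy.Integer(1)) - 1))
        assert rs.dcis_A(1.0, 1.0) == pytest.approx(expected_eq, abs=1e-12)
        expected_10 = float(sympy.Rational(3, 10) * (coth(sympy.Integer(10)) - sympy.Rational(1, 10)))
        assert rs.dcis_A(1.0, 10.0) == pytest.approx(expected_10, abs=1e-12)
        assert rs.dcis_A(1.0, 10.0) == pytest.approx(0.27, abs=1e-4)

    def test_small_ratio_limit_is_one(self):
        assert rs.dcis_A(1.0, 1e-6) == pytest.approx(1.0, abs=1e-9)

    def test_series_fallback_agrees_with_direct_form_at_the_switch(self):
        # both branches evaluated at the switch point rho = 0.05
        rho = 0.05
        direct = 3.0 / rho * (1.0 / np.tanh(rho) - 1.0 / rho)
        taylor = rs.dcis_A(1.0, rho * (1 - 1e-15))
        assert taylor == pytest.approx(direct, abs=1e-11)

    def test_strictly_decreasing_in_radius_ratio(self):
        rho = np.linspace(0.1, 20.0, 2000)
        values = rs.dcis_A(1.0, rho)
        assert np.all(np.diff(values) < 0)

    def test_rejects_non_positive_geometry(self):
        with pytest.raises(InvalidInputError):
            rs.dcis_A(0.0, 1.0)


class TestDcisDataset:
    def test_records_satisfy_the_law_exactly(self):
        df = rs.dcis_dataset(50, seed=2)
        assert np.array_equal(df["A"].to_numpy(), rs.dcis_A(df["L"].to_numpy(), df["R"].to_numpy()))

    def test_rejects_empty_request_and_bad_ranges(self):
        with pytest.raises(InvalidInputError):
            rs.dcis_dataset(0)
        with pytest.raises(InvalidConfigError):
            rs.dcis_dataset(5, L_range=(0.2, 0.1))

    def test_bitwise_reproducible(self):
        a, b = rs.dcis_dataset(20, seed=3), rs.dcis_dataset(20, seed=3)
        assert a.equals(b)

    def test_relation_series_is_sorted_and_consistent(self):
        series = rs.dcis_relation_series(100, seed=1)
        assert np.all(np.diff(series.series_a) > 0)
        assert np.allclose(series.series_b, rs.dcis_A(1.0, series.series_a))


class TestPhenotypicRates:
    def test_symmetric_point_gives_one_third(self):
        aP, aA = rs.phenotypic_rates(1.0, 1.0, 0.2, 0.2)
        assert aP == pytest.approx(1.0 / 3.0, abs=1e-15)
        assert aA == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_asymmetric_example(self):
        aP, aA = rs.phenotypic_rates(2.0, 5.0, 0.3, 0.1)
        assert aP == pytest.approx(0.315, abs=1e-12)
        assert aA == pytest.approx(0.055, abs=1e-12)

    def test_no_apoptosis_gives_zero_rate(self):
        _, aA = rs.phenotypic_rates(1.5, 2.5, 0.3, 0.0)
        assert aA == 0.0

    def test_rejects_saturated_indices(self):
        with pytest.raises(InvalidInputError):
            rs.phenotypic_rates(1.0, 1.0, 0.6, 0.4)

    def test_matches_exact_rational_arithmetic(self):
        # Fraction arithmetic is an exact independent oracle for this
        # rational-function law.
        rng = np.random.default_rng(17)
        for _ in range(1000):
            tau_P, tau_A = rng.uniform(0.1, 10.0, 2)
            PI = rng.uniform(0.0, 0.6)
            AI = rng.uniform(0.0, min(0.95 - PI, 0.6))
            fP, fA, fPI, fAI = map(Fraction, (tau_P, tau_A, PI, AI))
            denom = 1 - fAI - fPI
            exact_P = ((fPI + fPI**2) / fP - fAI * fPI / fA) / denom
            exact_A = ((fAI - fAI**2) / fA + fAI * fPI / fP) / denom
            aP, aA = rs.phenotypic_rates(tau_P, tau_A, PI, AI)
            assert abs(aP - float(exact_P)) < 1e-12 * max(1.0, abs(float(exact_P)))
            assert abs(aA - float(exact_A)) < 1e-12 * max(1.0, abs(float(exact_A)))


class TestPkUptake:
    def test_starts_at_zero_and_saturates(self):
        t = np.linspace(0.0, 100.0, 500)
        c = rs.pk_uptake(2.0, t)
        assert c[0] == pytest.approx(0.0, abs=1e-12) or t[0] > 0
        plateau = PKParams().plateau_max * 2.0 / (2.0 + PKParams().km)
        assert c[-1] == pytest.approx(plateau, abs=1e-3)
        assert rs.pk_uptake(2.0, [0.0])[0] == 0.0

    def test_lowest_concentration_takes_longest_to_plateau(self):
        p = PKParams()
        time95 = lambda ce: 3.0 / (p.k0 * ce / (ce + p.km))
        assert time95(0.1) > time95(10.0)
        # and the curves themselves agree: fraction of plateau reached at a
        # fixed time is lower for the lower bath concentration
        t = np.array([1.0])
        frac = lambda ce: rs.pk_uptake(ce, t, p)[0] / (p.plateau_max * ce / (ce + p.km))
        assert frac(0.1) < frac(10.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            rs.pk_uptake(0.0, [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            rs.pk_uptake(1.0, [2.0, 1.0])


class TestApplyNoise:
    def test_zero_scale_leaves_series_unchanged(self):
        y = np.array([1.0, 2.0, 3.0])
        em = rs.ErrorModel(sigma_scale=0.0)
        assert np.array_equal(rs.apply_noise(y, em, seed=1), y)

    def test_empirical_sd_matches_the_model(self):
        y = np.full(10_000, 4.0)
        noisy = rs.apply_noise(y, seed=123)
        target = 0.21 * 4**0.84
        assert np.std(noisy - y) == pytest.approx(target, rel=0.05)

    def test_seeded_reproducibility_and_clamping(self):
        y = np.linspace(0.0, 5.0, 50)
        a = rs.apply_noise(y, seed=7)
        b = rs.apply_noise(y, seed=7)
        assert np.array_equal(a, b)
        assert np.all(a >= 0)
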