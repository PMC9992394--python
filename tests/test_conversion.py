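"""Conversion-equation combination, routing and application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olsenp.conversion import (
    ConversionEquation, ConversionError, Rejection, build_default_registry,
    load_components, validate_conversion, weighted_mean_equation,
)
from olsenp.records import Method, SoilClass


def eq(method, soil_class, slope, intercept, r2, n):
    return ConversionEquation(Method(method), SoilClass(soil_class),
                              slope, intercept, r2, n)


M3_NC = [eq("mehlich3", "non_calcareous", 0.33, 6.9, 0.88, 91),
         eq("mehlich3", "non_calcareous", 0.47, 1.2, 0.79, 180),
         eq("mehlich3", "non_calcareous", 0.70, -0.6, 0.71, 66)]
M3_CA = [eq("mehlich3", "calcareous", 0.45, 1.8, 0.81, 60),
         eq("mehlich3", "calcareous", 0.37, 0.4, 0.73, 54)]
BRAY = [eq("bray1", "non_calcareous", 0.43, 2.4, 0.68, 180),
        eq("bray1", "non_calcareous", 0.68, 3.9, 0.95, 165),
        eq("bray1", "non_calcareous", 0.30, 2.9, 0.85, 91)]


class TestWeightedMean:
    def test_full_precision_matches_direct_arithmetic(self):
        # independent oracle: plain sum-product arithmetic on the components
        for comps in (M3_NC, M3_CA, BRAY):
            combined = weighted_mean_equation(comps)
            n_tot = sum(c.n_samples for c in comps)
            assert combined.n_samples == n_tot
            assert combined.slope == pytest.approx(
                sum(c.n_samples * c.slope for c in comps) / n_tot)
            assert combined.intercept == pytest.approx(
                sum(c.n_samples * c.intercept for c in comps) / n_tot)
            assert combined.r_squared == pytest.approx(
                sum(c.n_samples * c.r_squared for c in comps) / n_tot)

    @pytest.mark.parametrize("comps,printed", [
        (M3_NC, (0.47, 2.4, 0.80, 337)),
        (M3_CA, (0.41, 1.1, 0.77, 114)),
        (BRAY, (0.49, 3.1, 0.82, 436)),
    ])
    def test_reproduces_published_combined_rows(self, comps, printed):
        got = weighted_mean_equation(comps).as_printed()
        slope, intercept, r2, n = printed
        assert got.slope == pytest.approx(slope, abs=1e-12)
        assert got.intercept == pytest.approx(intercept, abs=1e-12)
        assert got.r_squared == pytest.approx(r2, abs=1e-12)
        assert got.n_samples == n

    def test_single_equation_is_identity(self):
        assert weighted_mean_equation([M3_NC[0]]) == M3_NC[0]

    def test_mixed_methods_rejected(self):
        with pytest.raises(ConversionError, match="incompatible"):
            weighted_mean_equation([M3_NC[0], BRAY[0]])
        with pytest.raises(ConversionError):
            weighted_mean_equation([])

    def test_order_and_split_invariance(self):
        back = weighted_mean_equation(list(reversed(BRAY)))
        fwd = weighted_mean_equation(BRAY)
        assert back.slope == pytest.approx(fwd.slope)
        # splitting one component into two equal halves changes nothing
        half = BRAY[0].n_samples // 2
        split = [eq("bray1", "non_calcareous", 0.43, 2.4, 0.68, half),
                 eq("bray1", "non_calcareous", 0.43, 2.4, 0.68,
                    BRAY[0].n_samples - half)] + BRAY[1:]
        assert weighted_mean_equation(split).slope == pytest.approx(fwd.slope)
        assert weighted_mean_equation(split).intercept == pytest.approx(fwd.intercept)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(
        st.floats(0.1, 2.0), st.floats(-5, 10), st.floats(0.01, 1.0),
        st.integers(1, 500)), min_size=1, max_size=6))
    def test_combined_coefficients_are_convex(self, rows):
        comps = [eq("bray1", "non_calcareous", *r) for r in rows]
        c = weighted_mean_equation(comps)
        for attr in ("slope", "intercept", "r_squared"):
            vals = [getattr(x, attr) for x in comps]
            assert min(vals) - 1e-9 <= getattr(c, attr) <= max(vals) + 1e-9


class TestRegistry:
    def test_rebuilt_registry_matches_published_equations(self, registry):
        expect = {
            (Method.MEHLICH3, SoilClass.NON_CALCAREOUS): (0.47, 2.4),
            (Method.MEHLICH3, SoilClass.CALCAREOUS): (0.41, 1.1),
            (Method.BRAY1, SoilClass.NON_CALCAREOUS): (0.49, 3.1),
            (Method.ABDPTA, SoilClass.ANY): (1.81, 4.1),
            (Method.RESIN, SoilClass.NON_CALCAREOUS): (0.71, 0.1),
            (Method.RESIN, SoilClass.CALCAREOUS): (0.94, 0.0),
        }
        for key, (slope, intercept) in expect.items():
            got = registry.combined[key]
            assert got.slope == pytest.approx(slope, abs=1e-12), key
            assert got.intercept == pytest.approx(intercept, abs=1e-12), key
        # combined slope within component slope range
        comps = load_components()
        for (m, sc), c in registry.combined.items():
            slopes = [x.slope for x in comps
                      if x.method == m and x.soil_class == sc]
            assert min(slopes) - 0.01 <= c.slope <= max(slopes) + 0.01

    def test_bray1_high_ph_rejected(self, registry):
        out = registry.resolve(Method.BRAY1, SoilClass.NON_CALCAREOUS, pH=7.3)
        assert isinstance(out, Rejection) and out.reason == "pH"
        # kirsanov inherits the rule
        assert isinstance(
            registry.resolve(Method.KIRSANOV, pH=7.0), Rejection)

    def test_kirsanov_routes_to_bray(self, registry):
        got = registry.resolve(Method.KIRSANOV, SoilClass.NON_CALCAREOUS, pH=5.5)
        assert (got.slope, got.intercept) == (0.49, 3.1)

    def test_olsen_identity(self, registry):
        assert registry.resolve(Method.OLSEN) is None
        val, tag = registry.to_olsen(12.0, Method.OLSEN)
        assert val == 12.0 and tag == "olsen:identity"

    @pytest.mark.parametrize("value,method,soil_class,ph,expected", [
        (10.0, Method.BRAY1, SoilClass.NON_CALCAREOUS, 5.5, 8.0),
        (20.0, Method.MEHLICH3, SoilClass.CALCAREOUS, 7.8, 9.3),
    ])
    def test_to_olsen_arithmetic(self, registry, value, method, soil_class,
                                 ph, expected):
        got, _ = registry.to_olsen(value, method, soil_class, ph)
        assert got == pytest.approx(expected)

    def test_to_olsen_monotone_and_nonnegative(self, registry):
        vals = [registry.to_olsen(v, Method.BRAY1,
                                  SoilClass.NON_CALCAREOUS, 5.0)[0]
                for v in (0.0, 1.0, 5.0, 50.0)]
        assert vals == sorted(vals)
        assert all(v >= 0 for v in vals)

    def test_unknown_class_routes_by_ph(self, registry):
        low = registry.resolve(Method.MEHLICH3, SoilClass.UNKNOWN, pH=6.0)
        high = registry.resolve(Method.MEHLICH3, SoilClass.UNKNOWN, pH=8.0)
        assert low.soil_class is SoilClass.NON_CALCAREOUS
        assert high.soil_class is SoilClass.CALCAREOUS

    def test_round_trip_inversion(self, registry, rng):
        eq_ = registry.combined[(Method.BRAY1, SoilClass.NON_CALCAREOUS)]
        olsen = rng.uniform(5, 80, 50)
        raw = np.array([eq_.invert(o) for o in olsen])
        back = np.array([eq_.apply(v) for v in raw])
        np.testing.assert_allclose(back, olsen, rtol=1e-12)


class TestValidateConversion:
    def test_perfect_agreement(self, registry):
        eq_ = registry.combined[(Method.BRAY1, SoilClass.NON_CALCAREOUS)]
        raw = np.linspace(1, 50, 30)
        measured = np.array([eq_.apply(v) for v in raw])
        out = validate_conversion(raw, measured, eq_)
        assert out["slope"] == pytest.approx(1.0)
        assert out["nse"] == pytest.approx(1.0)

    def test_constant_shift(self, registry):
        eq_ = registry.combined[(Method.BRAY1, SoilClass.NON_CALCAREOUS)]
        raw = np.linspace(1, 50, 30)
        measured = np.array([eq_.apply(v) for v in raw]) + 5.0
        out = validate_conversion(raw, measured, eq_)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(5.0)

    def test_noisy_slope_near_one(self, registry, rng):
        eq_ = registry.combined[(Method.BRAY1, SoilClass.NON_CALCAREOUS)]
        raw = rng.uniform(1, 100, 200)
        pred = np.array([eq_.apply(v) for v in raw])
        measured = pred + rng.normal(0, 0.1 * pred.std(), 200)
        out = validate_conversion(raw, measured, eq_)
        assert 0.9 <= out["slope"] <= 1.1
        assert out["p_value"] < 0.001

    def test_degenerate_predictions_error(self, registry):
        eq_ = registry.combined[(Method.BRAY1, SoilClass.NON_CALCAREOUS)]
        with pytest.raises(ConversionError, match="variance"):
            validate_conversion([3.0] * 5, [1, 2, 3, 4, 5], eq_)
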