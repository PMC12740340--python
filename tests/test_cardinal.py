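"""Peak-function fitting and tangent-based cardinal-temperature extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from thermogerm import (
    PeakFit,
    aggregate_cardinals,
    fit_peak,
    inflection_points,
    peak_value,
    percentile_tt_regression,
    tangent_cardinals,
)

from helpers import default_lower, grid_oracle_cardinals, peak_curve, random_peak_params

REF = dict(a=0.3, b=5.0, c=29.0, d=35.0)
TEMPS = np.array([11.0, 14.0, 17.0, 21.0, 23.0, 25.0, 28.0, 31.0, 33.0])


@pytest.fixture
def ref_fit():
    return PeakFit(**REF)


class TestPeakValue:
    def test_value_at_nominal_peak_by_hand(self, ref_fit):
        # a * exp(0 + 1/(29-35)) = 0.3 * e^(-1/6)
        assert peak_value(ref_fit, 29.0) == pytest.approx(0.3 * math.exp(-1.0 / 6.0))

    def test_vanishes_approaching_descending_intercept(self, ref_fit):
        assert peak_value(ref_fit, 35.0 - 1e-4) < 1e-9

    def test_undefined_at_and_beyond_intercept(self, ref_fit):
        with pytest.raises(ValueError):
            peak_value(ref_fit, 35.0)
        with pytest.raises(ValueError):
            peak_value(ref_fit, 36.0)

    def test_invalid_parameter_combinations_rejected(self):
        with pytest.raises(ValueError):
            PeakFit(a=-0.1, b=5.0, c=29.0, d=35.0)
        with pytest.raises(ValueError):
            PeakFit(a=0.3, b=5.0, c=36.0, d=35.0)


class TestFitPeak:
    def test_recovers_noiseless_parameters(self):
        rates = peak_curve(TEMPS, **REF)
        fit = fit_peak(TEMPS, rates)
        for name in ("a", "b", "c", "d"):
            assert getattr(fit, name) == pytest.approx(REF[name], rel=1e-4)
        assert not fit.descending_limb_missing

    def test_underdetermined_input_rejected(self):
        with pytest.raises(ValueError):
            fit_peak([20.0, 25.0, 30.0], [0.1, 0.3, 0.2])

    def test_flat_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_peak(TEMPS, np.full_like(TEMPS, 0.2))

    def test_boundary_maximum_flagged(self):
        temps = TEMPS[:6]
        rates = peak_curve(temps, **REF)  # still rising at 25 °C
        fit = fit_peak(temps, rates)
        assert fit.descending_limb_missing


class TestInflectionPoints:
    def test_match_independent_dense_grid_scan(self, ref_fit):
        oracle = grid_oracle_cardinals(**REF, step=1e-5)
        x_max, x_min = inflection_points(ref_fit)
        assert x_max == pytest.approx(oracle["x_max"], abs=5e-3)
        assert x_min == pytest.approx(oracle["x_min"], abs=5e-3)

    def test_slope_vanishes_at_curve_maximum_between_them(self, ref_fit):
        x_max, x_min = inflection_points(ref_fit)
        grid = np.linspace(x_max, x_min, 2001)
        t_peak = grid[np.argmax(peak_value(ref_fit, grid))]
        h = 1e-6
        slope = (peak_value(ref_fit, t_peak + h) - peak_value(ref_fit, t_peak - h)) / (2 * h)
        assert x_max < t_peak < x_min
        assert abs(slope) < 1e-3

    def test_invariant_to_vertical_scaling(self, ref_fit):
        scaled = PeakFit(a=REF["a"] * 10, b=REF["b"], c=REF["c"], d=REF["d"])
        # flat derivative extremum limits the locator to ~1e-5 °C
        assert inflection_points(scaled) == pytest.approx(inflection_points(ref_fit), abs=5e-5)


class TestTangentCardinals:
    def test_tangents_extrapolate_beyond_inflections(self, ref_fit):
        est = tangent_cardinals(ref_fit)
        assert est.Tb < est.x_max
        assert est.Tc > est.x_min
        assert est.slope_max > 0 > est.slope_min

    def test_ordering_invariant(self, ref_fit):
        est = tangent_cardinals(ref_fit)
        assert est.Tb < est.x_max < est.x_min < est.Tc < ref_fit.d

    def test_vertical_scaling_leaves_cardinals_fixed_and_divides_tt(self, ref_fit):
        k = 10.0
        base = tangent_cardinals(ref_fit)
        scaled = tangent_cardinals(PeakFit(a=REF["a"] * k, b=REF["b"],
                                           c=REF["c"], d=REF["d"]))
        assert scaled.Tb == pytest.approx(base.Tb, abs=1e-6)
        assert scaled.Tc == pytest.approx(base.Tc, abs=1e-6)
        assert scaled.Tt_sub == pytest.approx(base.Tt_sub / k, rel=1e-6)
        assert scaled.Tt_sup == pytest.approx(base.Tt_sup / k, rel=1e-6)

    def test_reference_parameters_match_grid_oracle(self, ref_fit):
        oracle = grid_oracle_cardinals(**REF, step=1e-5)
        est = tangent_cardinals(ref_fit)
        assert est.Tb == pytest.approx(oracle["Tb"], abs=0.05)
        assert est.Tc == pytest.approx(oracle["Tc"], abs=0.05)
        assert est.Tt_sub == pytest.approx(oracle["Tt_sub"], abs=0.5)
        assert est.Tt_sup == pytest.approx(oracle["Tt_sup"], abs=0.5)

    def test_random_parameter_sets_match_grid_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(10):
            a, b, c, d = random_peak_params(rng)
            est = tangent_cardinals(PeakFit(a=a, b=b, c=c, d=d))
            oracle = grid_oracle_cardinals(a, b, c, d)
            assert est.Tb == pytest.approx(oracle["Tb"], abs=0.05)
            assert est.Tc == pytest.approx(oracle["Tc"], abs=0.05)
            assert est.Tt_sub == pytest.approx(oracle["Tt_sub"], rel=0.01)
            assert est.Tt_sup == pytest.approx(oracle["Tt_sup"], rel=0.01)
            assert est.Tb < est.x_max < est.x_min < est.Tc < d


class TestTtRegression:
    def test_exact_line(self):
        tts = np.array([10.0, 20.0, 30.0, 40.0])
        percentiles = 2.0 * tts - 10.0
        reg = percentile_tt_regression(percentiles, tts, "sub")
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(-10.0)
        assert reg.r2 == pytest.approx(1.0)

    def test_repeated_tt_rejected(self):
        with pytest.raises(ValueError):
            percentile_tt_regression([10, 20, 30], [5.0, 5.0, 5.0], "sub")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            percentile_tt_regression([10, 20], [1.0, 2.0], "supra")


class TestAggregateCardinals:
    def _table(self):
        rows = []
        for g in (10, 50):
            for r in range(5):
                rows.append({"elevation": 2345, "percentile": g, "replicate": f"R{r+1}",
                             "Tb": 10.0 + 0.1 * r, "Tc": 34.8, "Tt_sub": 60.0,
                             "Tt_sup": 6.0})
        return pd.DataFrame(rows)

    def test_identical_values_give_zero_sd(self):
        out = aggregate_cardinals(self._table())
        assert np.allclose(out["Tc_mean"], 34.8)
        assert np.allclose(out["Tc_sd"], 0.0)

    def test_one_row_per_elevation_percentile(self):
        out = aggregate_cardinals(self._table())
        assert len(out) == 2
        assert set(out["percentile"]) == {10, 50}
        assert (out["n"] == 5).all()
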