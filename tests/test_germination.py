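"""Sigmoid fitting, percentile scaling, inversion, and group comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermogerm import (
    NoGerminationError,
    PercentileUnreachableError,
    SigmoidFit,
    SimulationConfig,
    arcsine_transform,
    compare_groups,
    fit_sigmoid,
    germination_rate,
    lag_time,
    scale_to_max,
    sigmoid,
    simulate_population,
    time_to_percentile,
)
from thermogerm.simulate import TimeCourse

from helpers import sigmoid_timecourse


def make_tc(counts, n_seeds=50, temperature=25.0, replicate="R1"):
    return TimeCourse(elevation=2345.0, temperature=temperature,
                      replicate=replicate, n_seeds=n_seeds,
                      counts=dict(enumerate(counts, start=1)))


class TestFitSigmoid:
    @pytest.mark.parametrize("a,b,c", [
        (90.0, 15.0, 0.6),
        (60.0, 40.0, 0.3),
        (99.0, 5.0, 1.2),
        (45.0, 100.0, 0.8),
    ])
    def test_recovers_noiseless_parameters(self, a, b, c):
        fit = fit_sigmoid(sigmoid_timecourse(a, b, c))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_counts_raise(self):
        with pytest.raises(NoGerminationError):
            fit_sigmoid(make_tc([0] * 10))

    def test_saturated_course_is_degenerate(self):
        fit = fit_sigmoid(make_tc([50] * 10))
        assert fit.degenerate_c
        assert fit.a == pytest.approx(100.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(make_tc([0, 1, 2]))


class TestScaleToMax:
    def test_scaling_factor_from_best_treatment(self):
        tcs = [make_tc([0, 10, 30, 45, 45], temperature=25.0),  # 90 %
               make_tc([0, 5, 20, 40, 44], temperature=28.0)]   # 88 %
        res = scale_to_max(tcs)
        assert res.max_observed_final == pytest.approx(90.0)
        # scaled percentile 50 corresponds to raw 45 %
        assert res.raw_percentage(50) == pytest.approx(45.0)

    def test_identity_when_maximum_hits_100(self):
        tcs = [make_tc([10, 30, 50, 50], temperature=25.0)]
        assert scale_to_max(tcs).factor == pytest.approx(1.0)

    def test_floor_to_decile_rule(self):
        # min scaled final across temperatures = 68 % -> deciles 10..60
        tcs = [make_tc([0, 20, 40, 50], temperature=25.0),          # 100 %
               make_tc([0, 10, 20, 34], temperature=14.0)]          # 68 %
        assert scale_to_max(tcs).percentiles == tuple(range(10, 70, 10))

    def test_all_zero_set_raises(self):
        with pytest.raises(NoGerminationError):
            scale_to_max([make_tc([0, 0, 0, 0])])
        with pytest.raises(ValueError):
            scale_to_max([])


class TestTimeToPercentile:
    def test_closed_form_median(self):
        fit = SigmoidFit(a=100.0, b=20.0, c=0.5, r2=1.0, source=())
        assert time_to_percentile(fit, 50.0) == pytest.approx(math.log(20.0) / 0.5)

    def test_intercept_maps_to_time_zero(self):
        fit = SigmoidFit(a=100.0, b=20.0, c=0.5, r2=1.0, source=())
        assert time_to_percentile(fit, 100.0 / 21.0) == pytest.approx(0.0, abs=1e-12)

    def test_asymptote_unreachable(self):
        fit = SigmoidFit(a=80.0, b=20.0, c=0.5, r2=1.0, source=())
        with pytest.raises(PercentileUnreachableError):
            time_to_percentile(fit, 80.0)
        with pytest.raises(ValueError):
            time_to_percentile(fit, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=st.floats(30.0, 100.0), b=st.floats(0.5, 200.0),
           c=st.floats(0.05, 3.0), frac=st.floats(0.05, 0.95))
    def test_round_trip_through_the_sigmoid(self, a, b, c, frac):
        fit = SigmoidFit(a=a, b=b, c=c, r2=1.0, source=())
        y = frac * a
        try:
            t = time_to_percentile(fit, y)
        except ValueError:
            return  # y below the fitted intercept: legitimately rejected
        assert sigmoid(t, a, b, c) == pytest.approx(y, rel=1e-9)

    def test_monotone_in_percentage_and_rate(self):
        fit1 = SigmoidFit(a=100.0, b=20.0, c=0.5, r2=1.0, source=())
        fit2 = SigmoidFit(a=100.0, b=20.0, c=0.8, r2=1.0, source=())
        ys = np.linspace(10.0, 90.0, 9)
        times1 = [time_to_percentile(fit1, y) for y in ys]
        assert all(t2 > t1 for t1, t2 in zip(times1, times1[1:]))
        # steeper curve reaches every percentage earlier
        assert all(time_to_percentile(fit2, y) < time_to_percentile(fit1, y)
                   for y in ys)


class TestRatesAndLags:
    @pytest.mark.parametrize("t,expected", [(5.0, 0.2), (2.5, 0.4)])
    def test_rate_is_reciprocal_time(self, t, expected):
        assert germination_rate(t) == pytest.approx(expected)

    def test_rate_of_median_time(self):
        t = math.log(20.0) / 0.5
        assert germination_rate(t) == pytest.approx(0.16690, abs=5e-6)

    def test_rate_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            germination_rate(0.0)

    def test_lag_is_first_day_with_germination(self):
        assert lag_time(make_tc([0, 0, 3, 5, 9])) == 3
        assert lag_time(make_tc([0, 0, 0, 0])) is None

    def test_lag_shorter_at_warmer_temperature(self):
        cfg = SimulationConfig(rng_seed=21, viability=1.0,
                               temperatures=(14.0, 28.0), n_replicates=1)
        cold, warm = simulate_population(cfg, 2345.0)
        assert lag_time(warm) <= lag_time(cold)


class TestArcsineTransform:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (100.0, math.pi / 2), (50.0, math.pi / 4),
    ])
    def test_reference_values(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_strictly_increasing(self):
        ps = np.linspace(0.0, 100.0, 51)
        vals = [arcsine_transform(p) for p in ps]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))

    @pytest.mark.parametrize("p", [-0.1, 100.1])
    def test_domain_enforced(self, p):
        with pytest.raises(ValueError):
            arcsine_transform(p)


class TestCompareGroups:
    def test_f_statistic_by_hand(self):
        res = compare_groups([1, 2, 3, 7, 8, 9], ["A"] * 3 + ["B"] * 3)
        assert res.f_statistic == pytest.approx(54.0)
        assert res.letters["A"] != res.letters["B"]

    def test_identical_groups_share_a_letter(self):
        res = compare_groups([5, 5, 5, 5], ["A", "A", "B", "B"])
        assert res.letters["A"] == res.letters["B"]

    def test_separated_group_gets_distinct_letter(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                                 rng.normal(15, 1, 10)])
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        res = compare_groups(values, labels)
        assert set(res.letters["A"]) & set(res.letters["B"])
        assert not set(res.letters["C"]) & set(res.letters["A"])
        assert not set(res.letters["C"]) & set(res.letters["B"])

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], ["A", "B"])
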