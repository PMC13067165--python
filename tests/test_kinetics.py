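"""Closed-form models, series oracles, and the overshoot peak finder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swellkit import (
    DensityParams,
    FirstOrderParams,
    PeppasSahlinParams,
    PowerLawParams,
    ShortTimeParams,
    SwellingEqParams,
    component_series,
    eval_density_law,
    eval_first_order,
    eval_peppas_sahlin,
    eval_power_law,
    eval_short_time,
    eval_swelling_eq,
    overshoot_peak,
    taylor_partial_sum,
)

finite_params = st.builds(
    SwellingEqParams,
    k=st.floats(1e-3, 50.0),
    a_star=st.floats(-5.0, 5.0),
    b_star=st.floats(0.1, 50.0),
)


@pytest.mark.parametrize(
    "fn,params,t,expected",
    [
        (eval_swelling_eq, SwellingEqParams(0.1, 1.0, 10.0), 4.0, 12 * (1 - math.exp(-0.4))),
        (eval_swelling_eq, SwellingEqParams(2.0, -3.0, 7.0), 0.0, 0.0),
        (eval_power_law, PowerLawParams(2.0, 0.5), 9.0, 6.0),
        (eval_power_law, PowerLawParams(0.5, 0.63), 10.0, 0.5 * 10**0.63),
        (eval_first_order, FirstOrderParams(5.0, 0.1), 0.0, 0.0),
        (eval_first_order, FirstOrderParams(12.0, 0.0211), 50.0, 12 * (1 - math.exp(-1.055))),
        (eval_peppas_sahlin, PeppasSahlinParams(1.0, 2.0), 4.0, 10.0),
        (eval_density_law, DensityParams(0.3, 0.05), 36.0, 0.10),
        (eval_density_law, DensityParams(0.2966, 0.0472), 1.0, 0.3438),
    ],
)
def test_closed_form_point_values(fn, params, t, expected):
    assert fn(params, [t])[0] == pytest.approx(expected, rel=1e-12)


@given(finite_params)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_swelling_starts_at_zero(params):
    """No solvent has penetrated at t = 0, whatever the parameters."""
    assert eval_swelling_eq(params, [0.0])[0] == 0.0


@given(st.floats(1e-3, 5.0), st.floats(0.1, 50.0))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_pure_relaxation_is_first_order(k, b):
    """a* = 0 collapses the swelling equation onto first-order kinetics
    with S_inf = b*, to machine precision."""
    t = np.linspace(0.0, 100.0, 201)
    full = eval_swelling_eq(SwellingEqParams(k, 0.0, b), t)
    fo = eval_first_order(FirstOrderParams(b, k), t)
    np.testing.assert_array_equal(full, fo)


@given(finite_params.filter(lambda p: p.a_star >= 0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_nonnegative_amplitudes_monotone(params):
    t = np.linspace(0.0, 60.0, 400)
    S = eval_swelling_eq(params, t)
    assert np.all(np.diff(S) >= -1e-12 * np.abs(S[1:]).clip(min=1.0))


def test_peppas_sahlin_pure_limits():
    t = np.array([0.25, 1.0, 4.0, 9.0])
    lin = eval_peppas_sahlin(PeppasSahlinParams(0.0, 3.0), t)
    np.testing.assert_allclose(lin, 3.0 * t)
    fick = eval_peppas_sahlin(PeppasSahlinParams(3.0, 0.0), t)
    np.testing.assert_allclose(fick, 3.0 * np.sqrt(t))


class TestShortTime:
    def test_point_value(self):
        # x = 0.01 by construction: D = 0.01 * pi, r = 1, t = 1
        res = eval_short_time(ShortTimeParams(D=0.01 * math.pi, r=1.0), [1.0])
        assert res.x[0] == pytest.approx(0.01)
        assert res.fractional_uptake[0] == pytest.approx(
            0.4 - 0.01 * math.pi - (math.pi / 3) * 0.001, rel=1e-12
        )

    def test_zero_and_validity_flag(self):
        res = eval_short_time(ShortTimeParams(D=math.pi, r=1.0), [0.0, 0.1, 0.5])
        assert res.fractional_uptake[0] == 0.0
        assert list(res.valid) == [True, True, False]

    def test_monotone_on_valid_range(self):
        # dense scan: the truncation is increasing wherever flagged valid
        res = eval_short_time(ShortTimeParams(D=math.pi, r=1.0), np.linspace(0, 0.15, 2000))
        assert res.valid.all()
        assert np.all(np.diff(res.fractional_uptake) > 0)


class TestDensityLaw:
    def test_decreasing_to_floor(self):
        p = DensityParams(0.3, 0.05)
        t = np.geomspace(0.1, 1e6, 500)
        rho = eval_density_law(p, t)
        assert np.all(np.diff(rho) < 0)
        assert np.all(rho > p.rho_eq)
        assert rho[-1] == pytest.approx(p.rho_eq, abs=1e-3)

    def test_rejects_time_zero(self):
        with pytest.raises(ValueError):
            eval_density_law(DensityParams(0.3, 0.05), [0.0, 1.0])


class TestTaylor:
    def test_order_one_is_linearization(self, mixed_params):
        t = np.linspace(0.0, 5.0, 50)
        expected = mixed_params.k * t * (
            mixed_params.a_star * np.sqrt(t) + mixed_params.b_star
        )
        np.testing.assert_allclose(taylor_partial_sum(mixed_params, t, 1), expected)

    def test_order_two_value_and_bound(self, mixed_params):
        got = taylor_partial_sum(mixed_params, [4.0], 2)[0]
        assert got == pytest.approx((0.4 - 0.08) * 12, rel=1e-12)
        exact = eval_swelling_eq(mixed_params, [4.0])[0]
        assert abs(got - exact) <= 0.4**3 / 6 * 12

    @pytest.mark.parametrize("order", [1, 2, 4, 8, 15])
    def test_remainder_bound(self, order):
        """Truncation error bounded by the next term magnitude."""
        for k, a, b in [(0.1, 1.0, 10.0), (0.5, -0.8, 30.0), (1.0, 2.0, 0.5)]:
            p = SwellingEqParams(k, a, b)
            t = np.linspace(0.05, min(3.0 / k, 40.0), 30)
            kt = k * t
            bound = kt ** (order + 1) / math.factorial(order + 1) * np.abs(
                a * np.sqrt(t) + b
            )
            err = np.abs(taylor_partial_sum(p, t, order) - eval_swelling_eq(p, t))
            assert np.all(err <= bound * (1 + 1e-9) + 1e-14)

    def test_high_order_converges(self):
        for k in (0.05, 0.2, 1.0):
            p = SwellingEqParams(k, 1.3, 4.0)
            t = np.linspace(0.01, 3.0 / k, 100)
            exact = eval_swelling_eq(p, t)
            approx = taylor_partial_sum(p, t, 30)
            assert np.max(np.abs(approx - exact) / np.abs(exact)) <= 1e-10

    def test_rejects_bad_order(self, mixed_params):
        with pytest.raises(ValueError):
            taylor_partial_sum(mixed_params, [1.0], 0)


class TestComponentSeries:
    def test_relaxational_sum_is_exponential_series(self, mixed_params):
        t = np.linspace(0.1, 30.0, 40)
        _, r = component_series(mixed_params, t, 60)
        expected = mixed_params.b_star * (1 - np.exp(-mixed_params.k * t))
        np.testing.assert_allclose(r, expected, rtol=1e-12, atol=1e-14)

    def test_equal_amplitudes_split_evenly_at_t1(self):
        p = SwellingEqParams(0.2, 3.0, 3.0)
        f, r = component_series(p, [1.0], 60)
        assert f[0] == pytest.approx(r[0], rel=1e-12)
        assert f[0] / (f[0] + r[0]) == pytest.approx(0.5, rel=1e-12)

    def test_rejects_time_zero(self, mixed_params):
        with pytest.raises(ValueError):
            component_series(mixed_params, [0.0, 1.0], 10)


class TestOvershootPeak:
    def test_absent_for_nonnegative_amplitudes(self):
        assert overshoot_peak(SwellingEqParams(0.1, 1.0, 10.0)) is None
        assert overshoot_peak(SwellingEqParams(0.1, 0.0, 5.0)) is None

    def test_unique_interior_maximum(self):
        p = SwellingEqParams(1.0, -1.0, 10.0)
        peak = overshoot_peak(p)
        assert peak is not None
        # dense grid-scan oracle: the located peak dominates its neighborhood
        t = np.geomspace(1e-4, 200.0, 20000)
        S = eval_swelling_eq(p, t)
        i = int(np.argmax(S))
        assert peak.t_peak == pytest.approx(t[i], rel=1e-2)
        assert peak.S_peak >= S[i]
        # exactly one sign change of the finite-difference slope
        sign_changes = np.sum(np.diff(np.sign(np.diff(S))) != 0)
        assert sign_changes == 1

    def test_search_window_excluding_peak(self, overshoot_params):
        peak = overshoot_peak(overshoot_params)
        assert overshoot_peak(overshoot_params, search_window=(peak.t_peak * 4, peak.t_peak * 8)) is None


@pytest.mark.parametrize(
    "bad",
    [
        dict(k=-1.0, a_star=1.0, b_star=1.0),
        dict(k=0.0, a_star=1.0, b_star=1.0),
        dict(k=float("nan"), a_star=1.0, b_star=1.0),
        dict(k=1.0, a_star=0.0, b_star=0.0),
    ],
)
def test_parameter_validation(bad):
    with pytest.raises(ValueError):
        SwellingEqParams(**bad)


def test_times_validation(mixed_params):
    with pytest.raises(ValueError):
        eval_swelling_eq(mixed_params, [-1.0])
    with pytest.raises(ValueError):
        eval_swelling_eq(mixed_params, [float("inf")])
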