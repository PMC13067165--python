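"""Closed-form evaluation of the swelling-kinetics model family.

Pure computational module: no file I/O, plain numeric arrays in and out.
Besides the forward models it houses the series machinery used as
internal oracles — the exact Taylor partial sums of the unified swelling
equation and the as-printed diffusive/relaxational component series
whose ratio yields the closed-form Fickian contribution.

Two distinct series chains are kept deliberately separate:

* ``taylor_partial_sum`` truncates the exact expansion of
  (1 - e^{-kt})(a* sqrt(t) + b*) and converges to ``eval_swelling_eq``
  with a factorial remainder bound.
* ``component_series`` evaluates the two-term mechanism superposition
  f + r exactly as conventionally printed (diffusive terms carry
  t^{n-1/2}, relaxational terms t^n); its ratio f/(f+r) converges to the
  closed-form Fickian contribution 1/(1 + (b*/a*) sqrt(t)) and is the
  oracle for the mechanism module.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .parameters import (
    DensityParams,
    FirstOrderParams,
    PeppasSahlinParams,
    PowerLawParams,
    ShortTimeParams,
    SwellingEqParams,
)

# cap on k*t inside exp(-k*t): beyond this the exponential underflows anyway
# and extreme arguments only produce overflow noise in downstream gradients.
EXP_CLAMP = 700.0

DEFAULT_SERIES_ORDER = 40
SHORT_TIME_VALIDITY_X = 0.15


def _as_times(times, *, positive: bool = False) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if positive:
        if np.any(t <= 0):
            raise ValueError("times must be strictly positive")
    elif np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def saturation(k: float, t: np.ndarray) -> np.ndarray:
    """(1 - e^{-kt}) evaluated stably; exactly 0 at t = 0."""
    kt = np.minimum(k * t, EXP_CLAMP)
    return -np.expm1(-kt)


def eval_swelling_eq(params: SwellingEqParams, times) -> np.ndarray:
    """Unified swelling equation S(t) = (1 - e^{-kt})(a* sqrt(t) + b*).

    S(0) = 0 exactly (no solvent has penetrated at t = 0).
    """
    t = _as_times(times)
    return saturation(params.k, t) * (params.a_star * np.sqrt(t) + params.b_star)


def eval_power_law(params: PowerLawParams, times) -> np.ndarray:
    """Power law S = k_pl * t^n (with S(0) = 0)."""
    t = _as_times(times)
    return params.k_pl * np.power(t, params.n)


def eval_first_order(params: FirstOrderParams, times) -> np.ndarray:
    """First-order kinetics S = S_inf (1 - e^{-kt}); saturates at S_inf."""
    t = _as_times(times)
    return params.S_inf * saturation(params.k, t)


def eval_peppas_sahlin(params: PeppasSahlinParams, times) -> np.ndarray:
    """Two-term model S = k_d sqrt(t) + k_r t."""
    t = _as_times(times)
    return params.k_d * np.sqrt(t) + params.k_r * t


class ShortTimeResult(NamedTuple):
    fractional_uptake: np.ndarray
    valid: np.ndarray
    x: np.ndarray


def eval_short_time(
    params: ShortTimeParams, times, validity_threshold: float = SHORT_TIME_VALIDITY_X
) -> ShortTimeResult:
    """Short-time fractional uptake S/S_eq = 4 x^{1/2} - pi x - (pi/3) x^{3/2}.

    x = D t / (pi r^2).  The truncation only approximates the diffusion
    solution at small x; points with x > ``validity_threshold`` are
    flagged invalid rather than rejected.
    """
    t = _as_times(times)
    x = params.D * t / (math.pi * params.r**2)
    sx = np.sqrt(x)
    frac = 4.0 * sx - math.pi * x - (math.pi / 3.0) * x * sx
    return ShortTimeResult(frac, x <= validity_threshold, x)


def eval_density_law(params: DensityParams, times) -> np.ndarray:
    """Network density rho_net(t) = beta * t^{-1/2} + rho_eq for t > 0.

    Strictly decreasing, bounded below by rho_eq.  t = 0 is rejected
    because the regressor diverges there.
    """
    t = _as_times(times, positive=True)
    return params.beta / np.sqrt(t) + params.rho_eq


def _alternating_bracket(k: float, t: np.ndarray, order: int) -> np.ndarray:
    """sum_{m=1..order} (-1)^{m+1} (kt)^m / m!  computed termwise."""
    kt = k * t
    term = kt.copy()  # m = 1
    total = term.copy()
    for m in range(2, order + 1):
        term = term * (-kt) / m
        total += term
    return total


def taylor_partial_sum(params: SwellingEqParams, times, order: int) -> np.ndarray:
    """Truncated exact Taylor expansion of the swelling equation.

    Returns [sum_{m=1..order} (-1)^{m+1}(kt)^m/m!] * (a* sqrt(t) + b*);
    converges to :func:`eval_swelling_eq` with truncation error bounded
    by (kt)^{order+1}/(order+1)! * |a* sqrt(t) + b*| (alternating series
    remainder for kt <= order + 2).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order!r}")
    t = _as_times(times)
    return _alternating_bracket(params.k, t, order) * (
        params.a_star * np.sqrt(t) + params.b_star
    )


class ComponentSeries(NamedTuple):
    f: np.ndarray  # diffusive (Fickian) component
    r: np.ndarray  # relaxational component


def component_series(params: SwellingEqParams, times, order: int) -> ComponentSeries:
    """Truncated diffusive/relaxational component sums of the mechanism superposition.

    f = a* sum_{n=1..order} (-1)^{n+1} k^n t^{n-1/2} / n!
    r = b* sum_{n=1..order} (-1)^{n+1} k^n t^n / n!

    Implemented termwise exactly as printed, hence restricted to t > 0
    (the first diffusive term carries t^{1/2} only after combining
    t^{-1/2} with t).  As order grows, f -> a* t^{-1/2} (1 - e^{-kt})
    and r -> b* (1 - e^{-kt}), so f/(f+r) converges to the closed-form
    Fickian contribution.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order!r}")
    t = _as_times(times, positive=True)
    k = params.k
    sqrt_t = np.sqrt(t)
    term_r = k * t  # n = 1 relaxational term, sign +
    term_f = term_r / sqrt_t  # k^n t^{n-1/2}
    f = term_f.copy()
    r = term_r.copy()
    for n in range(2, order + 1):
        term_r = term_r * (-k * t) / n
        term_f = term_r / sqrt_t
        f += term_f
        r += term_r
    return ComponentSeries(params.a_star * f, params.b_star * r)


class OvershootPeak(NamedTuple):
    t_peak: float
    S_peak: float


def _dSdt(params: SwellingEqParams, t: float) -> float:
    k, a, b = params.k, params.a_star, params.b_star
    e = math.exp(-min(k * t, EXP_CLAMP))
    return k * e * (a * math.sqrt(t) + b) + (1.0 - e) * a / (2.0 * math.sqrt(t))


def overshoot_peak(
    params: SwellingEqParams, search_window: tuple[float, float] | None = None
) -> OvershootPeak | None:
    """Locate the interior swelling maximum of an overshoot-shaped curve.

    Only a* < 0 < b* produces a transient maximum (uptake peaks, then the
    relaxing network expels solvent): dS/dt is positive near 0 (the
    penetration term k e^{-kt} b* dominates) and eventually negative
    (the a*/(2 sqrt(t)) term survives).  For a*, b* >= 0 every term of
    dS/dt is non-negative, so S is non-decreasing and None is returned;
    other sign combinations have no interior maximum either.

    A ``search_window`` restricts the bracket; None is returned when the
    derivative does not change sign inside it.
    """
    a, b, k = params.a_star, params.b_star, params.k
    if not (a < 0 < b):
        return None
    if search_window is not None:
        lo, hi = search_window
        lo = max(lo, 1e-12)
        if hi <= lo:
            raise ValueError("search_window must satisfy 0 <= lo < hi")
    else:
        # derivative is positive for small t; double until it turns negative
        lo = 1e-9 / k
        hi = 1.0 / k
        for _ in range(200):
            if _dSdt(params, hi) < 0:
                break
            hi *= 2.0
    if not (_dSdt(params, lo) > 0 and _dSdt(params, hi) < 0):
        return None
    t_peak = brentq(lambda t: _dSdt(params, t), lo, hi, xtol=1e-12, rtol=1e-14)
    S_peak = float(eval_swelling_eq(params, [t_peak])[0])
    return OvershootPeak(float(t_peak), S_peak)
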