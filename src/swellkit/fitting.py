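"""Curve-level fitting interface.

Thin functional wrappers over the sklearn-style estimators in
:mod:`swellkit.estimators`, operating on :class:`~swellkit.data.SwellingCurve`
and :class:`~swellkit.data.DensitySeries` records and stamping
sample/replicate metadata into the returned :class:`FitResult`.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .data import DensitySeries, SwellingCurve
from .estimators import (
    DensityDecayModel,
    FirstOrderModel,
    FitResult,
    PeppasSahlinModel,
    PowerLawModel,
    SwellingEquationModel,
)

__all__ = [
    "fit_swelling_eq",
    "fit_power_law",
    "fit_first_order",
    "fit_peppas_sahlin",
    "fit_density",
    "estimate_diffusion_coefficient",
    "MODEL_REGISTRY",
]


def _with_meta(result: FitResult, curve) -> FitResult:
    return dataclasses.replace(
        result, sample_id=curve.sample_id, replicate_id=curve.replicate_id
    )


def fit_swelling_eq(
    curve: SwellingCurve,
    init=None,
    n_starts: int = 5,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Fit the unified swelling equation to the full curve.

    ``init`` (optional :class:`SwellingEqParams` or (k, a*, b*) triple)
    is tried as an additional start ahead of the built-in multi-start
    policy.
    """
    est = SwellingEquationModel(n_starts=n_starts, seed=seed, **kwargs)
    if init is not None:
        if dataclasses.is_dataclass(init):
            init = (init.k, init.a_star, init.b_star)
        init = tuple(float(v) for v in init)
        base_starts = est._starts

        def _starts(t, S, _base=base_starts, _init=init):
            return [_init] + _base(t, S)

        est._starts = _starts  # type: ignore[method-assign]
    est.fit(curve.times, curve.S)
    return _with_meta(est.result_, curve)


def fit_power_law(
    curve: SwellingCurve, window_fraction: float = 0.60, **kwargs
) -> FitResult:
    """Power-law fit on the early-uptake window (default first 60% of uptake)."""
    est = PowerLawModel(window_fraction=window_fraction, **kwargs)
    est.fit(curve.times, curve.S)
    return _with_meta(est.result_, curve)


def fit_first_order(curve: SwellingCurve, **kwargs) -> FitResult:
    """First-order (saturating exponential) fit to the full curve."""
    est = FirstOrderModel(**kwargs)
    est.fit(curve.times, curve.S)
    return _with_meta(est.result_, curve)


def fit_peppas_sahlin(
    curve: SwellingCurve, window_fraction: float = 0.60, **kwargs
) -> FitResult:
    """Two-term (sqrt(t), t) fit on the early-uptake window."""
    est = PeppasSahlinModel(window_fraction=window_fraction, **kwargs)
    est.fit(curve.times, curve.S)
    return _with_meta(est.result_, curve)


def fit_density(series: DensitySeries) -> FitResult:
    """Linear regression of network density on t^{-1/2}."""
    est = DensityDecayModel()
    est.fit(series.times, series.rho)
    return _with_meta(est.result_, series)


def estimate_diffusion_coefficient(power_fit: FitResult, r: float) -> float:
    """Diffusion coefficient from a power-law fit: D = pi r^2 (k_pl / 4)^{1/n}.

    ``r`` is the characteristic gel radius, in the length unit whose
    square sets the unit of D (per hour).
    """
    if power_fit.model_id != "power_law":
        raise ValueError("estimate_diffusion_coefficient requires a power-law fit")
    if not power_fit.converged:
        raise ValueError("power-law fit did not converge")
    if not r > 0:
        raise ValueError(f"radius must be > 0, got {r!r}")
    p = power_fit.params
    if not (p.k_pl > 0 and p.n > 0):
        raise ValueError("power-law parameters must be positive")
    return math.pi * r**2 * (p.k_pl / 4.0) ** (1.0 / p.n)


MODEL_REGISTRY = {
    "swelling_eq": fit_swelling_eq,
    "power_law": fit_power_law,
    "first_order": fit_first_order,
    "peppas_sahlin": fit_peppas_sahlin,
}
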