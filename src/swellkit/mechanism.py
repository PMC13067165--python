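"""Transport-mechanism decomposition and classification.

The swelling equation superposes a diffusive (Fickian) and a
relaxational component; at any time the Fickian contribution fraction
has the closed form

    CF(t) = 1 / (1 + (b*/a*) sqrt(t)),      CR(t) = 1 - CF(t)

which is independent of the rate constant k: the mechanism is decided by
the amplitude ratio a*/b* alone.  A ratio scale classifies the call —
relaxation-dominated when b* is roughly ten times a* or more, Fickian
when a* exceeds roughly a hundred times b*, anomalous (mixed) in
between.  Both thresholds are configuration, not constants: the
crossover is gradual and pure mechanisms arise only as limit cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics
from .parameters import SwellingEqParams

__all__ = [
    "MechanismProfile",
    "MechanismCall",
    "ExponentCall",
    "fickian_contribution",
    "cf_series_oracle",
    "classify_from_ratio",
    "classify_from_exponent",
    "DEFAULT_THRESHOLDS",
]

# (lower, upper) on the ratio a*/b*: <= lower -> relaxation, >= upper -> Fickian
DEFAULT_THRESHOLDS = (0.1, 100.0)

FICKIAN = "fickian_diffusion"
RELAXATION = "macromolecular_relaxation"
ANOMALOUS = "anomalous"


@dataclass(frozen=True)
class MechanismProfile:
    """Time-resolved mechanism contributions.

    CF + CR = 1 at every valid point.  Points where the closed form
    leaves [0, 1] (possible for mixed-sign parameters, e.g. overshoot
    curves with a* < 0) are flagged invalid rather than clipped.
    """

    times: np.ndarray
    CF: np.ndarray
    CR: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class MechanismCall:
    """Categorical mechanism call for one parameter set.

    ``hard_label`` comes from the ratio a*/b* against the configured
    thresholds; ``dominance_label`` says which mechanism contributes more
    than half at ``reference_time``.  ``overshoot_regime`` (a* < 0)
    forces relaxation dominance — transient over-swelling is a
    relaxation phenomenon — and invalidates CF.  ``ratio_defined`` is
    False only in the b* = 0 limit, which is labeled as the Fickian
    limit with this flag raised.
    """

    ratio: float
    hard_label: str
    dominance_label: str
    reference_time: float
    overshoot_regime: bool
    ratio_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "hard_label": self.hard_label,
            "dominance_label": self.dominance_label,
            "reference_time": self.reference_time,
            "overshoot_regime": self.overshoot_regime,
            "ratio_defined": self.ratio_defined,
        }


def fickian_contribution(params: SwellingEqParams, times) -> MechanismProfile:
    """Closed-form CF(t) = 1/(1 + (b*/a*) sqrt(t)) with CR = 1 - CF.

    k plays no role.  a* = 0 is the pure-relaxation limit (CF = 0
    everywhere), not an error.
    """
    t = kinetics._as_times(times, positive=True)
    if params.a_star == 0:
        cf = np.zeros_like(t)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            cf = 1.0 / (1.0 + (params.b_star / params.a_star) * np.sqrt(t))
    cr = 1.0 - cf
    valid = np.isfinite(cf) & (cf >= 0.0) & (cf <= 1.0)
    return MechanismProfile(t, cf, cr, valid)


def cf_series_oracle(params: SwellingEqParams, times, order: int = kinetics.DEFAULT_SERIES_ORDER) -> np.ndarray:
    """CF from the truncated component series, f_N / (f_N + r_N).

    Independent oracle for :func:`fickian_contribution`: converges to the
    closed form as the order grows (already exact at order 1, where both
    single terms share the factor kt).
    """
    f, r = kinetics.component_series(params, times, order)
    with np.errstate(divide="ignore", invalid="ignore"):
        return f / (f + r)


def classify_from_ratio(
    params: SwellingEqParams,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    reference_time: float = 1.0,
) -> MechanismCall:
    """Mechanism call from the amplitude ratio a*/b*.

    hard label: Fickian for ratio >= upper threshold, relaxation for
    0 <= ratio <= lower threshold, anomalous otherwise (including any
    negative ratio).  Dominance: CF(reference_time) vs 0.5, except that
    an overshoot regime (a* < 0) always calls relaxation dominance.
    """
    lower, upper = thresholds
    if not lower < upper:
        raise ValueError("thresholds must satisfy lower < upper")
    if not reference_time > 0:
        raise ValueError("reference_time must be > 0")
    overshoot = params.a_star < 0
    if params.b_star == 0:
        return MechanismCall(
            ratio=float("inf") if params.a_star > 0 else float("-inf"),
            hard_label=FICKIAN,
            dominance_label=RELAXATION if overshoot else FICKIAN,
            reference_time=reference_time,
            overshoot_regime=overshoot,
            ratio_defined=False,
        )
    ratio = params.ratio
    if ratio >= upper:
        hard = FICKIAN
    elif 0 <= ratio <= lower:
        hard = RELAXATION
    else:
        hard = ANOMALOUS
    if overshoot:
        dominance = RELAXATION
    else:
        cf = float(fickian_contribution(params, [reference_time]).CF[0])
        dominance = FICKIAN if cf > 0.5 else RELAXATION
    return MechanismCall(
        ratio=float(ratio),
        hard_label=hard,
        dominance_label=dominance,
        reference_time=float(reference_time),
        overshoot_regime=overshoot,
    )


@dataclass(frozen=True)
class ExponentCall:
    """Classification of a power-law diffusional exponent."""

    label: str
    nearest: str | None = None


def classify_from_exponent(n: float) -> ExponentCall:
    """Classical exponent ranges: Fickian for n in [0.43, 0.50], relaxation
    (case-II) for n in [0.85, 1.0], anomalous in between; values outside
    [0.43, 1.0] are out of range with the nearest class noted."""
    if not n > 0:
        raise ValueError(f"n must be > 0, got {n!r}")
    if n < 0.43:
        return ExponentCall("out_of_range", nearest=FICKIAN)
    if n <= 0.50:
        return ExponentCall(FICKIAN)
    if n < 0.85:
        return ExponentCall(ANOMALOUS)
    if n <= 1.0:
        return ExponentCall(RELAXATION)
    return ExponentCall("out_of_range", nearest=RELAXATION)
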