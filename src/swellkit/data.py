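"""Input data containers and mass/volume plumbing.

A :class:`SwellingCurve` — one sample/replicate's (time, S) series with
S in grams of water per gram of dry gel — is the universal input record
for all curve fitters.  Raw gravimetric series (:class:`MassSeries`) and
Archimedes-type density series (:class:`DensitySeries`) convert into it
or feed the density regression directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np


def _validate_series(times: np.ndarray, values: np.ndarray, name: str) -> None:
    if times.ndim != 1 or values.ndim != 1:
        raise ValueError("times and values must be one-dimensional")
    if len(times) != len(values):
        raise ValueError(f"times and {name} must have equal length")
    if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
        raise ValueError(f"times and {name} must be finite")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class SwellingCurve:
    """One replicate's swelling time series.

    times are hours, strictly increasing, >= 0; S is the swelling degree
    (w(t) - w0)/w0 in g/g.  Negative S values are permitted away from
    t = 0 (measurement noise), but a t = 0 point must be non-negative.
    """

    sample_id: str
    replicate_id: str
    times: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        _validate_series(self.times, self.S, "S")
        if len(self.times) < 4:
            raise ValueError("a swelling curve needs at least 4 points")
        if self.times[0] < 0:
            raise ValueError("times must be >= 0")
        if self.times[0] == 0 and self.S[0] < 0:
            raise ValueError("S at t = 0 must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MassSeries:
    """Wet-mass time series w(t) with dry mass w0 (> 0), in grams.

    w(t) >= w0 is deliberately not required: overshoot drainage and
    weighing noise can push w below the dry mass plus plateau water.
    """

    sample_id: str
    replicate_id: str
    times: np.ndarray
    w: np.ndarray
    w0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        _validate_series(self.times, self.w, "w")
        if not (np.isfinite(self.w0) and self.w0 > 0):
            raise ValueError(f"w0 must be > 0, got {self.w0!r}")
        if self.times[0] < 0:
            raise ValueError("times must be >= 0")


@dataclass(frozen=True)
class DensitySeries:
    """Network-density time series rho(t) = w0 / V(t), t > 0, rho > 0."""

    sample_id: str
    replicate_id: str
    times: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        _validate_series(self.times, self.rho, "rho")
        if self.times[0] <= 0:
            raise ValueError("density series times must be > 0")
        if np.any(self.rho <= 0):
            raise ValueError("rho must be > 0")


def swelling_degree_from_mass(series: MassSeries) -> SwellingCurve:
    """S(t) = (w(t) - w0) / w0, metadata carried over."""
    S = (series.w - series.w0) / series.w0
    return SwellingCurve(series.sample_id, series.replicate_id, series.times, S)


def mass_from_swelling(curve: SwellingCurve, w0: float) -> MassSeries:
    """Inverse of :func:`swelling_degree_from_mass`: w(t) = w0 (1 + S)."""
    if not w0 > 0:
        raise ValueError(f"w0 must be > 0, got {w0!r}")
    return MassSeries(
        curve.sample_id, curve.replicate_id, curve.times, w0 * (1.0 + curve.S), w0
    )


def network_density_from_mass_volume(
    w0: float, volumes, times, sample_id: str = "", replicate_id: str = ""
) -> DensitySeries:
    """rho(t) = w0 / V(t) from a dry mass and a swollen-volume series."""
    if not w0 > 0:
        raise ValueError(f"w0 must be > 0, got {w0!r}")
    V = np.asarray(volumes, dtype=float)
    if np.any(V <= 0):
        raise ValueError("volumes must be > 0")
    t = np.asarray(times, dtype=float)
    return DensitySeries(sample_id, replicate_id, t, w0 / V)


class EquilibriumEstimate(NamedTuple):
    S_eq: float
    overshoot: bool


def estimate_equilibrium(
    curve: SwellingCurve,
    tail_fraction: float = 0.2,
    overshoot_factor: float = 0.05,
) -> EquilibriumEstimate:
    """Plateau estimate: mean of the trailing ``tail_fraction`` of points.

    The curve is flagged as overshooting when its maximum, reached before
    the tail window, exceeds the plateau by more than ``overshoot_factor``
    (relative) — the signature of transient over-expansion before network
    relaxation expels solvent.  A monotone curve peaks inside the tail
    window and is never flagged.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    n = len(curve)
    n_tail = max(2, int(np.ceil(tail_fraction * n)))
    if n < 2:
        raise ValueError("need at least 2 points to estimate the plateau")
    S_eq = float(curve.S[-n_tail:].mean())
    pre_tail_max = float(curve.S[:-n_tail].max()) if n > n_tail else -np.inf
    overshoot = bool(pre_tail_max > S_eq * (1.0 + overshoot_factor)) and S_eq > 0
    return EquilibriumEstimate(S_eq, overshoot)


def with_metadata(curve: SwellingCurve, sample_id=None, replicate_id=None) -> SwellingCurve:
    kwargs = {}
    if sample_id is not None:
        kwargs["sample_id"] = sample_id
    if replicate_id is not None:
        kwargs["replicate_id"] = replicate_id
    return replace(curve, **kwargs)
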