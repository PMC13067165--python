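"""Typed parameter records for the swelling-kinetics model family.

Every record is an immutable dataclass that validates its physical
constraints on construction.  The unified swelling equation

    S(t) = (1 - exp(-k t)) * (a* sqrt(t) + b*)

carries its entire state in :class:`SwellingEqParams`; the classical
limiting-case models (power law, first-order, Peppas-Sahlin two-term,
short-time fractional uptake) and the network-density decay law have
records of their own.  Time is in hours throughout; unit conversion is
the caller's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields


def _require_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SwellingEqParams:
    """Parameters of the unified swelling equation S = (1 - e^{-kt})(a* t^{1/2} + b*).

    Attributes
    ----------
    k : float
        Solvent-penetration rate constant, 1/h.  Strictly positive.
    a_star : float
        Diffusive-amplitude parameter, (g/g)·h^(-1/2).  Any sign; a
        negative value encodes overshoot-shaped curves (transient
        maximum followed by partial solvent expulsion).
    b_star : float
        Relaxational-amplitude parameter, g/g.  Any sign.

    Notes
    -----
    ``a_star`` and ``b_star`` are composites of the derivation-stage
    proportionality constants (penetration amplitude x network-expansion
    slope / intercept); those constants are not separately identifiable
    and are never exposed.  The ratio ``a_star / b_star`` is the
    mechanism index: large values mean diffusion-dominated uptake, small
    values relaxation-dominated uptake.
    """

    k: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k!r}")
        if self.a_star == 0 and self.b_star == 0:
            raise ValueError("at least one of a_star, b_star must be nonzero")

    @property
    def ratio(self) -> float:
        """Mechanism index a*/b*; defined only for b* != 0."""
        if self.b_star == 0:
            raise ZeroDivisionError("ratio a*/b* undefined for b_star == 0")
        return self.a_star / self.b_star


@dataclass(frozen=True)
class PowerLawParams:
    """Power-law (Korsmeyer-Peppas) parameters, S = k_pl * t^n.

    ``k_pl`` is the prefactor in (g/g)·h^(-n); ``n`` is the dimensionless
    diffusional exponent used to classify the transport mechanism.
    """

    k_pl: float
    n: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if not self.k_pl > 0:
            raise ValueError(f"k_pl must be > 0, got {self.k_pl!r}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n!r}")


@dataclass(frozen=True)
class FirstOrderParams:
    """First-order (Berens-Hopfenberg relaxation) parameters, S = S_inf (1 - e^{-kt})."""

    S_inf: float
    k: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if not self.S_inf > 0:
            raise ValueError(f"S_inf must be > 0, got {self.S_inf!r}")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k!r}")


@dataclass(frozen=True)
class PeppasSahlinParams:
    """Two-term diffusion/relaxation parameters, S = k_d sqrt(t) + k_r t.

    The order-1 linearization of the swelling equation identifies
    ``k_d = k * a_star`` and ``k_r = k * b_star``.
    """

    k_d: float
    k_r: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.k_d == 0 and self.k_r == 0:
            raise ValueError("k_d and k_r must not both be zero")


@dataclass(frozen=True)
class ShortTimeParams:
    """Short-time (Higuchi-type) fractional-uptake parameters.

    With x = D t / (pi r^2):  S/S_eq = 4 x^{1/2} - pi x - (pi/3) x^{3/2}.
    ``D`` is the diffusion coefficient (length^2/h), ``r`` the
    characteristic radius (length).  The truncation is accurate only for
    small x; evaluation attaches a per-point validity flag.
    """

    D: float
    r: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D!r}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r!r}")


@dataclass(frozen=True)
class DensityParams:
    """Network-density decay parameters, rho_net(t) = beta * t^{-1/2} + rho_eq.

    ``beta`` (density-units · h^{1/2}) scales the random-walk expansion of
    cross-linking points; ``rho_eq`` is the equilibrium network density
    the gel relaxes to.  Density decreases monotonically toward
    ``rho_eq`` as the network expands.
    """

    beta: float
    rho_eq: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta!r}")
        if not self.rho_eq >= 0:
            raise ValueError(f"rho_eq must be >= 0, got {self.rho_eq!r}")
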