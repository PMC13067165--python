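"""Seeded synthetic-data generator.

Forward-simulates swelling curves from the unified swelling equation (or
any registered limiting-case model), gravimetric mass series, and
network-density decay series, with the replicate structure the analysis
assumes (triplicates by default) and additive homoscedastic Gaussian
noise on S.  No non-negativity clipping is applied, so the noise model
stays exactly Gaussian for estimator-property tests.  Identical spec +
seed produce bit-identical output.

Two study presets bundle 3 samples x 3 replicates at magnitudes typical
of slow-swelling polysaccharide gels:

* ``pectin_like`` — slow uptake (k ~ 0.02 1/h), diffusion-leaning
  amplitude ratios (a*/b* ~ 6-21), plateaus 12-13 g/g over ~150 h.
* ``alginate_like`` — fast uptake (k ~ 0.3-0.5 1/h), relaxation-leaning
  ratios (~0.27-0.35), plateaus ~24-30 g/g over 50 h, with one
  overshoot-shaped sample (a* < 0).

Time grids are log-spaced (dense early sampling), the standard design in
swelling kinetics: it resolves the early-uptake window on which the
power-law exponent is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Sequence

import numpy as np

from . import kinetics
from .data import DensitySeries, MassSeries, SwellingCurve, mass_from_swelling
from .parameters import (
    DensityParams,
    FirstOrderParams,
    PeppasSahlinParams,
    PowerLawParams,
    SwellingEqParams,
)

__all__ = [
    "GeneratorSpec",
    "SimulatedCurves",
    "StudyFixture",
    "simulate_curve",
    "simulate_mass_series",
    "simulate_density_series",
    "make_study_fixture",
    "PRESETS",
]

_EVALUATORS = {
    "swelling_eq": kinetics.eval_swelling_eq,
    "power_law": kinetics.eval_power_law,
    "first_order": kinetics.eval_first_order,
    "peppas_sahlin": kinetics.eval_peppas_sahlin,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one sample's simulated replicates.

    ``noise_sd`` is interpreted per ``noise_mode``: an absolute sd on S
    (g/g) or a fraction of the noise-free plateau (trailing 20% mean).
    """

    model_id: str
    params: Any
    t_start: float = 0.0
    t_stop: float = 50.0
    n_points: int = 30
    spacing: Literal["linear", "log"] = "linear"
    noise_sd: float = 0.0
    noise_mode: Literal["absolute", "fraction_of_plateau"] = "absolute"
    replicates: int = 3
    seed: int = 0
    sample_id: str = "S1"

    def __post_init__(self) -> None:
        if self.model_id not in _EVALUATORS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if not self.t_stop > self.t_start:
            raise ValueError("t_stop must exceed t_start")
        if self.spacing == "log" and not self.t_start > 0:
            raise ValueError("log spacing requires t_start > 0")
        if self.spacing not in ("linear", "log"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def time_grid(self) -> np.ndarray:
        if self.spacing == "linear":
            return np.linspace(self.t_start, self.t_stop, self.n_points)
        return np.geomspace(self.t_start, self.t_stop, self.n_points)


@dataclass(frozen=True)
class SimulatedCurves:
    curves: tuple[SwellingCurve, ...]
    truth: Any
    noise_sd_abs: float
    spec: GeneratorSpec


def _noise_scale(spec: GeneratorSpec, S_true: np.ndarray) -> float:
    if spec.noise_mode == "absolute":
        return spec.noise_sd
    n_tail = max(2, int(np.ceil(0.2 * len(S_true))))
    return spec.noise_sd * abs(float(S_true[-n_tail:].mean()))


def simulate_curve(spec: GeneratorSpec) -> SimulatedCurves:
    """Simulate ``spec.replicates`` noisy swelling curves plus the truth record.

    S_obs = S_true + N(0, sd), independent across points and replicates;
    negative observations are preserved (no clipping).
    """
    t = spec.time_grid()
    S_true = _EVALUATORS[spec.model_id](spec.params, t)
    sd = _noise_scale(spec, S_true)
    rng = np.random.default_rng(spec.seed)
    curves = []
    for i in range(spec.replicates):
        S_obs = S_true + rng.normal(0.0, sd, size=len(t)) if sd > 0 else S_true.copy()
        if t[0] == 0:
            S_obs[0] = max(S_obs[0], 0.0)  # curve record requires S(0) >= 0
        curves.append(SwellingCurve(spec.sample_id, f"r{i + 1}", t, S_obs))
    return SimulatedCurves(tuple(curves), spec.params, sd, spec)


def simulate_mass_series(spec: GeneratorSpec, w0: float) -> list[MassSeries]:
    """Gravimetric view of :func:`simulate_curve`: w(t) = w0 (1 + S_obs).

    Noise is injected at the S level only, so mass noise scales with w0
    and the pair round-trips exactly through the S = (w - w0)/w0
    conversion.
    """
    sim = simulate_curve(spec)
    return [mass_from_swelling(c, w0) for c in sim.curves]


def simulate_density_series(
    beta: float,
    rho_eq: float,
    times,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    sample_id: str = "S1",
) -> tuple[list[DensitySeries], DensityParams]:
    """Simulate density decay rho = beta t^{-1/2} + rho_eq + N(0, sd)."""
    params = DensityParams(beta=beta, rho_eq=rho_eq)
    t = np.asarray(times, dtype=float)
    rho_true = kinetics.eval_density_law(params, t)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(replicates):
        rho = rho_true + rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else rho_true.copy()
        out.append(DensitySeries(sample_id, f"r{i + 1}", t, rho))
    return out, params


def _solve_amplitudes(k: float, ratio: float, plateau: float, t: np.ndarray) -> SwellingEqParams:
    """(a*, b*) with a*/b* = ratio such that the noise-free trailing-20%
    mean of S equals ``plateau``."""
    n_tail = max(2, int(np.ceil(0.2 * len(t))))
    tt = t[-n_tail:]
    scale = float(np.mean(kinetics.saturation(k, tt) * (ratio * np.sqrt(tt) + 1.0)))
    b = plateau / scale
    return SwellingEqParams(k=k, a_star=ratio * b, b_star=b)


def _pectin_truth() -> dict[str, SwellingEqParams]:
    t = np.geomspace(0.25, 150.0, 30)
    return {
        "P1": _solve_amplitudes(0.0211, 20.79, 12.2, t),
        "P2": _solve_amplitudes(0.0239, 5.84, 12.5, t),
        "P3": _solve_amplitudes(0.0148, 7.13, 12.8, t),
    }


def _alginate_truth() -> dict[str, SwellingEqParams]:
    t = np.geomspace(0.1, 50.0, 40)
    return {
        "A1": _solve_amplitudes(0.2802, 0.35, 24.0, t),
        # overshoot variant: negative diffusive amplitude
        "A2": SwellingEqParams(k=0.5080, a_star=-0.8, b_star=30.0),
        "A3": _solve_amplitudes(0.5200, 0.27, 30.0, t),
    }


PRESETS: dict[str, dict[str, Any]] = {
    "pectin_like": {
        "truth": _pectin_truth,
        "grid": dict(t_start=0.25, t_stop=150.0, n_points=30, spacing="log"),
    },
    "alginate_like": {
        "truth": _alginate_truth,
        "grid": dict(t_start=0.1, t_stop=50.0, n_points=40, spacing="log"),
    },
}


@dataclass(frozen=True)
class StudyFixture:
    preset: str
    curves: tuple[SwellingCurve, ...]
    truth: Mapping[str, SwellingEqParams]
    noise_sd_abs: Mapping[str, float]
    seed: int

    def by_sample(self) -> dict[str, list[SwellingCurve]]:
        out: dict[str, list[SwellingCurve]] = {}
        for c in self.curves:
            out.setdefault(c.sample_id, []).append(c)
        return out


def make_study_fixture(
    preset: str,
    seed: int = 0,
    noise_sd: float = 0.02,
    replicates: int = 3,
) -> StudyFixture:
    """Full study bundle: 3 samples x ``replicates`` noisy curves + truth.

    ``noise_sd`` is a fraction of each sample's plateau (default 2%).
    Per-sample sub-seeds are derived deterministically from ``seed``.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    truth = cfg["truth"]()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(truth))
    curves: list[SwellingCurve] = []
    noise_abs: dict[str, float] = {}
    for (sample, params), sub in zip(sorted(truth.items()), sub_seeds):
        spec = GeneratorSpec(
            model_id="swelling_eq",
            params=params,
            noise_sd=noise_sd,
            noise_mode="fraction_of_plateau",
            replicates=replicates,
            seed=int(sub),
            sample_id=sample,
            **cfg["grid"],
        )
        sim = simulate_curve(spec)
        curves.extend(sim.curves)
        noise_abs[sample] = sim.noise_sd_abs
    return StudyFixture(preset, tuple(curves), truth, noise_abs, seed)
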