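"""Scikit-learn style estimators for the swelling-kinetics model family.

Each estimator fits one model to a single (time, S) series via
``fit(t, S)`` (times may be a 1-D array or an (n, 1) column), exposes
fitted parameters as trailing-underscore attributes, predicts with
``predict(t)``, and records the complete outcome in a :class:`FitResult`
(``result_``).  They compose with sklearn pipelines and model selection
through ``get_params``/``set_params``; the thin functional wrappers in
:mod:`swellkit.fitting` operate on :class:`~swellkit.data.SwellingCurve`
records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from . import kinetics
from .parameters import (
    DensityParams,
    FirstOrderParams,
    PeppasSahlinParams,
    PowerLawParams,
    SwellingEqParams,
)

__all__ = [
    "FitResult",
    "SwellingEquationModel",
    "PowerLawModel",
    "FirstOrderModel",
    "PeppasSahlinModel",
    "DensityDecayModel",
]


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model to one series.

    ``params`` is the typed parameter record of the fitted model (a plain
    mapping only for degenerate density fits where the record's
    invariants cannot hold); ``stderr`` maps parameter names to standard
    errors from the linearized covariance at the optimum; ``window`` is
    the (t_min, t_max) actually fitted.
    """

    model_id: str
    params: Any
    stderr: Mapping[str, float]
    r2: float
    r2_adj: float
    rss: float
    n_points: int
    window: tuple[float, float]
    converged: bool
    n_starts_used: int = 1
    sample_id: str | None = None
    replicate_id: str | None = None

    def param_dict(self) -> dict[str, float]:
        if dataclasses.is_dataclass(self.params):
            return dataclasses.asdict(self.params)
        return dict(self.params)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "model_id": self.model_id,
            "params": self.param_dict(),
            "stderr": dict(self.stderr),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "rss": self.rss,
            "n_points": self.n_points,
            "window": list(self.window),
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "sample_id": self.sample_id,
            "replicate_id": self.replicate_id,
        }
        return d


def _extract_times(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("times must be a 1-D array or an (n, 1) column")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    return t


def _check_xy(X, y, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t = _extract_times(X)
    S = np.asarray(y, dtype=float)
    if S.shape != t.shape:
        raise ValueError("times and S must have equal length")
    if not np.all(np.isfinite(S)):
        raise ValueError("S must be finite")
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] < 0:
        raise ValueError("times must be >= 0")
    return t, S


def _gof(y: np.ndarray, yhat: np.ndarray, n_params: int):
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    n = len(y)
    denom = n - n_params - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else float("nan")
    return rss, r2, r2_adj


def _stderr_from_jacobian(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    dof = max(n - p, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    return np.sqrt(var)


def _tail_plateau(S: np.ndarray, tail_fraction: float) -> float:
    n_tail = max(2, int(np.ceil(tail_fraction * len(S))))
    return float(S[-n_tail:].mean())


def _first_order_inits(t: np.ndarray, S: np.ndarray, tail_fraction: float):
    """(S_inf, k) starting values: plateau from the tail, k from the
    log-linear decay of the unrealized uptake 1 - S/S_inf."""
    S_inf0 = _tail_plateau(S, tail_fraction)
    if S_inf0 <= 0:
        S_inf0 = max(S.max(), 1e-6)
    frac = 1.0 - S / S_inf0
    mask = (frac > 1e-8) & (frac < 1.0) & (t > 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(frac[mask]), 1)[0]
        k0 = -slope
    else:
        k0 = np.nan
    if not np.isfinite(k0) or k0 <= 0:
        # time at ~63% of plateau is ~1/k for a saturating curve
        idx = np.searchsorted(S, 0.632 * S_inf0)
        k0 = 1.0 / t[idx] if 0 < idx < len(t) and t[idx] > 0 else 1.0 / max(t[-1], 1.0)
    return S_inf0, k0


class _KineticEstimator(RegressorMixin, BaseEstimator):
    """Shared predict/score plumbing; subclasses set ``params_`` in fit."""

    _model_id = ""

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        return self._evaluate(_extract_times(X))

    def _evaluate(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _store(self, result: FitResult) -> None:
        self.result_ = result
        self.params_ = result.params
        self.stderr_ = dict(result.stderr)
        self.r2_ = result.r2
        self.r2_adj_ = result.r2_adj
        self.rss_ = result.rss
        self.n_points_ = result.n_points
        self.window_ = result.window
        self.converged_ = result.converged


class SwellingEquationModel(_KineticEstimator):
    """Nonlinear least-squares fit of S = (1 - e^{-kt})(a* sqrt(t) + b*).

    The full curve is fitted (no windowing): the unified equation is
    meant to describe the entire uptake profile, including overshoot.
    Multi-start local optimization guards against the k/(a*, b*)
    trade-off: a relaxation-only start (a* = 0, from a first-order fit),
    a diffusion-only start (b* = 0), seeded jittered combinations, and —
    when the data themselves overshoot — a negative-a* start.  Best
    residual sum of squares wins; near-ties go to the smallest k.

    Parameters
    ----------
    n_starts : int
        Number of optimization starts (>= 2; default 5).
    seed : int
        Seed for the deterministic jittered starts.
    k_bounds : tuple
        Box for the rate constant in 1/h.
    tail_fraction : float
        Trailing fraction used for plateau-based starting values.
    """

    _model_id = "swelling_eq"

    def __init__(
        self,
        n_starts: int = 5,
        seed: int = 0,
        k_bounds: tuple[float, float] = (1e-6, 1e3),
        tail_fraction: float = 0.2,
        max_nfev: int = 10000,
        tol: float = 1e-10,
    ):
        self.n_starts = n_starts
        self.seed = seed
        self.k_bounds = k_bounds
        self.tail_fraction = tail_fraction
        self.max_nfev = max_nfev
        self.tol = tol

    def _evaluate(self, t):
        return kinetics.eval_swelling_eq(self.params_, t)

    def _starts(self, t, S):
        S_eq = _tail_plateau(S, self.tail_fraction)
        S_inf0, k0 = _first_order_inits(t, S, self.tail_fraction)
        a0 = S_eq / np.sqrt(t[-1]) if t[-1] > 0 else 1.0
        starts = [
            (k0, 0.0, S_inf0),  # relaxation-only start (first-order fit)
            (k0, a0, 0.0),  # diffusion-only start
        ]
        overshoots = S.max() > S_eq * 1.05 > 0
        rng = np.random.default_rng(self.seed)
        while len(starts) < max(self.n_starts, 2):
            if overshoots and len(starts) == 4:
                starts.append((k0, -a0, max(S.max(), S_eq) * 1.1))
                continue
            j = rng.lognormal(0.0, 0.7, size=3)
            starts.append((k0 * j[0], 0.5 * a0 * j[1], 0.5 * S_inf0 * j[2]))
        lo, hi = self.k_bounds
        return [
            (float(np.clip(k, lo * 1.01, hi * 0.99)), float(a), float(b))
            for k, a, b in starts[: max(self.n_starts, 2)]
        ]

    def fit(self, X, y):
        t, S = _check_xy(X, y, min_points=4)
        if np.ptp(S) == 0:
            raise ValueError("degenerate flat curve: S has no variation")

        def resid(p):
            k, a, b = p
            return kinetics.saturation(k, t) * (a * np.sqrt(t) + b) - S

        lo, hi = self.k_bounds
        bounds = ([lo, -np.inf, -np.inf], [hi, np.inf, np.inf])
        best = None
        n_used = 0
        for x0 in self._starts(t, S):
            n_used += 1
            try:
                res = least_squares(
                    resid,
                    x0,
                    bounds=bounds,
                    xtol=self.tol,
                    ftol=self.tol,
                    gtol=self.tol,
                    max_nfev=self.max_nfev,
                )
            except Exception:
                continue
            if not res.success:
                continue
            if (
                best is None
                or res.cost < best.cost * (1 - 1e-9)
                or (abs(res.cost - best.cost) <= 1e-9 * max(best.cost, 1e-300)
                    and res.x[0] < best.x[0])
            ):
                best = res
        converged = best is not None
        if not converged:
            # flagged failure, never a silent success: report the raw start
            k0, a0, b0 = self._starts(t, S)[0]
            params = SwellingEqParams(k=k0, a_star=a0, b_star=b0 if b0 or a0 else 1.0)
            yhat = kinetics.eval_swelling_eq(params, t)
            rss, r2, r2_adj = _gof(S, yhat, 3)
            self._store(
                FitResult(
                    self._model_id, params, {}, r2, r2_adj, rss, len(t),
                    (float(t[0]), float(t[-1])), False, n_used,
                )
            )
            return self
        k, a, b = best.x
        if a == 0 and b == 0:
            b = np.finfo(float).tiny
        params = SwellingEqParams(k=float(k), a_star=float(a), b_star=float(b))
        yhat = kinetics.eval_swelling_eq(params, t)
        rss, r2, r2_adj = _gof(S, yhat, 3)
        se = _stderr_from_jacobian(best.jac, rss, len(t), 3)
        stderr = {"k": float(se[0]), "a_star": float(se[1]), "b_star": float(se[2])}
        self._store(
            FitResult(
                self._model_id, params, stderr, r2, r2_adj, rss, len(t),
                (float(t[0]), float(t[-1])), True, n_used,
            )
        )
        return self


class FirstOrderModel(_KineticEstimator):
    """Least-squares fit of the first-order law S = S_inf (1 - e^{-kt})."""

    _model_id = "first_order"

    def __init__(self, tail_fraction: float = 0.2, max_nfev: int = 10000, tol: float = 1e-10):
        self.tail_fraction = tail_fraction
        self.max_nfev = max_nfev
        self.tol = tol

    def _evaluate(self, t):
        return kinetics.eval_first_order(self.params_, t)

    def fit(self, X, y):
        t, S = _check_xy(X, y, min_points=3)
        if np.ptp(S) == 0:
            raise ValueError("degenerate flat curve: S has no variation")
        S_inf0, k0 = _first_order_inits(t, S, self.tail_fraction)

        def resid(p):
            return p[0] * kinetics.saturation(p[1], t) - S

        res = least_squares(
            resid,
            [max(S_inf0, 1e-9), k0],
            bounds=([1e-12, 1e-9], [np.inf, 1e6]),
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_nfev,
        )
        params = FirstOrderParams(S_inf=float(res.x[0]), k=float(res.x[1]))
        yhat = kinetics.eval_first_order(params, t)
        rss, r2, r2_adj = _gof(S, yhat, 2)
        se = _stderr_from_jacobian(res.jac, rss, len(t), 2)
        self._store(
            FitResult(
                self._model_id, params,
                {"S_inf": float(se[0]), "k": float(se[1])},
                r2, r2_adj, rss, len(t), (float(t[0]), float(t[-1])),
                bool(res.success), 1,
            )
        )
        return self


def _uptake_window(t, S, window_fraction, tail_fraction):
    """Points in the early portion of uptake: S <= window_fraction * S_eq.

    The threshold is computed against the plateau (tail mean), not the
    peak, so overshooting curves window consistently.
    """
    S_eq = _tail_plateau(S, tail_fraction)
    return (S <= window_fraction * S_eq) & (t > 0), S_eq


class PowerLawModel(_KineticEstimator):
    """Power-law (Korsmeyer-Peppas) fit S = k_pl t^n on the early-uptake window.

    The power law only describes the first part of absorption, so the fit
    is restricted to points with S <= window_fraction * S_eq (default the
    classical 60%).  The default objective is ordinary least squares on
    log S vs log t — the classical protocol for extracting the
    diffusional exponent; ``objective="nls"`` refines on the original
    scale afterwards.  Goodness of fit is always reported on the original
    scale over the windowed points.
    """

    _model_id = "power_law"

    def __init__(
        self,
        window_fraction: float = 0.60,
        tail_fraction: float = 0.2,
        objective: str = "loglog",
        max_nfev: int = 10000,
        tol: float = 1e-10,
    ):
        self.window_fraction = window_fraction
        self.tail_fraction = tail_fraction
        self.objective = objective
        self.max_nfev = max_nfev
        self.tol = tol

    def _evaluate(self, t):
        return kinetics.eval_power_law(self.params_, t)

    def fit(self, X, y):
        if self.objective not in ("loglog", "nls"):
            raise ValueError("objective must be 'loglog' or 'nls'")
        t, S = _check_xy(X, y, min_points=4)
        mask, S_eq = _uptake_window(t, S, self.window_fraction, self.tail_fraction)
        log_mask = mask & (S > 0)
        if log_mask.sum() < 3:
            raise ValueError(
                "power-law window (S <= "
                f"{self.window_fraction:g} * S_eq = {self.window_fraction * S_eq:.4g}) "
                f"leaves {int(log_mask.sum())} usable points; need >= 3"
            )
        tw, Sw = t[log_mask], S[log_mask]
        A = np.column_stack([np.ones_like(tw), np.log(tw)])
        (c, n0), *_ = np.linalg.lstsq(A, np.log(Sw), rcond=None)
        k0 = float(np.exp(c))
        n0 = float(n0)
        if self.objective == "nls" and n0 > 0:
            res = least_squares(
                lambda p: p[0] * tw ** p[1] - Sw,
                [k0, n0],
                bounds=([1e-300, 1e-6], [np.inf, np.inf]),
                xtol=self.tol, ftol=self.tol, gtol=self.tol, max_nfev=self.max_nfev,
            )
            k0, n0 = float(res.x[0]), float(res.x[1])
            jac = res.jac
        else:
            # delta-method jacobian of k t^n at the log-log optimum
            yhat_w = k0 * tw ** n0
            jac = np.column_stack([yhat_w / k0, yhat_w * np.log(tw)])
        if n0 <= 0:
            raise ValueError(f"fitted exponent n = {n0:.4g} is not positive")
        params = PowerLawParams(k_pl=k0, n=n0)
        yhat = kinetics.eval_power_law(params, tw)
        rss, r2, r2_adj = _gof(Sw, yhat, 2)
        se = _stderr_from_jacobian(jac, rss, len(tw), 2)
        self._store(
            FitResult(
                self._model_id, params,
                {"k_pl": float(se[0]), "n": float(se[1])},
                r2, r2_adj, rss, int(len(tw)),
                (float(tw[0]), float(tw[-1])), True, 1,
            )
        )
        self.S_eq_ = S_eq
        return self


class PeppasSahlinModel(_KineticEstimator):
    """Linear least squares in the (sqrt(t), t) basis: S = k_d sqrt(t) + k_r t.

    The two-term diffusion/relaxation superposition, fitted on the same
    early-uptake window as the power law.
    """

    _model_id = "peppas_sahlin"

    def __init__(self, window_fraction: float = 0.60, tail_fraction: float = 0.2):
        self.window_fraction = window_fraction
        self.tail_fraction = tail_fraction

    def _evaluate(self, t):
        return kinetics.eval_peppas_sahlin(self.params_, t)

    def fit(self, X, y):
        t, S = _check_xy(X, y, min_points=3)
        mask, S_eq = _uptake_window(t, S, self.window_fraction, self.tail_fraction)
        if mask.sum() < 3:
            raise ValueError(
                f"window leaves {int(mask.sum())} points with t > 0; need >= 3"
            )
        tw, Sw = t[mask], S[mask]
        Xb = np.column_stack([np.sqrt(tw), tw])
        coef, *_ = np.linalg.lstsq(Xb, Sw, rcond=None)
        k_d, k_r = float(coef[0]), float(coef[1])
        if k_d == 0 and k_r == 0:
            k_r = np.finfo(float).tiny
        params = PeppasSahlinParams(k_d=k_d, k_r=k_r)
        yhat = Xb @ coef
        rss, r2, r2_adj = _gof(Sw, yhat, 2)
        se = _stderr_from_jacobian(Xb, rss, len(tw), 2)
        self._store(
            FitResult(
                self._model_id, params,
                {"k_d": float(se[0]), "k_r": float(se[1])},
                r2, r2_adj, rss, int(len(tw)),
                (float(tw[0]), float(tw[-1])), True, 1,
            )
        )
        self.S_eq_ = S_eq
        return self


class DensityDecayModel(_KineticEstimator):
    """Ordinary linear regression of network density on t^{-1/2}.

    rho_net(t) = beta * t^{-1/2} + rho_eq: slope beta, intercept rho_eq.
    R^2 and adjusted R^2 are reported exactly as the regression computes
    them.  A constant (or non-decaying) series is degenerate: beta is
    clamped at 0, R^2 at 0, and the result flagged unconverged.
    """

    _model_id = "density"

    def __init__(self):
        pass

    def _evaluate(self, t):
        if isinstance(self.params_, DensityParams):
            return kinetics.eval_density_law(self.params_, t)
        p = dict(self.params_)
        t = np.asarray(t, dtype=float)
        return p["beta"] / np.sqrt(t) + p["rho_eq"]

    def fit(self, X, y):
        import statsmodels.api as sm

        t, rho = _check_xy(X, y, min_points=3)
        if t[0] <= 0:
            raise ValueError("density regression requires t > 0")
        regressor = 1.0 / np.sqrt(t)
        exog = sm.add_constant(regressor)
        tss = float(((rho - rho.mean()) ** 2).sum())
        if tss == 0:
            params = {"beta": 0.0, "rho_eq": float(rho.mean())}
            self._store(
                FitResult(
                    self._model_id, params, {"beta": float("nan"), "rho_eq": float("nan")},
                    0.0, 0.0, 0.0, len(t), (float(t[0]), float(t[-1])), False, 1,
                )
            )
            return self
        ols = sm.OLS(rho, exog).fit()
        rho_eq, beta = float(ols.params[0]), float(ols.params[1])
        se = {"rho_eq": float(ols.bse[0]), "beta": float(ols.bse[1])}
        # adjusted R^2 counts both fitted parameters, matching the
        # package-wide convention (statsmodels excludes the intercept)
        rss, r2, r2_adj = _gof(rho, np.asarray(ols.fittedvalues), 2)
        if beta > 0 and rho_eq >= 0:
            params: Any = DensityParams(beta=beta, rho_eq=rho_eq)
            converged = True
        else:
            # decaying-law invariants violated; report raw coefficients, flagged
            params = {"beta": beta, "rho_eq": rho_eq}
            converged = False
        self._store(
            FitResult(
                self._model_id, params, se, r2, r2_adj, rss, len(t),
                (float(t[0]), float(t[-1])), converged, 1,
            )
        )
        return self
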