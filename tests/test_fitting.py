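"""Fitting: round-trip recovery, windows, uncertainties, goodness of fit."""

import numpy as np
import pytest
from sklearn.base import clone

from swellkit import (
    DensityDecayModel,
    FirstOrderParams,
    PowerLawModel,
    SwellingCurve,
    SwellingEquationModel,
    SwellingEqParams,
    estimate_diffusion_coefficient,
    eval_first_order,
    eval_swelling_eq,
    fit_density,
    fit_first_order,
    fit_peppas_sahlin,
    fit_power_law,
    fit_swelling_eq,
    overshoot_peak,
    simulate_curve,
    simulate_density_series,
    GeneratorSpec,
)


def _curve(t, S, sid="s", rid="r1"):
    return SwellingCurve(sid, rid, np.asarray(t, float), np.asarray(S, float))


class TestSwellingEqFit:
    def test_noise_free_round_trip(self, clean_curve):
        curve, truth = clean_curve
        fr = fit_swelling_eq(curve)
        assert fr.converged
        assert fr.params.k == pytest.approx(truth.k, rel=1e-6)
        assert fr.params.a_star == pytest.approx(truth.a_star, rel=1e-6)
        assert fr.params.b_star == pytest.approx(truth.b_star, rel=1e-6)
        assert fr.r2 == pytest.approx(1.0, abs=1e-12)

    def test_nested_first_order_truth(self):
        t = np.linspace(0.0, 40.0, 30)
        S = eval_first_order(FirstOrderParams(S_inf=7.0, k=0.2), t)
        fr = fit_swelling_eq(_curve(t, S))
        assert abs(fr.params.a_star) <= max(fr.stderr["a_star"], 1e-6)
        assert fr.r2 >= 1 - 1e-10

    def test_overshoot_recovery(self, noisy_overshoot_curves, overshoot_params):
        truth_peak = overshoot_peak(overshoot_params)
        fr = fit_swelling_eq(noisy_overshoot_curves.curves[0])
        assert fr.converged
        assert fr.params.a_star < 0
        fitted_peak = overshoot_peak(fr.params)
        assert fitted_peak is not None
        assert abs(fitted_peak.t_peak - truth_peak.t_peak) / truth_peak.t_peak <= 0.10

    def test_flat_curve_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            fit_swelling_eq(_curve([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0]))

    def test_explicit_init_honored(self, clean_curve):
        curve, truth = clean_curve
        fr = fit_swelling_eq(curve, init=(truth.k, truth.a_star, truth.b_star))
        assert fr.params.k == pytest.approx(truth.k, rel=1e-8)


class TestFirstOrderFit:
    def test_exact_recovery(self):
        t = np.linspace(0.0, 50.0, 25)
        S = eval_first_order(FirstOrderParams(5.0, 0.1), t)
        fr = fit_first_order(_curve(t, S))
        assert fr.params.S_inf == pytest.approx(5.0, rel=1e-8)
        assert fr.params.k == pytest.approx(0.1, rel=1e-8)

    def test_near_first_order_swelling_data(self):
        # b* >> a*: the swelling equation is effectively first order
        p = SwellingEqParams(k=0.2, a_star=0.01, b_star=10.0)
        t = np.linspace(0.0, 40.0, 30)
        fr = fit_first_order(_curve(t, eval_swelling_eq(p, t)))
        assert fr.r2 >= 0.999

    def test_noisy_within_three_stderr(self):
        truth = FirstOrderParams(S_inf=12.0, k=0.15)
        t = np.linspace(0.0, 50.0, 30)
        rng = np.random.default_rng(42)
        S = eval_first_order(truth, t) + rng.normal(0, 0.02 * truth.S_inf, len(t))
        fr = fit_first_order(_curve(t, S))
        assert abs(fr.params.S_inf - truth.S_inf) <= 3 * fr.stderr["S_inf"]
        assert abs(fr.params.k - truth.k) <= 3 * fr.stderr["k"]


class TestPowerLawFit:
    def test_exact_sqrt_data(self):
        t = np.geomspace(0.01, 10.0, 25)
        fr = fit_power_law(_curve(t, 3.0 * np.sqrt(t)))
        assert fr.params.n == pytest.approx(0.5, abs=1e-10)
        assert fr.params.k_pl == pytest.approx(3.0, rel=1e-10)

    def test_exact_linear_data(self):
        t = np.geomspace(0.01, 10.0, 25)
        fr = fit_power_law(_curve(t, 2.0 * t))
        assert fr.params.n == pytest.approx(1.0, abs=1e-10)

    def test_relaxation_limit_band(self):
        """a* = 0 swelling data windowed at 60% shows a near-unity exponent."""
        for k in (0.02, 0.1, 0.5):
            p = SwellingEqParams(k=k, a_star=0.0, b_star=12.0)
            t = np.geomspace(0.01 / k, 6.0 / k, 40)
            fr = fit_power_law(_curve(t, eval_swelling_eq(p, t)))
            assert 0.85 < fr.params.n <= 1.0, (k, fr.params.n)

    def test_diffusion_limit_band(self):
        for k in (0.02, 0.5):
            p = SwellingEqParams(k=k, a_star=2.0, b_star=0.0)
            t = np.geomspace(0.01 / k, 6.0 / k, 40)
            fr = fit_power_law(_curve(t, eval_swelling_eq(p, t)))
            assert 0.43 < fr.params.n < 1.5, (k, fr.params.n)

    def test_window_restricts_points(self):
        p = SwellingEqParams(k=0.1, a_star=0.0, b_star=10.0)
        t = np.geomspace(0.1, 60.0, 40)
        fr = fit_power_law(_curve(t, eval_swelling_eq(p, t)))
        assert fr.n_points < 40
        assert fr.window[1] < t[-1]

    def test_too_few_windowed_points(self):
        # plateaued almost immediately: nothing below 60% of S_eq
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        S = np.array([9.9, 10.0, 10.0, 10.0, 10.0])
        with pytest.raises(ValueError, match="window"):
            fit_power_law(_curve(t, S))

    def test_nls_objective_available(self):
        t = np.geomspace(0.01, 10.0, 25)
        fr = fit_power_law(_curve(t, 3.0 * np.sqrt(t)), objective="nls")
        assert fr.params.n == pytest.approx(0.5, abs=1e-8)


class TestPeppasSahlinFit:
    def test_exact_basis(self):
        t = np.linspace(0.0, 5.0, 20)
        fr = fit_peppas_sahlin(_curve(t, 1.0 * np.sqrt(t) + 2.0 * t), window_fraction=1.0)
        assert fr.params.k_d == pytest.approx(1.0, abs=1e-10)
        assert fr.params.k_r == pytest.approx(2.0, abs=1e-10)

    def test_pure_sqrt_gives_zero_relaxation(self):
        t = np.linspace(0.0, 5.0, 20)
        fr = fit_peppas_sahlin(_curve(t, 2.5 * np.sqrt(t)), window_fraction=1.0)
        assert abs(fr.params.k_r) <= 1e-10

    def test_unbiased_over_replications(self):
        truth = (1.2, 0.8)
        t = np.linspace(0.1, 6.0, 20)
        S_true = truth[0] * np.sqrt(t) + truth[1] * t
        rng = np.random.default_rng(5)
        est = []
        for _ in range(200):
            S = S_true + rng.normal(0, 0.05, len(t))
            fr = fit_peppas_sahlin(_curve(t, S), window_fraction=1.0)
            est.append((fr.params.k_d, fr.params.k_r))
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - truth[0]) / truth[0] <= 0.02
        assert abs(mean[1] - truth[1]) / truth[1] <= 0.02


class TestDensityFit:
    def test_exact_line(self):
        t = np.geomspace(0.5, 50.0, 12)
        rho = 0.3 / np.sqrt(t) + 0.05
        from swellkit import DensitySeries

        fr = fit_density(DensitySeries("s", "r", t, rho))
        assert fr.params.beta == pytest.approx(0.3, rel=1e-10)
        assert fr.params.rho_eq == pytest.approx(0.05, rel=1e-10)
        assert fr.r2 == pytest.approx(1.0, abs=1e-12)

    def test_adjusted_r2_identity(self):
        series, _ = simulate_density_series(0.3, 0.05, np.geomspace(0.5, 50, 12),
                                            noise_sd=0.005, seed=2)
        fr = fit_density(series[0])
        n, p = fr.n_points, 2
        expected = 1 - (1 - fr.r2) * (n - 1) / (n - p - 1)
        assert fr.r2_adj == pytest.approx(expected, rel=1e-12)
        assert fr.r2_adj <= fr.r2

    def test_slope_unbiased_and_stderr_grows_with_noise(self):
        t = np.geomspace(0.5, 50.0, 12)
        slopes, se_by_noise = [], []
        for noise in (0.002, 0.01):
            se_acc = []
            for seed in range(60):
                series, _ = simulate_density_series(0.3, 0.05, t, noise_sd=noise,
                                                    replicates=1, seed=seed)
                fr = fit_density(series[0])
                se_acc.append(fr.stderr["beta"])
                if noise == 0.002:
                    slopes.append(fr.params.beta if fr.converged else fr.params["beta"])
            se_by_noise.append(np.mean(se_acc))
        assert np.mean(slopes) == pytest.approx(0.3, rel=0.01)
        assert se_by_noise[1] > se_by_noise[0]

    def test_constant_series_degenerate(self):
        from swellkit import DensitySeries

        fr = fit_density(DensitySeries("s", "r", np.array([1.0, 2.0, 3.0, 4.0]),
                                       np.full(4, 0.07)))
        assert not fr.converged
        assert fr.params["beta"] == 0.0
        assert fr.r2 == 0.0


class TestDiffusionCoefficient:
    def test_arithmetic(self):
        t = np.geomspace(0.01, 10.0, 25)
        fr = fit_power_law(_curve(t, 0.2 * np.sqrt(t)))
        D = estimate_diffusion_coefficient(fr, r=1.0)
        assert D == pytest.approx(np.pi * 0.05**2, rel=1e-8)
        # k_pl = 4 -> D = pi r^2 regardless of n
        fr4 = fit_power_law(_curve(t, 4.0 * np.sqrt(t)))
        assert estimate_diffusion_coefficient(fr4, r=1.0) == pytest.approx(np.pi, rel=1e-8)
        # quadratic scaling in the radius
        assert estimate_diffusion_coefficient(fr, r=3.0) == pytest.approx(9 * D, rel=1e-10)

    def test_requires_power_law_fit(self, clean_curve):
        fr = fit_swelling_eq(clean_curve[0])
        with pytest.raises(ValueError):
            estimate_diffusion_coefficient(fr, r=1.0)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = SwellingEquationModel(n_starts=7, seed=3)
        assert est.get_params()["n_starts"] == 7
        est2 = clone(est).set_params(seed=9)
        assert est2.seed == 9 and est2.n_starts == 7

    def test_column_vector_input_and_predict(self, clean_curve):
        curve, truth = clean_curve
        est = SwellingEquationModel().fit(curve.times.reshape(-1, 1), curve.S)
        pred = est.predict(curve.times.reshape(-1, 1))
        np.testing.assert_allclose(pred, curve.S, rtol=1e-6, atol=1e-8)
        assert est.score(curve.times, curve.S) == pytest.approx(1.0)
        assert est.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            PowerLawModel().predict([1.0, 2.0])

    def test_density_estimator_direct(self):
        t = np.geomspace(0.5, 50.0, 10)
        est = DensityDecayModel().fit(t, 0.3 / np.sqrt(t) + 0.05)
        np.testing.assert_allclose(est.predict(t), 0.3 / np.sqrt(t) + 0.05, rtol=1e-10)


def test_registry_round_trip_identity():
    """Every model's own fitter recovers noise-free data it generated."""
    cases = {
        "swelling_eq": (SwellingEqParams(0.4, 1.5, 6.0), fit_swelling_eq),
        "first_order": (FirstOrderParams(9.0, 0.25), fit_first_order),
    }
    t = np.linspace(0.0, 30.0, 25)
    from swellkit import eval_first_order as _fo

    evals = {"swelling_eq": eval_swelling_eq, "first_order": _fo}
    for model_id, (truth, fitter) in cases.items():
        S = evals[model_id](truth, t)
        fr = fitter(_curve(t, S))
        for name, val in fr.param_dict().items():
            target = getattr(truth, name)
            assert val == pytest.approx(target, rel=1e-6), (model_id, name)
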