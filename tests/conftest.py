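import numpy as np
import pytest

from swellkit import (
    GeneratorSpec,
    SwellingCurve,
    SwellingEqParams,
    eval_swelling_eq,
    simulate_curve,
)


@pytest.fixture
def mixed_params():
    """Anomalous-transport parameter set used across tests."""
    return SwellingEqParams(k=0.1, a_star=1.0, b_star=10.0)


@pytest.fixture
def overshoot_params():
    return SwellingEqParams(k=0.3, a_star=-0.8, b_star=30.0)


@pytest.fixture
def clean_curve():
    """Noise-free swelling curve from known parameters on a linear grid."""
    p = SwellingEqParams(k=0.5, a_star=2.0, b_star=8.0)
    t = np.linspace(0.0, 20.0, 30)
    return SwellingCurve("demo", "r1", t, eval_swelling_eq(p, t)), p


@pytest.fixture
def noisy_overshoot_curves(overshoot_params):
    spec = GeneratorSpec(
        model_id="swelling_eq",
        params=overshoot_params,
        t_start=0.1,
        t_stop=50.0,
        n_points=40,
        spacing="log",
        noise_sd=0.02,
        noise_mode="fraction_of_plateau",
        replicates=3,
        seed=7,
    )
    return simulate_curve(spec)
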