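import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tevp import TEVPParameters
from tevp.synthetic import BLOOD_LIKE_PARAMS, NoiseModel, generate_suite

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood_params() -> TEVPParameters:
    """Representative healthy-donor parameter set."""
    return BLOOD_LIKE_PARAMS


@pytest.fixture(scope="session")
def maxwell_params() -> TEVPParameters:
    """Degenerate parameter set collapsing the model to a single-mode Maxwell
    fluid with relaxation time τ = η_∞/G = 1 s (no yield stress, no
    structural viscosity, so λ decouples from the stress entirely)."""
    return TEVPParameters(t_r1=1.0, t_r2=1.0, sigma_y0=0.0, eta_ST=0.0,
                          eta_inf=1.0, tau_lambda=1.0, G=1.0)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Seed-fixed synthetic campaign at the default 2% measurement noise."""
    return generate_suite(BLOOD_LIKE_PARAMS, NoiseModel(rel_sd=0.02, seed=42),
                          include_oscillatory=False)


@pytest.fixture(scope="session")
def rate_grid() -> np.ndarray:
    """Decade grid spanning the instrument's usable shear-rate range."""
    return np.array([0.01, 0.1, 1.0, 10.0, 100.0, 1000.0])
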