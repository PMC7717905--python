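import numpy as np
import pytest

from thermolink.models import FourStateModel, celsius_to_kelvin


@pytest.fixture
def mthk_model() -> FourStateModel:
    """Static four-state MthK parameter set used throughout the suite."""
    return FourStateModel(
        L0=0.1, K_Ca=20000.0, theta_UC=150.0, theta_UO=18.0, theta_BC=8.0, theta_BO=8.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_four_state(rng: np.random.Generator) -> FourStateModel:
    """Log-uniform random positive parameter draw over physiological-ish ranges."""
    lo = lambda a, b: float(np.exp(rng.uniform(np.log(a), np.log(b))))  # noqa: E731
    return FourStateModel(
        L0=lo(1e-3, 10.0),
        K_Ca=lo(1e2, 1e6),
        theta_UC=lo(0.1, 10.0),
        theta_UO=lo(0.1, 10.0),
        theta_BC=lo(0.1, 10.0),
        theta_BO=lo(0.1, 10.0),
    )


T21 = celsius_to_kelvin(21.0)
T37 = celsius_to_kelvin(37.0)
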