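import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from dbssteer import SteeringModel, generate_dataset, run_grid

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def steering_model() -> SteeringModel:
    """One calibrated simulator shared by the whole suite (caches unit fields)."""
    model = SteeringModel()
    model.calibrate()  # single electrode 1.6 mA -> 3.00 mm anchor
    return model


@pytest.fixture(scope="session")
def grid_results(steering_model):
    """The full 9-radius experiment grid, run once."""
    return run_grid(steering_model)


@pytest.fixture(scope="session")
def impedance_ds():
    return generate_dataset(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
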