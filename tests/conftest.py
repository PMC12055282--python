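import numpy as np
import pytest
from hypothesis import settings

from occumix import ModelSpec, SimulationConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec_before():
    return ModelSpec("pant_hoot", "before")


@pytest.fixture(scope="session")
def small_dataset():
    """5 individuals x 4 events; small enough for brute-force integration."""
    cfg = SimulationConfig(
        n_individuals=5,
        events_per_individual=4,
        true_beta=(0.3, -0.5, 1.0),
        true_sigma=1.2,
        true_B=0.08,
        seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_dataset():
    """One dataset at the parameter-recovery settings (200 x 10, seed 1)."""
    cfg = SimulationConfig(
        n_individuals=200,
        events_per_individual=10,
        true_beta=(0.5, -0.5, 1.0),
        true_sigma=1.0,
        true_B=0.05,
        seed=1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_truth():
    return {"beta": np.array([0.5, -0.5, 1.0]), "sigma": 1.0, "B": 0.05}
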