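import pandas as pd
import pytest

from xcgh.pipeline import analyze_experiment, simulate_experiment
from xcgh.simulate import SimulationConfig


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down study (3000 features) for fast module tests."""
    base = dict(n_features=3000, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def simulans_data():
    return simulate_experiment("simulans_like", small_config())


@pytest.fixture(scope="session")
def simulans_result(simulans_data):
    return analyze_experiment(simulans_data, "conserved_1000")


@pytest.fixture()
def tiny_annotation():
    return pd.DataFrame({
        "feature_id": ["f1", "f2", "f3"],
        "chromosome": ["X", "2L", "3R"],
        "position_bp": [100, 200, 300],
        "is_x": [True, False, False],
        "conserved_1000": [True, True, False],
        "conserved_100": [True, False, False],
        "length_bp": [500, 480, 520],
        "gc_fraction": [0.41, 0.44, 0.38],
    })


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame({
        "chromosome": ["X", "2L", "3R", "het_scaffold"],
        "length_bp": [1_000_000, 2_000_000, 1_500_000, 400_000],
        "is_x": [True, False, False, False],
        "is_heterochromatin": [False, False, False, True],
    })
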