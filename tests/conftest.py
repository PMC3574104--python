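import numpy as np
import pytest

from consensusbn.io_cli import fixture_chest_clinic, fixture_random_bn
from consensusbn.model_core import DiscreteDataset, Variable, forward_sample


@pytest.fixture(scope="session")
def chest_clinic():
    return fixture_chest_clinic()


@pytest.fixture(scope="session")
def chest_data(chest_clinic):
    """1000 forward samples from the chest-clinic network."""
    return forward_sample(chest_clinic, 1000, seed=42)


@pytest.fixture
def rand_bn():
    """Factory for random fixture networks."""
    return fixture_random_bn


@pytest.fixture
def rand_dataset():
    """Factory for random categorical datasets (uniform independent)."""

    def make(n_vars=3, cardinality=3, n=200, seed=0, names=None):
        rng = np.random.default_rng(seed)
        names = names or [f"X{i}" for i in range(n_vars)]
        variables = [
            Variable(nm, tuple(f"s{j}" for j in range(cardinality)))
            for nm in names
        ]
        rows = rng.integers(0, cardinality, size=(n, n_vars))
        return DiscreteDataset(variables, rows)

    return make
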