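import numpy as np
import pytest
from hypothesis import settings

from hvlforest import CliffSpec, ForestConfig, fit_forest, generate_cliff_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cliff_data():
    """A small planted-cliff dataset shared across tests."""
    spec = CliffSpec(n=300, d=3, sigma_low=0.1, sigma_high=2.0, seed=7)
    X, y, in_cliff = generate_cliff_dataset(spec)
    return X, y, in_cliff


@pytest.fixture(scope="session")
def small_forest(cliff_data):
    """A 25-tree forest on the shared dataset."""
    X, y, _ = cliff_data
    return fit_forest(X, y, ForestConfig(n_trees=25), seed=3)


@pytest.fixture(scope="session")
def tiny_forest():
    """Three trees on 20 points: small enough for brute-force re-routing."""
    rng = np.random.default_rng(11)
    X = rng.uniform(size=(20, 2))
    y = rng.normal(size=20)
    return fit_forest(X, y, ForestConfig(n_trees=3), seed=5)
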