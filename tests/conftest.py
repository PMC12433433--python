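import numpy as np
import pytest

from respstyles import GenCondition, ModelSpec, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_bipolar_dataset():
    """A modest ERS/MRS dataset shared by estimation smoke tests."""
    condition = GenCondition("ers_mrs", 300, 10, 1, sigma_rs=1.0, seed=11)
    data, items, traits, _ = generate_dataset(condition)
    return condition, data, items, traits


@pytest.fixture(scope="session")
def tiny_dataset():
    """J=2, K=3 toy with a handful of persons, for brute-force oracles."""
    spec = ModelSpec.create("null", 2, 1, 3)
    responses = np.array([[0, 2], [1, 1], [2, 0]])
    return spec, responses
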