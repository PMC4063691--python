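import numpy as np
import pytest

from mlstkit import load_default_scheme, simulate_dataset


@pytest.fixture(scope="session")
def default_scheme():
    return load_default_scheme()


@pytest.fixture(scope="session")
def clonal_dataset():
    """One moderately sized clonal dataset shared across tests."""
    return simulate_dataset(mode="clonal", n_isolates=50, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240609)
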