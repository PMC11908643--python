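import numpy as np
import pytest

from ssblend.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small, high-heritability dataset every ensemble test can share."""
    return simulate_dataset(SimParams(n=300, m=200, n_qtn=40, h2=0.8, seed=11))


@pytest.fixture(scope="session")
def medium_dataset():
    """Criterion-scale dataset (n=600, m=500) for end-to-end accuracy checks."""
    return simulate_dataset(SimParams(n=600, m=500, n_qtn=50, h2=0.8, seed=29))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
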