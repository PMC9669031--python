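import numpy as np
import pytest

import emgmod as em


@pytest.fixture(scope="session")
def modules3():
    return em.generate_modules(3, 8, seed=11)


@pytest.fixture(scope="session")
def dataset3(modules3):
    """One 3-module dataset at moderate noise, shared across tests."""
    return em.simulate_emg(modules3, eta=0.9, seed=12)


@pytest.fixture(scope="session")
def noiseless3(modules3):
    return em.simulate_emg(modules3, eta=0.0, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
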