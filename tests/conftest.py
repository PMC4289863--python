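import numpy as np
import pytest

import ectofit as ef


@pytest.fixture(scope="session")
def helix():
    return ef.make_helix(12)


@pytest.fixture(scope="session")
def bundle():
    return ef.make_bundle(2, 10)


@pytest.fixture(scope="session")
def toy_receptor():
    """Default dimeric toy receptor with its ground truth."""
    return ef.make_toy_receptor(ef.ToySpec())


@pytest.fixture(scope="session")
def docking_toy():
    return ef.make_docking_toy(seed=0)


@pytest.fixture(scope="session")
def benchmark():
    return ef.make_fitting_benchmark(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
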