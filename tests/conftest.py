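import numpy as np
import pytest

import odfpeaks as op


@pytest.fixture(scope="session")
def mesh724():
    return op.even_sphere(724)


@pytest.fixture(scope="session")
def mesh2562():
    return op.even_sphere(2562)


@pytest.fixture(scope="session")
def scheme():
    return op.default_scheme()


@pytest.fixture(scope="session")
def phantoms():
    return op.benchmark_phantoms()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
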