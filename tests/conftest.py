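import numpy as np
import pytest

from betaplus import DNAGeometry, PhysicsModel, builtin_f18, default_source


@pytest.fixture(scope="session")
def f18():
    return builtin_f18()


@pytest.fixture(scope="session")
def geom():
    return DNAGeometry()


@pytest.fixture(scope="session")
def source(geom):
    return default_source(geom)


@pytest.fixture(scope="session")
def physics():
    return PhysicsModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
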