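import numpy as np
import pytest

from hydrapattern.geometry import build_spheroid_mesh
from hydrapattern.model import default_parameters


@pytest.fixture(scope="session")
def sphere_l2():
    return build_spheroid_mesh(2, 0.0)


@pytest.fixture(scope="session")
def sphere_l3():
    return build_spheroid_mesh(3, 0.0)


@pytest.fixture(scope="session")
def sphere_l4():
    return build_spheroid_mesh(4, 0.0)


@pytest.fixture(scope="session")
def spheroid_l2():
    return build_spheroid_mesh(2, 4.0)


@pytest.fixture()
def params():
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
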