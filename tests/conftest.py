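import numpy as np
import pytest

from phagozip import (
    Sphere,
    build_sphere_mesh,
    standard_parameters,
)


@pytest.fixture(scope="session")
def unit_icosphere():
    return build_sphere_mesh(1.0, 0.12)


@pytest.fixture(scope="session")
def coarse_icosphere():
    return build_sphere_mesh(1.0, 0.3)


@pytest.fixture()
def small_sphere():
    return Sphere(radius=1.5)


@pytest.fixture()
def sp_params():
    return standard_parameters(1.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
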