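import numpy as np
import pytest

from ellipshape.shape_core import ellipsoid_of_cloud
from ellipshape.synthetic_data import GeneratorSpec, make_ellipsoid_cloud


@pytest.fixture(scope="session")
def big_fill():
    """~1e5-atom uniform fill of a (30, 20, 10) Å ellipsoid."""
    spec = GeneratorSpec((30.0, 20.0, 10.0), n_residues=12_500, seed=42)
    return make_ellipsoid_cloud(spec)


@pytest.fixture(scope="session")
def big_fill_ellipsoid(big_fill):
    return ellipsoid_of_cloud(big_fill)


@pytest.fixture(scope="session")
def small_cloud():
    """Fast ~2400-atom cloud for I/O and mapping tests."""
    spec = GeneratorSpec((22.0, 16.0, 12.0), n_residues=300, seed=7)
    return make_ellipsoid_cloud(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
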