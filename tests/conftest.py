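import numpy as np
import pytest

from hemiconn.core import BinaryMask, ProbMap
from hemiconn.synth import PhantomSpec, make_phantom_anatomy


@pytest.fixture(scope="session")
def anatomy():
    """Default phantom anatomy, shared across tests (read-only)."""
    return make_phantom_anatomy(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def unit_affine():
    return np.eye(4)


def make_prob(data, scale="fraction", voxel_dims=(1.0, 1.0, 1.0)):
    return ProbMap(data=np.asarray(data, dtype=float), scale=scale,
                   voxel_dims=voxel_dims)


def make_mask(data, voxel_dims=(1.0, 1.0, 1.0)):
    return BinaryMask(data=np.asarray(data, dtype=float), voxel_dims=voxel_dims)
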