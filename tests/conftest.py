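import numpy as np
import pytest

from cerebseg.phantom import PhantomSpec, generate_phantom
from cerebseg.protocol import build_protocol


@pytest.fixture(scope="session")
def protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def small_phantom(protocol):
    """A 32-voxel phantom volume/label pair shared by read-only tests."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), seed=7)
    return generate_phantom(spec, protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
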