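import numpy as np
import pytest

from megconn.geometry import generate_geometry


@pytest.fixture(scope="session")
def small_geometry():
    """16 channels, 6 ROIs x 2 voxels: enough structure for forward/inverse
    round trips at negligible cost."""
    return generate_geometry(16, 6, 2, seed=11)


@pytest.fixture(scope="session")
def full_geometry():
    """The study-scale geometry: 151 channels, 78 ROIs, 5 voxels per ROI."""
    return generate_geometry(151, 78, 5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
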