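import numpy as np
import pytest

from lesionkit.phantoms import PhantomSpec, make_head_phantom, make_template_with_rois
from lesionkit.volume_io import Volume


@pytest.fixture(scope="session")
def phantom():
    """Default noisy head phantom with ground-truth masks."""
    return make_head_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_head_phantom(PhantomSpec(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def template_and_rois():
    return make_template_with_rois()


def make_mask(shape, coords, affine=None):
    """Binary mask Volume from explicit voxel coordinates."""
    data = np.zeros(shape, dtype=np.float64)
    for c in coords:
        data[tuple(c)] = 1.0
    return Volume(data, np.eye(4) if affine is None else affine)
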