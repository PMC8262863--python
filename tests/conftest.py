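import numpy as np
import pytest

from polegrow import synthetic as sy
from polegrow.segmentation import AxialProfile


@pytest.fixture
def noiseless_optics():
    return sy.OpticsParams(psf_sigma=0.0, poisson_gain=0.0, read_noise_sd=0.0)


@pytest.fixture
def rod():
    """A 3 × 1 µm axis-aligned rod centred in a small frame."""
    return sy.CellGeometry((3.0, 2.0), 0.0, 3.0, 1.0)


def make_profile(values, length=None, cell_id=0, channel="label"):
    values = np.asarray(values, dtype=float)
    if length is None:
        length = (len(values) - 1) * 0.1
    positions = np.linspace(0.0, length, len(values))
    return AxialProfile(
        cell_id=cell_id, channel=channel, positions=positions, values=values
    )


@pytest.fixture
def profile_factory():
    return make_profile
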