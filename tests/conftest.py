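import numpy as np
import pytest

from qspect.calibration import reference_calibration
from qspect.phantom import GridSpec


@pytest.fixture
def small_grid() -> GridSpec:
    """32^3 grid at 2 mm isotropic spacing — small enough for brute force."""
    return GridSpec((32, 32, 32), (2.0, 2.0, 2.0))


@pytest.fixture
def fine_grid() -> GridSpec:
    """64^3 at 1 mm, for voxelization-accuracy checks."""
    return GridSpec((64, 64, 64), (1.0, 1.0, 1.0))


@pytest.fixture
def ref_model():
    return reference_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(20230322)
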