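import numpy as np
import pytest

from stimmap.io import ElectrodeStim, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_grid():
    """11^3 grid, 1 mm isotropic, centred on the origin (symmetric about x=0)."""
    affine = np.eye(4)
    affine[:3, 3] = -5.0
    return Volume(np.zeros((11, 11, 11)), affine)


@pytest.fixture
def stim():
    return ElectrodeStim(
        patient_id="P1",
        contact_mm=[0.0, 0.0, 0.0],
        amplitude=2.0,
        amplitude_unit="V",
    )


def random_volume(rng, shape=(10, 10, 10), voxel=1.0):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = rng.uniform(-5, 5, 3)
    return Volume(rng.random(shape), affine)
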