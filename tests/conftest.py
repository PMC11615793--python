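import numpy as np
import pytest

from fetalvol.synthetic import PhantomSpec, make_phantom
from fetalvol.volumes import BinaryMask, Volume, VolumeGrid, normalize_intensity


@pytest.fixture
def small_grid():
    return VolumeGrid((16, 16, 16), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(small_grid, rng):
    return Volume(rng.random(small_grid.shape), small_grid)


@pytest.fixture
def random_mask(small_grid, rng):
    return BinaryMask((rng.random(small_grid.shape) > 0.7).astype(np.uint8), small_grid)


@pytest.fixture(scope="session")
def phantom_pair():
    """A clean 48-cubed head phantom and its normalized volume."""
    grid = VolumeGrid((48, 48, 48), 1.0)
    spec = PhantomSpec(
        grid=grid,
        head_semiaxes_mm=(14.0, 13.0, 10.0),
        skull_thickness_mm=2.0,
        speckle_strength=0.0,
        seed=7,
    )
    vol, mask, icv = make_phantom(spec)
    return normalize_intensity(vol), mask, icv, spec
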