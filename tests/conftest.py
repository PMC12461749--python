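import numpy as np
import pytest

from cryoplan import LabelVolume


def make_volume(array, spacing=(1.0, 1.0, 1.0), origin=None, directions=None):
    arr = np.asarray(array)
    if origin is None:
        # center the grid on the world origin
        origin = -(np.asarray(arr.shape) - 1) / 2.0 * np.asarray(spacing, dtype=float)
    if directions is None:
        directions = np.eye(3)
    return LabelVolume(array=arr, spacing=np.asarray(spacing, dtype=float),
                       origin=np.asarray(origin, dtype=float), directions=directions)


def sphere_volume(radius_mm, shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                  center=(0.0, 0.0, 0.0)):
    """Binary sphere mask by voxel-center membership on a centered grid."""
    vol = make_volume(np.zeros(shape, dtype=np.uint8), spacing=spacing)
    centers = vol.voxel_centers()
    inside = np.linalg.norm(centers - np.asarray(center, dtype=float), axis=1) <= radius_mm
    return vol.with_array(inside.reshape(shape).astype(np.uint8))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_phantom():
    """A 32^3, 2 mm-spacing phantom small enough for brute-force checks."""
    from cryoplan import PhantomSpec, make_phantom

    spec = PhantomSpec(shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0), seed=7)
    return make_phantom(spec)
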