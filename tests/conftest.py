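import numpy as np
import pytest

from sabreval.grids import BinaryMask, GridGeometry, VolumeGrid


def make_geometry(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=None):
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(shape)
    if origin is None:
        origin = -(np.asarray(shape) - 1) / 2.0 * spacing
    return GridGeometry(origin=origin, spacing=spacing, shape=shape)


@pytest.fixture
def geom8():
    return make_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def affine_volume(geom, coeffs=(2.0, -1.0, 0.5), const=3.0, fill=0.0):
    """Scalar field a.x + c, exactly representable by trilinear interpolation."""
    centers = geom.voxel_centers()
    vals = centers @ np.asarray(coeffs, dtype=float) + const
    return VolumeGrid(geom, vals, fill=fill)


def ball_mask(geom, center, radius_mm):
    centers = geom.voxel_centers()
    d = np.linalg.norm(centers - np.asarray(center, dtype=float), axis=-1)
    return BinaryMask(geom, (d <= radius_mm).astype(np.uint8))
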