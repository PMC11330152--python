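"""Geometry-aware 3D grid containers and resampling primitives.

All grids are axis-aligned in a world frame measured in millimetres, with
voxel centers at ``origin + index * spacing`` (0-based indices).  Scalar
volumes hold HU for CT-like images and cGy for dose grids; displacement
fields hold per-voxel 3-vectors in mm using the fixed-frame (pull-back)
convention: a fixed-frame point ``x`` corresponds to the moving-frame point
``x + u(x)``.

Oblique orientations are deliberately unsupported — every image produced or
consumed here is axis-aligned, which keeps resampling exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "VolumeGrid",
    "BinaryMask",
    "DisplacementField",
    "RigidTransform",
    "sample_at_points",
    "resample_to",
    "mask_volume_cc",
    "equivalent_sphere_diameter_mm",
]

# Outside-grid fill values by grid role: dose and occupancy vanish outside
# the field of view, CT-like images continue as air.
FILL_AIR_HU = -1000.0
FILL_ZERO = 0.0


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size != 3 or not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be a finite 3-vector, got {v!r}")
    return a


@dataclass(frozen=True)
class GridGeometry:
    """Origin (mm), spacing (mm) and shape of an axis-aligned voxel grid."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        object.__setattr__(self, "spacing", _as_vec3(self.spacing, "spacing"))
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (*shape, 3)."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm)."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return self.origin + idx * self.spacing

    def same_as(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def _check_geometry_values(geom: GridGeometry, values: np.ndarray, ncomp: int | None):
    expected = geom.shape if ncomp is None else (*geom.shape, ncomp)
    if values.shape != expected:
        raise ValueError(f"values shape {values.shape} does not match geometry {expected}")
    if not np.all(np.isfinite(values)):
        raise ValueError("grid values must all be finite")


@dataclass
class VolumeGrid:
    """Axis-aligned scalar field (HU or cGy) with grid geometry metadata."""

    geometry: GridGeometry
    values: np.ndarray
    fill: float = FILL_ZERO  # value returned for samples outside the grid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_geometry_values(self.geometry, self.values, None)

    @property
    def shape(self):
        return self.geometry.shape

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(self.geometry, values, fill=self.fill)


@dataclass
class BinaryMask:
    """Structure occupancy on a grid; values restricted to {0, 1}."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.dtype == bool:
            v = v.astype(np.uint8)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8)
        _check_geometry_values(self.geometry, self.values, None)

    @property
    def shape(self):
        return self.geometry.shape

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    @property
    def volume_cc(self) -> float:
        return mask_volume_cc(self)


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm on a fixed-frame grid."""

    geometry: GridGeometry
    values: np.ndarray  # shape (*shape, 3)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_geometry_values(self.geometry, self.values, 3)

    @property
    def shape(self):
        return self.geometry.shape

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=-1)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map y = R x + t in world mm (couch-correction style)."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "translation", _as_vec3(self.translation, "translation"))
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", R)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.translation, 0) and np.allclose(self.rotation, np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(translation=-(Rinv @ self.translation), rotation=Rinv)


def _fill_value(grid) -> float:
    if isinstance(grid, BinaryMask):
        return 0.0
    return getattr(grid, "fill", 0.0)


def sample_at_points(grid, points, mode: str = "trilinear") -> np.ndarray:
    """Sample a scalar grid at world points (mm).

    ``trilinear`` returns the weighted average of the 8 surrounding voxel
    centers; ``nearest`` snaps to the closest center.  Points outside the
    grid return the grid's declared fill value (0 for masks and dose,
    -1000 HU for CT images).
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must be 3-vectors")
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    order = {"trilinear": 1, "nearest": 0}[mode]
    idx = grid.geometry.world_to_index(pts)
    out = ndimage.map_coordinates(
        np.asarray(grid.values, dtype=float),
        idx.T,
        order=order,
        mode="constant",
        cval=_fill_value(grid),
    )
    return float(out[0]) if squeeze else out


def sample_field_at_indices(values: np.ndarray, idx: np.ndarray, cval: float = 0.0,
                            mode: str = "constant", order: int = 1) -> np.ndarray:
    """map_coordinates helper: sample ``values`` at continuous indices (3, ...)."""
    return ndimage.map_coordinates(values, idx, order=order, mode=mode, cval=cval)


def resample_to(grid, target_geometry: GridGeometry, mode: str = "trilinear"):
    """Resample a grid onto a target geometry (each target voxel center is
    sampled from the source).  Masks are thresholded back to {0, 1}."""
    centers = target_geometry.voxel_centers().reshape(-1, 3)
    vals = sample_at_points(grid, centers, mode=mode).reshape(target_geometry.shape)
    if isinstance(grid, BinaryMask):
        return BinaryMask(target_geometry, (vals >= 0.5).astype(np.uint8))
    return VolumeGrid(target_geometry, vals, fill=_fill_value(grid))


def mask_volume_cc(mask: BinaryMask) -> float:
    """Structure volume in cc: voxel count times voxel volume (mm^3) / 1000."""
    return float(mask.values.sum()) * mask.geometry.voxel_volume_mm3 / 1000.0


def equivalent_sphere_diameter_mm(volume_cc: float) -> float:
    """Diameter (mm) of the sphere with the same volume: d = 2 (3V / 4 pi)^(1/3)."""
    if volume_cc < 0:
        raise ValueError("volume must be non-negative")
    v_mm3 = volume_cc * 1000.0
    return 2.0 * (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
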