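"""Cubic B-spline lattices on regular grids.

Shared by the deformable registration (as the transform parameterisation)
and by the synthetic cohort generator (as the ground-truth deformation
model), so that registration recovery has a well-defined target.
"""

from __future__ import annotations

import numpy as np

from .grids import GridGeometry

__all__ = ["cubic_bspline", "BsplineLattice"]


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis function with support |t| < 2 (knot spacing 1)."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    inner = t < 1
    out[inner] = 2.0 / 3.0 - t[inner] ** 2 + 0.5 * t[inner] ** 3
    shell = (t >= 1) & (t < 2)
    out[shell] = (2.0 - t[shell]) ** 3 / 6.0
    return out


class BsplineLattice:
    """Separable cubic B-spline expansion from a regular control-point grid
    (spacing ``cp_spacing_mm``) onto the voxel centers of ``geometry``.

    The expansion and its adjoint are tensor-product contractions with the
    per-axis basis matrices, which keeps the registration gradient exact.
    """

    def __init__(self, geometry: GridGeometry, cp_spacing_mm: float):
        if cp_spacing_mm <= 0:
            raise ValueError("control-point spacing must be positive")
        self.geometry = geometry
        self.cp_spacing_mm = float(cp_spacing_mm)
        self._B = []          # per-axis (n_vox, n_ctrl) basis matrices
        self.control_shape = []
        for a in range(3):
            x = geometry.origin[a] + geometry.spacing[a] * np.arange(geometry.shape[a])
            # control points start one knot before the grid so the cubic
            # support covers every voxel
            first = geometry.origin[a] - cp_spacing_mm
            extent = x[-1] - first
            n_ctrl = int(np.ceil(extent / cp_spacing_mm)) + 3
            c = first + cp_spacing_mm * np.arange(n_ctrl)
            B = cubic_bspline((x[:, None] - c[None, :]) / cp_spacing_mm)
            self._B.append(B)
            self.control_shape.append(n_ctrl)
        self.control_shape = tuple(self.control_shape)

    def expand(self, coeff: np.ndarray) -> np.ndarray:
        """Dense scalar field (*geometry.shape,) from control coefficients."""
        Bx, By, Bz = self._B
        return np.einsum("ia,jb,kc,abc->ijk", Bx, By, Bz, coeff, optimize=True)

    def adjoint(self, dense: np.ndarray) -> np.ndarray:
        """Transpose of :meth:`expand` (gradient back-projection)."""
        Bx, By, Bz = self._B
        return np.einsum("ia,jb,kc,ijk->abc", Bx, By, Bz, dense, optimize=True)

    def expand_vector(self, coeff: np.ndarray) -> np.ndarray:
        """Dense 3-vector field (*shape, 3) from coefficients (*control, 3)."""
        return np.stack([self.expand(coeff[..., a]) for a in range(3)], axis=-1)
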