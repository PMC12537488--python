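"""Voxelized 3D magnetization vector fields.

The coordinate convention used throughout the package is right-handed with
``z`` along the particle long axis (base at low ``z``, tip at high ``z``)
and ``x`` along the X-ray beam at zero tilt.  Voxel indices are 0-based and
the physical position of the center of voxel ``(i, j, k)`` is
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class VectorField3D:
    """A magnetization vector field sampled on a regular cubic-voxel grid.

    Parameters
    ----------
    m : ndarray, shape (3, nx, ny, nz)
        Magnetization components ``(M_x, M_y, M_z)`` in A/m.  Zero outside
        the mask.
    mask : ndarray of bool, shape (nx, ny, nz)
        True inside the magnetic material.
    voxel_size : float
        Edge length of the cubic voxels (m).
    origin : ndarray, shape (3,)
        Physical coordinate of the low corner of voxel (0, 0, 0) (m).
    """

    m: np.ndarray
    mask: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.m.ndim != 4 or self.m.shape[0] != 3:
            raise ValueError("m must have shape (3, nx, ny, nz)")
        if self.m.shape[1:] != self.mask.shape:
            raise ValueError("mask shape does not match field grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers, as three 1-D arrays."""
        h = self.voxel_size
        return tuple(
            self.origin[a] + (np.arange(self.grid_shape[a]) + 0.5) * h
            for a in range(3)
        )

    # -- derived quantities ---------------------------------------------
    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.m**2).sum(axis=0))

    def unit_vectors(self) -> np.ndarray:
        """Return unit direction vectors inside the mask (zeros outside)."""
        mag = self.magnitude()
        out = np.zeros_like(self.m)
        inside = self.mask & (mag > 0)
        out[:, inside] = self.m[:, inside] / mag[inside]
        return out

    def net_moment(self) -> np.ndarray:
        """Total magnetic moment (A·m^2): integral of M over the volume."""
        return self.m[:, self.mask].sum(axis=1) * self.voxel_size**3

    def copy(self) -> "VectorField3D":
        return replace(self, m=self.m.copy(), mask=self.mask.copy(),
                       origin=self.origin.copy())


def assert_unit_magnitude(field3d: VectorField3D, M_s: float,
                          rtol: float = 1e-6) -> None:
    """Raise if |M| deviates from M_s inside the mask (or from 0 outside)."""
    mag = field3d.magnitude()
    if field3d.mask.any():
        dev = np.abs(mag[field3d.mask] / M_s - 1.0).max()
        if dev > rtol:
            raise ValueError(
                f"|M| deviates from M_s by {dev:.2e} inside the mask")
    outside = ~field3d.mask
    if outside.any() and mag[outside].max() > rtol * M_s:
        raise ValueError("non-zero magnetization outside the mask")
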