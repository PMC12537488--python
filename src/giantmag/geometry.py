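"""Spearhead particle geometry as a stack of elliptical frustrums.

A giant spearhead magnetofossil is modelled as a solid of revolutionally
symmetric cross section (optionally squashed into an ellipse) built from a
stack of thin frustrum slabs along the long axis ``z``.  The idealized
radial profile is a cylinder over the basal body smoothly tapering to a
cone at the tip.  The default dimensions follow the studied "no-stalk"
spearhead: base radius 0.55 µm, tip radius 0.058 µm, length 2.25 µm,
90 slabs of 25 nm, minor/major axis ratio 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: Fraction of the length occupied by the cylindrical body before the
#: linear taper to the tip begins.
BODY_FRACTION = 0.55


@dataclass
class ParticleGeometry:
    """Stacked-frustrum solid with elliptical cross section.

    ``major_radii`` holds the semi-major axis (along ``x``) at each of the
    ``n + 1`` slab boundaries; the semi-minor axis (along ``y``) is
    ``ellipticity * major``.  ``z = 0`` is the base, ``z = long_axis_length``
    the tip.
    """

    frustrum_heights: np.ndarray
    major_radii: np.ndarray
    ellipticity: float = 0.85

    def __post_init__(self) -> None:
        self.frustrum_heights = np.asarray(self.frustrum_heights, dtype=float)
        self.major_radii = np.asarray(self.major_radii, dtype=float)
        if self.frustrum_heights.size == 0:
            raise ValueError("geometry must contain at least one slab")
        if self.major_radii.size != self.frustrum_heights.size + 1:
            raise ValueError("need one radius per slab boundary")
        if (self.frustrum_heights <= 0).any():
            raise ValueError("slab heights must be positive")
        if (self.major_radii <= 0).any():
            raise ValueError("all radii must be positive")
        if not 0 < self.ellipticity <= 1:
            raise ValueError("ellipticity must lie in (0, 1]")

    @property
    def n_frustrums(self) -> int:
        return self.frustrum_heights.size

    @property
    def long_axis_length(self) -> float:
        return float(self.frustrum_heights.sum())

    @property
    def boundary_z(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.frustrum_heights)])

    @property
    def base_major_radius(self) -> float:
        return float(self.major_radii.max())

    @property
    def base_minor_radius(self) -> float:
        return self.base_major_radius * self.ellipticity

    def major_radius_at(self, z) -> np.ndarray:
        """Semi-major axis at height(s) ``z``, linear between boundaries."""
        return np.interp(z, self.boundary_z, self.major_radii)

    def contains(self, x, y, z) -> np.ndarray:
        """Boolean inside test for physical points (broadcastable arrays)."""
        a = self.major_radius_at(z)
        b = a * self.ellipticity
        inside_z = (np.asarray(z) >= 0) & (np.asarray(z) <= self.long_axis_length)
        return inside_z & ((x / a) ** 2 + (y / b) ** 2 <= 1.0)


def build_spearhead_geometry(
    base_radius: float,
    tip_radius: float,
    total_length: float,
    n_frustrums: int = 90,
    ellipticity: float = 0.85,
    body_fraction: float = BODY_FRACTION,
) -> ParticleGeometry:
    """Idealized spearhead: cylindrical body, linear taper to the tip.

    The radial profile is constant at ``base_radius`` over the first
    ``body_fraction`` of the length, then tapers linearly to ``tip_radius``
    at the tip.  The knee between body and taper is smoothed over two
    slabs so the projected outline has no hard corner.

    Raises
    ------
    ValueError
        For non-positive dimensions, ``tip_radius >= base_radius`` or
        fewer than 2 frustrums.
    """
    if min(base_radius, tip_radius, total_length) <= 0:
        raise ValueError("all dimensions must be positive")
    if tip_radius > base_radius:
        raise ValueError("tip_radius must not exceed base_radius")
    if n_frustrums < 2:
        raise ValueError("need at least 2 frustrums")

    heights = np.full(n_frustrums, total_length / n_frustrums)
    zb = np.concatenate([[0.0], np.cumsum(heights)])
    z_knee = body_fraction * total_length
    radii = np.where(
        zb <= z_knee,
        base_radius,
        base_radius + (tip_radius - base_radius)
        * (zb - z_knee) / (total_length - z_knee),
    )
    # smooth the knee over ~2 slabs with a clamped [1,2,1]/4 pass (twice);
    # linear segments away from the knee are unaffected
    for _ in range(2):
        interior = (radii[:-2] + 2 * radii[1:-1] + radii[2:]) / 4.0
        radii = np.concatenate([[radii[0]], interior, [radii[-1]]])
    return ParticleGeometry(heights, radii, ellipticity)


@dataclass
class VoxelGrid:
    """A boolean occupancy mask on a regular cubic-voxel grid."""

    mask: np.ndarray
    voxel_size: float
    origin: np.ndarray

    @property
    def volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_size**3

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.voxel_size
        return tuple(
            self.origin[a] + (np.arange(self.mask.shape[a]) + 0.5) * h
            for a in range(3)
        )


def voxelize(geometry: ParticleGeometry, voxel_size: float) -> VoxelGrid:
    """Rasterize the frustrum solid: a voxel is inside iff its center is.

    The grid tightly covers the solid with a one-voxel margin on every
    side; the long axis runs along the third array axis and the symmetry
    axis passes through the grid center in x and y.

    Raises
    ------
    ValueError
        If ``voxel_size`` exceeds a quarter of the base minor radius (the
        cross section would no longer be resolved).
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if voxel_size > geometry.base_minor_radius / 4:
        raise ValueError(
            f"voxel_size {voxel_size:g} m too coarse: must be at most a "
            f"quarter of the base minor radius "
            f"({geometry.base_minor_radius / 4:g} m) to resolve the "
            "cross section")

    h = voxel_size
    a = geometry.base_major_radius
    b = geometry.base_minor_radius
    L = geometry.long_axis_length
    nx = 2 * (int(np.ceil(a / h)) + 1)
    ny = 2 * (int(np.ceil(b / h)) + 1)
    nz = int(np.ceil(L / h)) + 2
    origin = np.array([-nx * h / 2.0, -ny * h / 2.0, -h])
    x = origin[0] + (np.arange(nx) + 0.5) * h
    y = origin[1] + (np.arange(ny) + 0.5) * h
    z = origin[2] + (np.arange(nz) + 0.5) * h
    mask = geometry.contains(
        x[:, None, None], y[None, :, None], z[None, None, :])
    return VoxelGrid(mask, h, origin)


def is_simply_connected(mask: np.ndarray) -> bool:
    """True if the mask is one connected component without internal voids."""
    if not mask.any():
        return False
    _, n = ndimage.label(mask)
    if n != 1:
        return False
    _, n_bg = ndimage.label(~mask)
    return n_bg == 1
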