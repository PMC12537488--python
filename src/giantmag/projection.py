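"""Phase-XMCD projection forward model for dual-axis tilt series.

The XMCD signal of a projection is the line integral along the X-ray beam
of the magnetization component parallel to the beam; the charge (phase)
signal is the projected thickness of the material.  Projections are
simulated by rotating the volume into the laboratory frame by trilinear
resampling and summing along the beam axis ``x``.  The back-projection
operator is the exact adjoint of the resampling (same interpolation
weights, scattered instead of gathered), which the iterative
reconstruction relies on.

Acquisition geometry: the first tilt axis is the laboratory ``y`` axis;
the second series is acquired after rotating the sample by 90° about the
sample normal (the beam direction at zero tilt) and tilting about ``y``
again.  Positive tilt is a right-handed rotation about the named axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fields import VectorField3D

__all__ = [
    "TiltSeries", "rotation_matrix", "beam_direction",
    "xmcd_project", "charge_project", "simulate_tilt_series",
    "project_scalar", "backproject_scalar", "lab_shape_for",
]


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def _ry(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_matrix(axis_id: str, angle_deg: float) -> np.ndarray:
    """Sample-to-lab rotation for a tilt of ``angle_deg`` about a series
    axis.  ``axis_id`` is ``"first"`` (tilt about lab y) or ``"second"``
    (90° pre-rotation about the sample normal, then tilt about lab y)."""
    a = np.radians(angle_deg)
    if axis_id == "first":
        return _ry(a)
    if axis_id == "second":
        return _ry(a) @ _rx(np.pi / 2)
    raise ValueError("axis_id must be 'first' or 'second'")


def beam_direction(R: np.ndarray) -> np.ndarray:
    """Beam direction (lab +x) expressed in the sample frame."""
    return R.T @ np.array([1.0, 0.0, 0.0])


def _rotation_from_beam(beam: np.ndarray) -> np.ndarray:
    """Minimal rotation taking the sample-frame beam direction to lab +x."""
    b = np.asarray(beam, dtype=float)
    n = np.linalg.norm(b)
    if abs(n - 1.0) > 1e-8:
        raise ValueError("beam_direction must be a unit vector")
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(b, x)
    c = float(b @ x)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([-1.0, 1.0, -1.0])  # 180° about y
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# trilinear gather / scatter (exact adjoint pair)
# ---------------------------------------------------------------------------

def _corner_data(coords: np.ndarray, shape: tuple[int, int, int]):
    """Shared corner indices and weights for trilinear interpolation.

    ``coords`` has shape (3, N) in voxel-index units (0 at the center of
    the first voxel).  Points outside the grid are dropped.
    """
    i0 = np.floor(coords).astype(np.int64)
    f = coords - i0
    valid = np.ones(coords.shape[1], dtype=bool)
    for a in range(3):
        valid &= (i0[a] >= 0) & (i0[a] <= shape[a] - 2)
    i0 = i0[:, valid]
    f = f[:, valid]
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    base = strides @ i0
    corners = []
    for dx in (0, 1):
        wx = f[0] if dx else 1.0 - f[0]
        for dy in (0, 1):
            wy = f[1] if dy else 1.0 - f[1]
            for dz in (0, 1):
                wz = f[2] if dz else 1.0 - f[2]
                off = dx * strides[0] + dy * strides[1] + dz * strides[2]
                corners.append((base + off, wx * wy * wz))
    return valid, corners


def trilinear_gather(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample ``vol`` at fractional voxel coordinates (zeros outside)."""
    valid, corners = _corner_data(coords, vol.shape)
    flat = vol.ravel()
    out = np.zeros(coords.shape[1])
    acc = np.zeros(valid.sum())
    for idx, w in corners:
        acc += w * flat[idx]
    out[valid] = acc
    return out


def trilinear_scatter(values: np.ndarray, coords: np.ndarray,
                      shape: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of :func:`trilinear_gather`: spread values into a volume."""
    valid, corners = _corner_data(coords, shape)
    vals = values[valid]
    n = int(np.prod(shape))
    out = np.zeros(n)
    for idx, w in corners:
        out += np.bincount(idx, weights=w * vals, minlength=n)
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# projection geometry
# ---------------------------------------------------------------------------

def lab_shape_for(vol_shape: tuple[int, int, int],
                  axis_id: str) -> tuple[int, int, int]:
    """Laboratory grid shape that contains the rotated volume for any
    tilt angle of the given series axis."""
    nx, ny, nz = vol_shape
    if axis_id == "first":
        s = int(np.ceil(np.hypot(nx, nz))) + 2
        return (s, ny, s)
    if axis_id == "second":
        s = int(np.ceil(np.hypot(nx, ny))) + 2
        return (s, nz, s)
    raise ValueError("axis_id must be 'first' or 'second'")


def _lab_coords(lab_shape: tuple[int, int, int], vol_shape, R: np.ndarray
                ) -> np.ndarray:
    """Sample-frame voxel coordinates of every lab voxel center (3, N)."""
    centers_lab = [(np.arange(n) - (n - 1) / 2.0) for n in lab_shape]
    gx, gy, gz = np.meshgrid(*centers_lab, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sample = R.T @ pts
    for a in range(3):
        sample[a] += (vol_shape[a] - 1) / 2.0
    return sample


def project_scalar(vol: np.ndarray, R: np.ndarray,
                   lab_shape: tuple[int, int, int],
                   voxel_size: float) -> np.ndarray:
    """Line integral along lab x of the rotated scalar volume.

    Returns an image of shape ``(lab_shape[1], lab_shape[2])`` in units of
    [vol units] × meters.
    """
    coords = _lab_coords(lab_shape, vol.shape, R)
    samples = trilinear_gather(vol, coords).reshape(lab_shape)
    return samples.sum(axis=0) * voxel_size


def backproject_scalar(image: np.ndarray, R: np.ndarray,
                       vol_shape: tuple[int, int, int],
                       lab_nx: int, voxel_size: float) -> np.ndarray:
    """Exact adjoint of :func:`project_scalar` for a given lab depth."""
    lab_shape = (lab_nx, image.shape[0], image.shape[1])
    coords = _lab_coords(lab_shape, vol_shape, R)
    values = np.broadcast_to(image[None, :, :], lab_shape).ravel()
    return trilinear_scatter(values * voxel_size, coords, vol_shape)


# ---------------------------------------------------------------------------
# user-facing operations
# ---------------------------------------------------------------------------

def xmcd_project(field3d: VectorField3D, beam: np.ndarray,
                 pixel_size: float | None = None) -> np.ndarray:
    """Phase-XMCD projection: line integral of M·(beam direction).

    The image plane is perpendicular to the beam; its orientation is fixed
    by the minimal rotation taking the beam to the lab ``x`` axis.  Pixel
    size defaults to (and currently must equal) the voxel size.
    """
    if not field3d.mask.any():
        raise ValueError("field has an empty mask")
    if pixel_size is not None and not np.isclose(pixel_size,
                                                 field3d.voxel_size):
        raise NotImplementedError("pixel_size must equal the voxel size")
    R = _rotation_from_beam(np.asarray(beam, dtype=float))
    s = int(np.ceil(np.linalg.norm(field3d.grid_shape))) + 2
    lab_shape = (s, s, s)
    scalar = np.tensordot(beam_direction(R), field3d.m, axes=(0, 0))
    return project_scalar(scalar, R, lab_shape, field3d.voxel_size)


def charge_project(mask: np.ndarray, voxel_size: float,
                   R: np.ndarray | None = None,
                   lab_shape: tuple[int, int, int] | None = None
                   ) -> np.ndarray:
    """Projected thickness map (m) of the occupancy mask."""
    if R is None:
        R = np.eye(3)
    if lab_shape is None:
        s = int(np.ceil(np.linalg.norm(mask.shape))) + 2
        lab_shape = (s, s, s)
    return project_scalar(mask.astype(float), R, lab_shape, voxel_size)


@dataclass
class TiltSeries:
    """A stack of projections acquired about one rotation axis.

    ``images`` are XMCD signal maps, one per angle; ``charge_images`` are
    the matching projected-thickness maps used for alignment.  Applied
    shifts record the ground-truth misalignments injected by the
    simulator (axis-0 and axis-1 pixel offsets per image).
    """

    images: np.ndarray          # (n_angles, n0, n1)
    angles: np.ndarray          # degrees, strictly increasing
    axis_id: str                # "first" | "second"
    pixel_size: float
    applied_shifts: np.ndarray = None
    charge_images: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, h, w) stack")
        if self.angles.size != self.images.shape[0]:
            raise ValueError("one angle per image required")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.axis_id not in ("first", "second"):
            raise ValueError("axis_id must be 'first' or 'second'")
        if self.applied_shifts is None:
            self.applied_shifts = np.zeros((self.images.shape[0], 2))
        self.applied_shifts = np.asarray(self.applied_shifts, dtype=float)

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    def nearest_to_angle(self, angle_deg: float) -> int:
        return int(np.argmin(np.abs(self.angles - angle_deg)))


def simulate_tilt_series(field3d: VectorField3D, axis_id: str,
                         angles: Sequence[float], noise_sd: float = 0.0,
                         shift_sd: float = 0.0, seed: int = 0,
                         with_charge: bool = True) -> TiltSeries:
    """Simulate a phase-XMCD tilt series about one rotation axis.

    For each tilt angle the XMCD projection (line integral of the beam-
    parallel magnetization component) and, optionally, the charge
    projection of the mask are computed; Gaussian signal noise of standard
    deviation ``noise_sd`` (same units as the images) and random per-image
    shifts (integer plus subpixel, standard deviation ``shift_sd`` pixels)
    are then applied.  The true shifts are recorded in
    ``applied_shifts``.  Deterministic for a fixed seed.
    """
    angles = np.asarray(angles, dtype=float)
    if np.any(np.abs(angles) >= 90.0):
        raise ValueError("tilt angles must lie in (-90°, 90°)")
    rng = np.random.default_rng(seed)
    h = field3d.voxel_size
    lab_shape = lab_shape_for(field3d.grid_shape, axis_id)
    imgs, charges, shifts = [], [], []
    for ang in angles:
        R = rotation_matrix(axis_id, float(ang))
        scalar = np.tensordot(beam_direction(R), field3d.m, axes=(0, 0))
        img = project_scalar(scalar, R, lab_shape, h)
        chg = (project_scalar(field3d.mask.astype(float), R, lab_shape, h)
               if with_charge else None)
        shift = np.zeros(2)
        if shift_sd > 0:
            shift = (rng.integers(-2, 3, size=2)
                     + rng.normal(scale=shift_sd, size=2))
        if shift.any():
            img = ndimage.shift(img, shift, order=1, mode="constant")
            if chg is not None:
                chg = ndimage.shift(chg, shift, order=1, mode="constant")
        if noise_sd > 0:
            img = img + rng.normal(scale=noise_sd, size=img.shape)
        imgs.append(img)
        if chg is not None:
            charges.append(chg)
        shifts.append(shift)
    return TiltSeries(
        np.array(imgs), angles, axis_id, h,
        applied_shifts=np.array(shifts),
        charge_images=np.array(charges) if charges else None,
    )
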