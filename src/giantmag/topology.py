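"""Topological analysis of 3D magnetization fields.

Extracts the interpretive features of a single-vortex state: the vortex
core path (the in-plane winding singularity traced slice by slice along
``z``), its polarization (sign of ``M_z`` on the core), Bloch points
(core-polarity reversals, at which |M| is locally depressed), and the
medial ``M_z = 0`` domain wall with its in-plane twist profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import measure

from .fields import VectorField3D

__all__ = ["winding_number", "trace_core", "detect_bloch_points",
           "extract_medial_wall", "CorePath", "MedialWall", "BlochPoint",
           "CoreTraceError", "DegenerateLoopError"]


class CoreTraceError(RuntimeError):
    """Raised when the vortex core cannot be traced.

    Carries ``slice_index`` of the offending slice when applicable.
    """

    def __init__(self, message: str, slice_index: int | None = None):
        super().__init__(message)
        self.slice_index = slice_index


class DegenerateLoopError(RuntimeError):
    """Raised when a winding loop crosses a zero of the in-plane field."""


# ---------------------------------------------------------------------------
# winding numbers
# ---------------------------------------------------------------------------

def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def winding_number(field3d: VectorField3D, z_slice: int,
                   loop: np.ndarray) -> int:
    """In-plane winding number along a closed pixel loop.

    ``loop`` is an (n, 2) array of (ix, iy) pixel indices (the closing
    edge back to the first vertex is implied).  The winding number is the
    accumulated in-plane angle change around the loop divided by 2π,
    rounded to the nearest integer.

    Raises
    ------
    DegenerateLoopError
        If the in-plane magnetization vanishes on a loop vertex.
    ValueError
        If a loop vertex lies outside the mask.
    """
    loop = np.asarray(loop, dtype=int)
    mx = field3d.m[0, loop[:, 0], loop[:, 1], z_slice]
    my = field3d.m[1, loop[:, 0], loop[:, 1], z_slice]
    if not field3d.mask[loop[:, 0], loop[:, 1], z_slice].all():
        raise ValueError("loop must lie inside the mask")
    mag = np.hypot(mx, my)
    if (mag < 1e-12 * max(mag.max(), 1e-300)).any() or (mag == 0).any():
        raise DegenerateLoopError(
            "in-plane magnetization vanishes on the loop")
    ang = np.arctan2(my, mx)
    total = _wrap(np.diff(np.concatenate([ang, ang[:1]]))).sum()
    return int(np.rint(total / (2 * np.pi)))


def rectangle_loop(center: tuple[int, int], half: int) -> np.ndarray:
    """Axis-aligned square pixel loop of half-width ``half`` around a
    center pixel, counter-clockwise."""
    cx, cy = center
    xs = range(cx - half, cx + half + 1)
    ys = range(cy - half, cy + half + 1)
    pts = ([(x, cy - half) for x in xs]
           + [(cx + half, y) for y in list(ys)[1:]]
           + [(x, cy + half) for x in list(xs)[-2::-1]]
           + [(cx - half, y) for y in list(ys)[-2:0:-1]])
    return np.asarray(pts)


def _plaquette_winding(mx: np.ndarray, my: np.ndarray) -> np.ndarray:
    """Winding density on each 2x2 plaquette of a slice (integer array of
    shape (nx-1, ny-1))."""
    ang = np.arctan2(my, mx)
    # accumulate wrapped angle differences counter-clockwise around each
    # plaquette: (i,j) -> (i+1,j) -> (i+1,j+1) -> (i,j+1) -> (i,j)
    d1 = _wrap(ang[1:, :-1] - ang[:-1, :-1])
    d2 = _wrap(ang[1:, 1:] - ang[1:, :-1])
    d3 = _wrap(ang[:-1, 1:] - ang[1:, 1:])
    d4 = _wrap(ang[:-1, :-1] - ang[:-1, 1:])
    return np.rint((d1 + d2 + d3 + d4) / (2 * np.pi)).astype(int)


# ---------------------------------------------------------------------------
# core tracing
# ---------------------------------------------------------------------------

@dataclass
class BlochPoint:
    """A core-polarity reversal with its local |M| depression."""

    position: np.ndarray        # (x, y, z) in voxel coordinates
    min_magnitude: float        # local minimum of |M| near the crossing
    magnitude_ratio: float      # min |M| / median inside-|M|


@dataclass
class CorePath:
    """Ordered vortex-core points traced along z (voxel coordinates)."""

    points: np.ndarray          # (n, 3): (x, y, z) subvoxel positions
    polarization: np.ndarray    # (n,): sign of M_z on the core
    mz_on_core: np.ndarray      # (n,): interpolated M_z values
    circulation: int
    bloch_points: list = dc_field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _subpixel_min(inplane_mag: np.ndarray, i: int, j: int
                  ) -> tuple[float, float]:
    """Quadratic refinement of an in-plane-magnitude minimum."""
    out = [float(i), float(j)]
    for ax, idx in ((0, i), (1, j)):
        if 1 <= idx < inplane_mag.shape[ax] - 1:
            if ax == 0:
                f0, f1, f2 = inplane_mag[idx - 1, j], inplane_mag[idx, j], \
                    inplane_mag[idx + 1, j]
            else:
                f0, f1, f2 = inplane_mag[i, idx - 1], inplane_mag[i, idx], \
                    inplane_mag[i, idx + 1]
            denom = f0 - 2 * f1 + f2
            if denom > 0:
                out[ax] = idx + float(np.clip(0.5 * (f0 - f2) / denom,
                                              -0.5, 0.5))
    return out[0], out[1]


def _bilinear(a: np.ndarray, x: float, y: float) -> float:
    i0 = int(np.clip(np.floor(x), 0, a.shape[0] - 2))
    j0 = int(np.clip(np.floor(y), 0, a.shape[1] - 2))
    fx, fy = x - i0, y - j0
    return float(a[i0, j0] * (1 - fx) * (1 - fy)
                 + a[i0 + 1, j0] * fx * (1 - fy)
                 + a[i0, j0 + 1] * (1 - fx) * fy
                 + a[i0 + 1, j0 + 1] * fx * fy)


def trace_core(field3d: VectorField3D, min_mask_pixels: int = 9,
               interior_gap_error: bool = True) -> CorePath:
    """Trace the vortex core through z-slices.

    Per slice, the in-plane winding singularity is located on the
    plaquette lattice and refined to subpixel precision by a quadratic
    fit of the in-plane magnitude; candidate singularities are linked by
    proximity to the previous slice's core.  The polarization is the
    sign of the interpolated ``M_z`` at the core point; Bloch points are
    recorded where it changes sign.

    Raises
    ------
    CoreTraceError
        If no singularity is found in an interior occupied slice (broken
        core) while ``interior_gap_error`` is set, or if no core exists
        at all.
    """
    mask = field3d.mask
    nz = mask.shape[2]
    found: list[tuple[int, float, float, int]] = []
    missing: list[int] = []
    occupied = [k for k in range(nz) if mask[:, :, k].sum() >= min_mask_pixels]
    prev_xy: tuple[float, float] | None = None
    multi_warned = False

    for k in occupied:
        mx = field3d.m[0, :, :, k]
        my = field3d.m[1, :, :, k]
        wind = _plaquette_winding(mx, my)
        # only plaquettes fully inside the mask are trustworthy
        msk = mask[:, :, k]
        interior = msk[:-1, :-1] & msk[1:, :-1] & msk[:-1, 1:] & msk[1:, 1:]
        cand = np.argwhere((wind != 0) & interior)
        if cand.shape[0] == 0:
            missing.append(k)
            continue
        if cand.shape[0] > 1:
            if prev_xy is None:
                # keep the strongest isolated candidate: nearest to the
                # slice in-plane magnitude minimum
                pass
            if not multi_warned and cand.shape[0] > 2:
                warnings.warn(
                    f"slice {k}: {cand.shape[0]} winding singularities; "
                    "keeping the one nearest the previous core "
                    "(multi-core diagnostic)")
                multi_warned = True
        inplane = np.hypot(mx, my)
        if prev_xy is not None:
            d2 = ((cand[:, 0] + 0.5 - prev_xy[0]) ** 2
                  + (cand[:, 1] + 0.5 - prev_xy[1]) ** 2)
            pick = cand[int(np.argmin(d2))]
        else:
            vals = inplane[cand[:, 0], cand[:, 1]]
            pick = cand[int(np.argmin(vals))]
        w = int(wind[pick[0], pick[1]])
        # plaquette corner with the smallest in-plane magnitude
        sub = inplane[pick[0]:pick[0] + 2, pick[1]:pick[1] + 2]
        ci, cj = np.unravel_index(np.argmin(sub), sub.shape)
        x, y = _subpixel_min(inplane, pick[0] + ci, pick[1] + cj)
        found.append((k, x, y, w))
        prev_xy = (x, y)

    if not found:
        raise CoreTraceError("no winding singularity found in any slice")

    ks = [f[0] for f in found]
    if interior_gap_error:
        interior_missing = [k for k in missing if ks[0] < k < ks[-1]]
        if interior_missing:
            raise CoreTraceError(
                f"no singularity in interior slice {interior_missing[0]} "
                "(broken core)", slice_index=interior_missing[0])

    pts = np.array([[x, y, float(k)] for k, x, y, _ in found])
    mz = np.array([
        _bilinear(field3d.m[2, :, :, k], x, y) for k, x, y, _ in found])
    pol = np.sign(mz)
    # circulation sense from the tangential orientation about the core
    # (the winding index of a vortex is +1 for either sense)
    senses = []
    for k, x, y, _ in found:
        xi, yi = np.indices(mask.shape[:2])
        dx = xi - x
        dy = yi - y
        curlz = dx * field3d.m[1, :, :, k] - dy * field3d.m[0, :, :, k]
        senses.append(np.sign(curlz[mask[:, :, k]].sum()))
    circ = int(np.sign(np.median(senses))) or 1
    path = CorePath(pts, pol, mz, circ)
    path.bloch_points = detect_bloch_points(path, field3d)
    return path


def detect_bloch_points(core: CorePath,
                        field3d: VectorField3D) -> list[BlochPoint]:
    """Locate core-polarity reversals and their local |M| depression.

    For each sign change of the core polarization the crossing position
    is interpolated from the ``M_z`` values on the path, and the local
    minimum of |M| within a 3-voxel neighborhood is reported relative to
    the median inside-magnitude (near a Bloch point the reconstructed or
    relaxed magnetization magnitude is depressed).
    """
    out: list[BlochPoint] = []
    mz = core.mz_on_core
    mag = field3d.magnitude()
    med = float(np.median(mag[field3d.mask])) if field3d.mask.any() else 1.0
    for i in range(len(mz) - 1):
        if mz[i] == 0 or mz[i + 1] == 0:
            continue
        if np.sign(mz[i]) != np.sign(mz[i + 1]):
            t = mz[i] / (mz[i] - mz[i + 1])
            pos = core.points[i] + t * (core.points[i + 1] - core.points[i])
            ic = np.clip(np.rint(pos).astype(int), 0,
                         np.array(field3d.grid_shape) - 1)
            sl = tuple(slice(max(c - 3, 0), min(c + 4, n))
                       for c, n in zip(ic, field3d.grid_shape))
            local = mag[sl][field3d.mask[sl]]
            mn = float(local.min()) if local.size else float("nan")
            out.append(BlochPoint(pos, mn, mn / med if med > 0 else
                                  float("nan")))
    return out


# ---------------------------------------------------------------------------
# medial wall
# ---------------------------------------------------------------------------

@dataclass
class MedialWall:
    """Triangulated M_z = 0 isosurface with its per-slice orientation."""

    vertices: np.ndarray        # (n, 3) voxel coordinates
    faces: np.ndarray
    slice_z: np.ndarray         # slices with a wall trace
    twist_profile: np.ndarray   # wall in-plane orientation (deg), unwrapped
    tip_twist: bool             # True if orientation rotates > 45° in tip


def extract_medial_wall(field3d: VectorField3D,
                        tip_fraction: float = 0.25,
                        core: CorePath | None = None,
                        core_exclusion: float = 2.5) -> MedialWall:
    """Extract the medial M_z = 0 wall and its twist along z.

    The isosurface is computed by marching cubes on ``M_z`` (restricted
    to mask-interior vertices).  The twist profile is the orientation of
    the best-fit line through each slice's in-mask zero crossings of
    ``M_z`` (excluding a neighborhood of the vortex core if a traced
    core is supplied, since the core region carries its own out-of-plane
    signal), unwrapped along ``z``.  ``tip_twist`` flags an orientation
    rotation of more than 45° over the final ``tip_fraction`` of the
    occupied length.

    Raises
    ------
    ValueError
        If ``M_z`` has a single sign inside the mask (no wall).
    """
    mask = field3d.mask
    mz = field3d.m[2]
    inside = mz[mask]
    if inside.size == 0 or inside.min() >= 0 or inside.max() <= 0:
        raise ValueError("M_z has a single sign inside the mask: no wall")

    # pad M_z outside the mask with nearest inside values so the
    # isosurface is not biased by the zero exterior
    idx = ndimage.distance_transform_edt(~mask, return_distances=False,
                                         return_indices=True)
    mz_f = mz[tuple(idx)]
    verts, faces, _, _ = measure.marching_cubes(mz_f, level=0.0)
    keep = np.zeros(len(verts), dtype=bool)
    iv = np.rint(verts).astype(int)
    for a in range(3):
        iv[:, a] = np.clip(iv[:, a], 0, mask.shape[a] - 1)
    keep = mask[iv[:, 0], iv[:, 1], iv[:, 2]]
    vkeep = np.where(keep)[0]
    remap = -np.ones(len(verts), dtype=int)
    remap[vkeep] = np.arange(vkeep.size)
    fkeep = faces[keep[faces].all(axis=1)]
    verts_k = verts[vkeep]
    faces_k = remap[fkeep]

    # per-slice orientation of the wall trace
    zs, angles = [], []
    for k in range(mask.shape[2]):
        msk = mask[:, :, k]
        if msk.sum() < 9:
            continue
        sl = mz_f[:, :, k]
        # zero crossings between in-mask neighbors
        pts = []
        cross_x = (np.signbit(sl[:-1, :]) != np.signbit(sl[1:, :])) \
            & msk[:-1, :] & msk[1:, :]
        ii, jj = np.nonzero(cross_x)
        for i, j in zip(ii, jj):
            t = sl[i, j] / (sl[i, j] - sl[i + 1, j])
            pts.append((i + t, float(j)))
        cross_y = (np.signbit(sl[:, :-1]) != np.signbit(sl[:, 1:])) \
            & msk[:, :-1] & msk[:, 1:]
        ii, jj = np.nonzero(cross_y)
        for i, j in zip(ii, jj):
            t = sl[i, j] / (sl[i, j] - sl[i, j + 1])
            pts.append((float(i), j + t))
        if len(pts) < 3:
            continue
        pts = np.asarray(pts)
        if core is not None:
            zc = core.points[:, 2]
            i_near = int(np.argmin(np.abs(zc - k)))
            if abs(zc[i_near] - k) <= 1.5:
                cxy = core.points[i_near, :2]
                d = np.hypot(pts[:, 0] - cxy[0], pts[:, 1] - cxy[1])
                pts = pts[d > core_exclusion]
                if len(pts) < 3:
                    continue
        pts = pts - pts.mean(axis=0)
        # principal orientation of the trace (axial angle in [0, 180°))
        cov = pts.T @ pts
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, -1]
        angles.append(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
        zs.append(k)

    zs = np.array(zs)
    angles = np.array(angles)
    # unwrap the axial (period-180°) orientation along z
    unwrapped = angles.copy()
    for i in range(1, len(unwrapped)):
        d = unwrapped[i] - unwrapped[i - 1]
        unwrapped[i] -= 180.0 * np.rint(d / 180.0)

    tip_twist = False
    if len(zs) >= 4:
        z_lo = zs[0] + (1.0 - tip_fraction) * (zs[-1] - zs[0])
        in_tip = zs >= z_lo
        if in_tip.sum() >= 2:
            tip_twist = bool(np.ptp(unwrapped[in_tip]) > 45.0)

    return MedialWall(verts_k, faces_k, zs, unwrapped, tip_twist)
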