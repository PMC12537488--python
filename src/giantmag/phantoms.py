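"""Analytic single-vortex magnetization phantoms.

These phantoms emulate the magnetic texture observed in the giant
spearhead magnetofossil: magnetization circulating about a (possibly
curved) core line along ``z``, a core magnetized out of plane whose
polarization may reverse at prescribed positions (Bloch points), lateral
halves carrying opposing ``M_z`` separated by a medial ``M_z = 0`` wall
through the core, and an optional reversal of the ``M_z`` half-pattern in
the tip realized as an in-plane twist of the wall.

Every phantom has exactly ``|M| = M_s`` inside the particle and zero
outside, so downstream projection, reconstruction and topology stages can
be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .fields import VectorField3D
from .geometry import ParticleGeometry, voxelize

#: Amplitude of the lateral M_z half-pattern relative to M_s.  The
#: observed magnetization is predominantly in-plane, with a moderate
#: length-parallel component of opposite sign in the two lateral halves.
DEFAULT_TILT_AMPLITUDE = 0.4

#: Fraction of the length at which the tip twist begins, and its extent.
TWIST_START_FRACTION = 0.78
TWIST_EXTENT_FRACTION = 0.16


@dataclass
class PhantomSpec:
    """Parameters of a single-vortex phantom.

    Parameters
    ----------
    core_path_control_points : sequence of (x, y, z) positions (m)
        Control points of the core trajectory, interpolated by a cubic
        spline in ``z`` (linear for two points).  Must lie inside the
        geometry and span its length.
    polarity_flip_positions : sequence of float
        Fractional positions along the length (each in (0, 1)) at which
        the core polarization reverses sign (a Bloch point).  Empty for a
        single-polarity core.
    circulation_sense : {+1, -1}
        Sense of the in-plane circulation about the core.
    tip_Mz_reversal : bool
        If True the lateral M_z half-pattern reverses in the tip region,
        twisting the medial wall through 180 degrees.
    core_radius : float
        1/e radius of the Gaussian core canting profile (m).
    base_polarity : {+1, -1}
        Core polarization sign at the base.
    tilt_amplitude : float
        Amplitude (fraction of M_s) of the lateral M_z half-pattern.
    """

    core_path_control_points: np.ndarray
    polarity_flip_positions: Sequence[float] = dc_field(default_factory=tuple)
    circulation_sense: int = 1
    tip_Mz_reversal: bool = False
    core_radius: float = 60e-9
    base_polarity: int = 1
    tilt_amplitude: float = DEFAULT_TILT_AMPLITUDE

    def __post_init__(self) -> None:
        self.core_path_control_points = np.atleast_2d(
            np.asarray(self.core_path_control_points, dtype=float))
        if self.core_path_control_points.shape[1] != 3:
            raise ValueError("control points must be (n, 3)")
        if self.circulation_sense not in (1, -1):
            raise ValueError("circulation_sense must be +1 or -1")
        if self.base_polarity not in (1, -1):
            raise ValueError("base_polarity must be +1 or -1")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")
        for f in self.polarity_flip_positions:
            if not 0.0 < f < 1.0:
                raise ValueError("flip positions must lie in (0, 1)")

    def validate_for(self, geometry: ParticleGeometry) -> None:
        pts = self.core_path_control_points
        if not geometry.contains(pts[:, 0], pts[:, 1], pts[:, 2]).all():
            raise ValueError("core path control points must lie inside "
                             "the geometry")
        if self.core_radius >= geometry.base_minor_radius:
            raise ValueError("core_radius must be smaller than the base "
                             "minor radius")

    def core_path(self, z: np.ndarray, length: float) -> np.ndarray:
        """Interpolated core position (x, y) at heights ``z``."""
        pts = self.core_path_control_points
        order = np.argsort(pts[:, 2])
        pz, px, py = pts[order, 2], pts[order, 0], pts[order, 1]
        z = np.clip(z, pz[0], pz[-1])
        if pts.shape[0] < 3:
            return np.stack([np.interp(z, pz, px), np.interp(z, pz, py)])
        return np.stack([CubicSpline(pz, px)(z), CubicSpline(pz, py)(z)])


def straight_core_spec(geometry: ParticleGeometry, **kwargs) -> PhantomSpec:
    """Convenience spec with an axial, straight core."""
    L = geometry.long_axis_length
    pts = [(0.0, 0.0, 0.0), (0.0, 0.0, L)]
    return PhantomSpec(core_path_control_points=np.array(pts), **kwargs)


def curved_core_spec(geometry: ParticleGeometry,
                     lateral_fraction: float = 0.5, **kwargs) -> PhantomSpec:
    """Spec with a core curving within the medial (x-z) plane.

    The core starts off-center at one edge of the base, moves through the
    center and exits near the tip, mimicking the observed trajectory.
    ``lateral_fraction`` scales the basal offset relative to the local
    major radius.
    """
    L = geometry.long_axis_length
    x0 = lateral_fraction * geometry.major_radius_at(0.0)
    x_mid = 0.0
    x_tip = -0.3 * geometry.major_radius_at(0.92 * L)
    pts = [(x0, 0.0, 0.01 * L), (x_mid, 0.0, 0.5 * L),
           (x_tip, 0.0, 0.92 * L)]
    return PhantomSpec(core_path_control_points=np.array(pts), **kwargs)


def _polarity_profile(z: np.ndarray, length: float,
                      flips: Sequence[float], base_polarity: int,
                      width: float) -> np.ndarray:
    """Smooth ±1 profile changing sign once at each flip position."""
    p = np.full_like(z, float(base_polarity))
    for f in flips:
        p = p * np.tanh((f * length - z) / width)
    return p


def _twist_angle(z: np.ndarray, length: float, enabled: bool) -> np.ndarray:
    """In-plane wall orientation angle phi(z): 0 in the body, rotating to
    pi across the tip region when the tip reversal is enabled."""
    if not enabled:
        return np.zeros_like(z)
    t = (z / length - TWIST_START_FRACTION) / TWIST_EXTENT_FRACTION
    t = np.clip(t, 0.0, 1.0)
    return np.pi * t * t * (3 - 2 * t)  # smoothstep


def make_vortex_phantom(geometry: ParticleGeometry, spec: PhantomSpec,
                        M_s: float, voxel_size: float) -> VectorField3D:
    """Build a unit-|M| single-vortex phantom on a voxel grid.

    Inside the mask the magnetization circulates about the interpolated
    core path with ``spec.circulation_sense``.  Within ``core_radius`` of
    the path it cants toward ±z with a Gaussian profile and polarization
    ``base_polarity`` (reversing at each flip position); away from the
    core a lateral ``M_z`` half-pattern of amplitude ``tilt_amplitude``
    forms a medial M_z = 0 wall through the core, which twists through
    180° in the tip when ``tip_Mz_reversal`` is set.  |M| = M_s exactly
    inside the mask.
    """
    spec.validate_for(geometry)
    grid = voxelize(geometry, voxel_size)
    L = geometry.long_axis_length
    x, y, z = grid.voxel_centers()
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = np.broadcast_to(z[None, None, :], grid.mask.shape)

    core_xy = spec.core_path(z, L)  # (2, nz)
    # verify the interpolated path stays inside the solid over the span
    # of the control points
    zs = np.linspace(spec.core_path_control_points[:, 2].min(),
                     spec.core_path_control_points[:, 2].max(), 200)
    cxy = spec.core_path(zs, L)
    if not geometry.contains(cxy[0], cxy[1], zs).all():
        raise ValueError("interpolated core path exits the solid")

    dx = X - core_xy[0][None, None, :]
    dy = Y - core_xy[1][None, None, :]
    rho2 = dx**2 + dy**2
    theta = np.arctan2(dy, dx)

    slab = L / max(geometry.n_frustrums, 1)
    pol = _polarity_profile(z, L, spec.polarity_flip_positions,
                            spec.base_polarity, width=slab)[None, None, :]
    phi = _twist_angle(z, L, spec.tip_Mz_reversal)[None, None, :]

    core = np.exp(-rho2 / spec.core_radius**2)
    mz = pol * core + spec.tilt_amplitude * (1 - core) * np.sin(theta - phi)
    mz = np.clip(mz, -1.0, 1.0)
    s_inplane = np.sqrt(np.maximum(0.0, 1.0 - mz**2))
    mx = -spec.circulation_sense * s_inplane * np.sin(theta)
    my = spec.circulation_sense * s_inplane * np.cos(theta)

    m = np.stack([mx, my, mz]) * M_s
    m[:, ~grid.mask] = 0.0
    return VectorField3D(m, grid.mask, voxel_size, grid.origin)


def perturb_phantom(field3d: VectorField3D, angular_noise_sd: float,
                    seed: int) -> VectorField3D:
    """Rotate each inside voxel's direction by a small random angle.

    The perturbation is an isotropic Gaussian kick in the local tangent
    plane, scaled so that the mean angular deviation equals
    ``angular_noise_sd`` (radians) in the small-angle regime.  Magnitudes
    are preserved and the operation is deterministic for a fixed seed.
    """
    if angular_noise_sd < 0:
        raise ValueError("angular_noise_sd must be non-negative")
    out = field3d.copy()
    if angular_noise_sd == 0 or not field3d.mask.any():
        return out
    rng = np.random.default_rng(seed)
    inside = field3d.mask
    v = field3d.m[:, inside]
    mag = np.linalg.norm(v, axis=0)
    ok = mag > 0
    u = v[:, ok] / mag[ok]

    # orthonormal tangent frame for each unit vector
    ref = np.zeros_like(u)
    ref[0] = 1.0
    swap = np.abs(u[0]) > 0.9
    ref[0, swap] = 0.0
    ref[1, swap] = 1.0
    e1 = np.cross(u.T, ref.T).T
    e1 /= np.linalg.norm(e1, axis=0)
    e2 = np.cross(u.T, e1.T).T

    # tangent-plane Gaussian: deviation angle ~ Rayleigh(sigma) with mean
    # sigma*sqrt(pi/2); choose sigma so the mean equals the requested sd
    sigma = angular_noise_sd * np.sqrt(2.0 / np.pi)
    g = rng.normal(scale=sigma, size=(2, u.shape[1]))
    tilted = u + g[0] * e1 + g[1] * e2
    tilted /= np.linalg.norm(tilted, axis=0)

    newv = v.copy()
    newv[:, ok] = tilted * mag[ok]
    out.m[:, inside] = newv
    return out
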