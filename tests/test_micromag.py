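"""Micromagnetic energies, demag oracles, minimization and protocols.

The heavy spearhead-scale protocols live in the acceptance tests; here
the individual operators are validated on small bodies with closed-form
oracles.
"""

import numpy as np
import pytest

from giantmag.constants import MU_0
from giantmag.fields import VectorField3D
from giantmag.geometry import VoxelGrid, build_spearhead_geometry, voxelize
from giantmag.micromag import (MaterialParams, effective_field,
                               growth_simulation, hysteresis_loop,
                               magnetite, minimize, orientation_from_axes,
                               random_state, susceptibility,
                               vortex_initialize)

MS = 4.80768e5


def _uniform_cube(n, direction, h=5e-9, M_s=MS):
    mask = np.ones((n, n, n), bool)
    m = np.zeros((3, n, n, n))
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    m[:, mask] = d[:, None] * M_s
    return VectorField3D(m, mask, h)


class TestEnergies:
    def test_uniform_cube_has_zero_exchange(self):
        f = _uniform_cube(8, [0.3, 0.5, 0.8])
        _, eb = effective_field(f, magnetite())
        assert eb.exchange == pytest.approx(0.0, abs=1e-30)

    def test_cube_demag_energy_closed_form(self):
        """Uniformly magnetized cube: E_d = (mu0/6) Ms^2 V (N = 1/3)."""
        f = _uniform_cube(32, [0, 0, 1])
        _, eb = effective_field(f, magnetite())
        V = f.mask.sum() * f.voxel_size**3
        expected = MU_0 / 6 * MS**2 * V
        assert eb.demagnetizing == pytest.approx(expected, rel=0.01)

    def test_sphere_demag_factor_one_third(self):
        n = 33
        c = (n - 1) / 2
        x, y, z = np.meshgrid(*([np.arange(n) - c] * 3), indexing="ij")
        mask = x**2 + y**2 + z**2 <= (n / 2 - 1) ** 2
        m = np.zeros((3, n, n, n))
        m[2][mask] = MS
        f = VectorField3D(m, mask, 5e-9)
        _, eb = effective_field(f, magnetite())
        V = mask.sum() * f.voxel_size**3
        assert eb.demagnetizing == pytest.approx(MU_0 / 6 * MS**2 * V,
                                                 rel=0.02)

    def test_cubic_anisotropy_easy_axis(self):
        """For K1 < 0 the [111] direction is the cubic minimum with
        energy density K1/3; [100] has density 0."""
        params = magnetite(z_axis=(0, 0, 1), inplane=(1, 0, 0))
        f111 = _uniform_cube(8, [1, 1, 1])
        f100 = _uniform_cube(8, [1, 0, 0])
        _, e111 = effective_field(f111, params)
        _, e100 = effective_field(f100, params)
        V = f111.mask.sum() * f111.voxel_size**3
        assert e111.anisotropy == pytest.approx(params.K_1 / 3 * V,
                                                rel=1e-9)
        assert e100.anisotropy == pytest.approx(0.0, abs=1e-25)
        assert e111.anisotropy < e100.anisotropy

    def test_frame_equivalence(self):
        """Rotating the crystal orientation and the applied field
        together leaves every energy term invariant."""
        f = _uniform_cube(8, [0.2, -0.4, 0.9])
        B = np.array([0.0, 0.0, 5e-3])
        p1 = magnetite(z_axis=(1, 1, 3), inplane=(1, 1, 1))
        _, e1 = effective_field(f, p1, applied=B)
        # rotate crystal frame by 90 deg about z together with the field
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        p2 = MaterialParams(
            crystal_orientation=p1.crystal_orientation @ Rz.T)
        m2 = np.tensordot(Rz, f.m, axes=(1, 0))
        f2 = VectorField3D(m2, f.mask, f.voxel_size)
        _, e2 = effective_field(f2, p2, applied=Rz @ B)
        for a, b in [(e1.exchange, e2.exchange),
                     (e1.anisotropy, e2.anisotropy),
                     (e1.zeeman, e2.zeeman)]:
            assert a == pytest.approx(b, rel=1e-8, abs=1e-28)
        # demag of the rotated cube: the cube itself is symmetric under
        # this rotation, so the demag energy is also invariant
        assert e1.demagnetizing == pytest.approx(e2.demagnetizing,
                                                 rel=1e-8)

    def test_demag_energy_scales_with_ms_squared(self):
        f1 = _uniform_cube(12, [0, 0, 1], M_s=MS)
        f2 = _uniform_cube(12, [0, 0, 1], M_s=2 * MS)
        p1 = magnetite()
        p2 = MaterialParams(M_s=2 * MS, K_1=p1.K_1, A_ex=p1.A_ex,
                            crystal_orientation=p1.crystal_orientation)
        _, e1 = effective_field(f1, p1)
        _, e2 = effective_field(f2, p2)
        assert e2.demagnetizing == pytest.approx(4 * e1.demagnetizing,
                                                 rel=1e-10)

    def test_energy_breakdown_total_consistent(self):
        f = _uniform_cube(8, [0.6, 0.0, 0.8])
        _, eb = effective_field(f, magnetite(), applied=(0, 0, 1e-3))
        parts = eb.exchange + eb.anisotropy + eb.demagnetizing + eb.zeeman
        assert eb.total == pytest.approx(parts, rel=1e-10)
        assert eb.exchange >= 0
        assert eb.demagnetizing >= 0

    def test_non_normalized_input_rejected(self):
        f = _uniform_cube(6, [0, 0, 1])
        f.m *= 0.5
        with pytest.raises(ValueError, match="normalized"):
            effective_field(f, magnetite())


class TestMinimize:
    def test_small_cube_stays_quasi_uniform(self):
        """A 40 nm magnetite cube is well below the vortex threshold."""
        f = _uniform_cube(8, [1, 1, 1], h=5e-9)
        res = minimize(f, magnetite(z_axis=(0, 0, 1), inplane=(1, 0, 0)),
                       tolerance=1e-5)
        mean_dir = res.field.unit_vectors()[:, res.field.mask].mean(axis=1)
        assert np.linalg.norm(mean_dir) > 0.99

    def test_energy_history_monotone(self):
        rnd = random_state(np.ones((6, 6, 6), bool), MS, 5e-9, seed=2)
        res = minimize(rnd, magnetite(), tolerance=1e-4)
        hist = res.energy_history
        assert (np.diff(hist) <= 1e-10 * np.abs(hist[:-1]) + 1e-30).all()

    def test_gradient_flow_agrees_with_lbfgs(self):
        rnd = random_state(np.ones((5, 5, 5), bool), MS, 5e-9, seed=4)
        r1 = minimize(rnd.copy(), magnetite(), tolerance=1e-3,
                      method="lbfgs")
        r2 = minimize(rnd.copy(), magnetite(), tolerance=1e-3,
                      method="gradient_flow", max_iterations=3000)
        assert r1.energy.total == pytest.approx(r2.energy.total, rel=0.01)

    def test_empty_mask_rejected(self):
        f = VectorField3D(np.zeros((3, 4, 4, 4)),
                          np.zeros((4, 4, 4), bool), 5e-9)
        with pytest.raises(ValueError):
            minimize(f, magnetite())


class TestVortexInitialize:
    def test_core_strength_sign_sets_polarity(self):
        mask = np.ones((15, 15, 9), bool)
        up = vortex_initialize(mask, MS, core_strength=2, voxel_size=10e-9)
        dn = vortex_initialize(mask, MS, core_strength=-2,
                               voxel_size=10e-9)
        assert up.m[2, 7, 7, 4] > 0
        assert dn.m[2, 7, 7, 4] < 0
        # mirror symmetry: M_z negated on the core, circulation equal
        np.testing.assert_allclose(up.m[2], -dn.m[2], atol=1e-9)
        np.testing.assert_allclose(up.m[0], dn.m[0], atol=1e-9)

    def test_zero_voxel_mask_raises(self):
        with pytest.raises(ValueError):
            vortex_initialize(np.zeros((4, 4, 4), bool), MS,
                              voxel_size=10e-9)

    def test_normalized(self):
        mask = np.ones((9, 9, 5), bool)
        f = vortex_initialize(mask, MS, voxel_size=10e-9)
        mag = f.magnitude()[mask]
        np.testing.assert_allclose(mag, MS, rtol=1e-9)


class TestProtocols:
    def test_single_domain_cube_loop_is_square(self):
        """Easy-axis loop of a single-domain cube: squareness ≈ 1."""
        n = 4
        grid = VoxelGrid(np.ones((n, n, n), bool), 8e-9,
                         np.zeros(3))
        # uniaxial-like situation: use [001] easy orientation and a
        # small cube that stays uniform
        params = magnetite(z_axis=(1, 1, 1), inplane=(1, -1, 0))
        df, summary = hysteresis_loop(grid, params, axis="z", B_max=0.1,
                                      B_step=0.02, tolerance=1e-4)
        assert summary.squareness > 0.9
        assert summary.B_c >= 0

    def test_loop_inversion_symmetry(self):
        n = 4
        grid = VoxelGrid(np.ones((n, n, n), bool), 8e-9, np.zeros(3))
        params = magnetite(z_axis=(1, 1, 1), inplane=(1, -1, 0))
        df, _ = hysteresis_loop(grid, params, axis="z", B_max=0.1,
                                B_step=0.02, tolerance=1e-4)
        down = df[df.branch == "down"].set_index("B").moment
        up = df[df.branch == "up"].set_index("B").moment
        common = [b for b in down.index if -b in up.index]
        asym = max(abs(down[b] + up[-b]) for b in common)
        assert asym < 0.05 * abs(down.iloc[0])

    def test_step_larger_than_bmax_rejected(self):
        grid = VoxelGrid(np.ones((3, 3, 3), bool), 8e-9, np.zeros(3))
        with pytest.raises(ValueError):
            hysteresis_loop(grid, magnetite(), B_max=0.01, B_step=0.02)

    def test_sphere_susceptibility_isotropic(self):
        n = 11
        c = (n - 1) / 2
        x, y, z = np.meshgrid(*([np.arange(n) - c] * 3), indexing="ij")
        mask = x**2 + y**2 + z**2 <= (n / 2 - 0.5) ** 2
        grid = VoxelGrid(mask, 8e-9, np.zeros(3))
        # isotropic material: no cubic anisotropy
        params = MaterialParams(K_1=0.0)
        # uniform ground state (single domain at this size)
        m = np.zeros((3,) + mask.shape)
        m[2][mask] = params.M_s
        ground = minimize(VectorField3D(m, mask, 8e-9), params,
                          tolerance=1e-4).field
        chi = susceptibility(grid, params, probe_field=1e-3,
                             ground=ground, tolerance=1e-4)
        # response along the moment axis vanishes (rigid moment); the
        # two transverse responses must agree by symmetry
        assert chi[0] == pytest.approx(chi[1], rel=0.1)

    def test_growth_of_thin_disc_is_in_plane(self):
        """A single-slab disc magnetizes in plane (shape anisotropy)."""
        geom = build_spearhead_geometry(120e-9, 120e-9, 25e-9, 2, 1.0)
        results = growth_simulation(geom, magnetite(), "base-up",
                                    slab_thickness=25e-9,
                                    voxel_size=12.5e-9, seed=1,
                                    tolerance=1e-4)
        final = results[-1].field
        u = final.unit_vectors()[:, final.mask]
        assert np.abs(u[2]).mean() < 0.25

    def test_growth_directions_reach_same_energy(self):
        """Tip-down and base-up growth end in states of equal energy."""
        geom = build_spearhead_geometry(100e-9, 40e-9, 200e-9, 8, 1.0)
        kw = dict(slab_thickness=50e-9, voxel_size=25e-9, seed=5,
                  tolerance=1e-4)
        up = growth_simulation(geom, magnetite(), "base-up", **kw)
        dn = growth_simulation(geom, magnetite(), "tip-down", **kw)
        e_up = up[-1].energy.total
        e_dn = dn[-1].energy.total
        assert abs(e_up - e_dn) < 0.01 * abs(e_up)


class TestOrientation:
    def test_orientation_is_proper_rotation(self):
        C = orientation_from_axes([1, 1, 3], [1, 1, 1])
        assert np.linalg.det(C) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(C @ C.T, np.eye(3), atol=1e-12)

    def test_z_axis_maps_to_requested_direction(self):
        C = orientation_from_axes([1, 1, 3], [1, 1, 1])
        z_crystal = C @ np.array([0.0, 0.0, 1.0])
        expected = np.array([1, 1, 3]) / np.sqrt(11)
        np.testing.assert_allclose(z_crystal, expected, atol=1e-12)

    def test_degenerate_inplane_rejected(self):
        with pytest.raises(ValueError):
            orientation_from_axes([0, 0, 1], [0, 0, 2])
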