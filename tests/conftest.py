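"""Shared fixtures.

Expensive micromagnetic and tomographic fixtures are session-scoped so
the relaxed spearhead state is computed once and shared between the
tests that interrogate it.
"""

from __future__ import annotations

import numpy as np
import pytest

import giantmag as gm
from giantmag.micromag import magnetite, minimize, vortex_initialize


SPEARHEAD_DIMS = dict(base_radius=0.55e-6, tip_radius=0.058e-6,
                      total_length=2.25e-6, n_frustrums=90,
                      ellipticity=0.85)

#: coarse voxel size used for desk-scale micromagnetics and tomography
COARSE_VOXEL = 40e-9


@pytest.fixture(scope="session")
def spearhead_geometry():
    return gm.build_spearhead_geometry(**SPEARHEAD_DIMS)


@pytest.fixture(scope="session")
def spearhead_grid(spearhead_geometry):
    return gm.voxelize(spearhead_geometry, COARSE_VOXEL)


@pytest.fixture(scope="session")
def vortex_phantom(spearhead_geometry):
    """Curved-core phantom with one polarity flip and a tip twist."""
    spec = gm.curved_core_spec(spearhead_geometry,
                               polarity_flip_positions=(0.5,),
                               tip_Mz_reversal=True)
    return gm.make_vortex_phantom(spearhead_geometry, spec, 1.0,
                                  COARSE_VOXEL)


@pytest.fixture(scope="session")
def magnetite_params():
    return magnetite()


@pytest.fixture(scope="session")
def relaxed_spearhead(spearhead_grid, magnetite_params):
    """Zero-field vortex state of the spearhead at coarse resolution."""
    init = vortex_initialize(spearhead_grid, magnetite_params.M_s)
    return minimize(init, magnetite_params, tolerance=1e-3)


@pytest.fixture(scope="session")
def dual_axis_series(vortex_phantom):
    """Noise-free wide-coverage dual-axis tilt series of the phantom."""
    angles = np.arange(-70.0, 70.1, 2.0)
    s1 = gm.simulate_tilt_series(vortex_phantom, "first", angles,
                                 with_charge=False)
    s2 = gm.simulate_tilt_series(vortex_phantom, "second", angles,
                                 with_charge=False)
    return s1, s2
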