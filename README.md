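# giantmag

Synthetic magnetic vector tomography, voxel micromagnetics and
torque-transducer magnetoreception modelling for **giant magnetofossils** —
micron-sized biogenic magnetite crystals (needles, giant bullets,
spearheads, spindles) preserved in marine sediments, whose internal
magnetic structure bears on whether their maker used them to sense the
Earth's magnetic field.

The package reimplements, end to end and fully synthetically, the
computational chain used to characterize a giant *spearhead*
magnetofossil (base radius 0.55 µm, tip radius 0.058 µm, length 2.25 µm,
elliptical cross section with axis ratio 0.85):

1. **`geometry` / `phantoms`** — the spearhead solid as a stack of 90
   elliptical frustrum slabs (25 nm each), rasterized to voxel masks, and
   analytic single-vortex magnetization phantoms with a controllable
   curved core, core-polarity reversals (Bloch points), a medial
   *M*<sub>z</sub> = 0 domain wall and an optional tip twist.
2. **`projection`** — dual-axis phase-XMCD tilt series: each projection
   is the line integral along the beam of the beam-parallel
   magnetization component, plus charge (thickness) projections, noise
   and misalignment.
3. **`recon`** — tilt-series alignment (neighbor cross-correlation +
   subpixel center-of-mass), registration of the two rotation axes, and
   gradient-based iterative vector reconstruction: from a zero-filled
   field, minimize the sum-squared projection error over both series
   with exact line searches and a material-mask constraint
   (10 iterations by default).
4. **`topology`** — vortex-core tracing by winding-number singularity
   detection per slice, core polarization and Bloch-point detection,
   medial-wall extraction by marching cubes with a per-slice twist
   profile.
5. **`micromag`** — voxel micromagnetics for magnetite
   (*M*<sub>s</sub> = 4.80768×10⁵ A/m, *K*₁ = −1.32658×10⁴ J/m³,
   *A*<sub>ex</sub> = 1.33487×10⁻¹¹ J/m): 6-neighbor exchange with free
   boundaries, cubic anisotropy in an arbitrary crystal orientation
   ([113] ∥ *z* by default), FFT demagnetization with the Newell
   cell-averaged tensor, projected L-BFGS energy minimization, plus
   hysteresis, backfield-remanence, susceptibility and slab-growth
   protocols.
6. **`reception`** — the torque-transducer model of magnetointensity
   reception: a particle of moment *M* in field *B*, elastically
   anchored with torsional stiffness *K*, has Boltzmann-distributed
   deflection ψ with energy (thermal units)

   *u*(ψ) = −*MB* cos(θ − ψ) + ½ *K* ψ²  on ψ ∈ (−π, π].

   For fields antiparallel to the rest position (θ = 180°) the system
   has a critical point at *MB*/*K* = 1 where the fluctuation amplitude
   Δψ rises most steeply with field intensity — the proposed operating
   point of a magnetite-based intensity receptor.

## Worked example

```python
import numpy as np
import giantmag as gm

# spearhead geometry and a curved-core vortex phantom
geom = gm.build_spearhead_geometry(0.55e-6, 0.058e-6, 2.25e-6, 90, 0.85)
spec = gm.curved_core_spec(geom, polarity_flip_positions=(0.5,),
                           tip_Mz_reversal=True)
phantom = gm.make_vortex_phantom(geom, spec, gm.MAGNETITE_MS, 40e-9)

# dual-axis tilt series and 10-iteration vector reconstruction
angles = np.arange(-70.0, 70.1, 2.0)
s1 = gm.simulate_tilt_series(phantom, "first", angles)
s2 = gm.simulate_tilt_series(phantom, "second", angles)
rec, state = gm.reconstruct_vector(s1, s2, phantom.mask, n_iterations=10)
err = (np.linalg.norm(rec.m[:, phantom.mask] - phantom.m[:, phantom.mask])
       / np.linalg.norm(phantom.m[:, phantom.mask]))
print(f"masked relative vector error: {err:.3f}")

core = gm.trace_core(rec, interior_gap_error=False)
print(f"core points: {core.n_points}, Bloch points: "
      f"{len(core.bloch_points)}")

# torque-transducer critical point
c121 = gm.sensitivity_curve(121.0)
c6 = gm.sensitivity_curve(6.0)
print(f"sharpness maximum at MB/K = {c121.peak_ratio:.3f}")
print(f"sharpness ratio K=121 vs K=6: "
      f"{c121.peak_sharpness / c6.peak_sharpness:.2f}")
print(f"minimum detectable angle: "
      f"{gm.minimum_detectable_angle(121.0, 121.0):.2f} deg")
```

Output:

```
masked relative vector error: 0.135
core points: 55, Bloch points: 1
sharpness maximum at MB/K = 1.007
sharpness ratio K=121 vs K=6: 2.48
minimum detectable angle: 0.73 deg
```

The reconstruction recovers the vortex texture with ~13% vector error
and finds the constructed mid-particle core-polarity reversal; the
deflection-fluctuation sharpness peaks essentially at *MB*/*K* = 1 and
is ≈2.5× greater for a giant-magnetofossil-scale receptor
(*K* = 121 k<sub>B</sub>T) than for a nanoparticle-cluster baseline
(*K* = 6 k<sub>B</sub>T), which is the quantitative sense in which the
spearhead is optimized for magnetointensity reception.

A micromagnetic counterpart (about half a minute on one CPU):

```python
grid = gm.voxelize(geom, 40e-9)
params = gm.magnetite()                       # [113] parallel to z
res = gm.minimize(gm.vortex_initialize(grid, params.M_s), params,
                  tolerance=1e-3)
mom = res.field.net_moment()
print(np.linalg.norm(mom))                    # ~1.4e-14 A·m²
```

relaxes to a single-vortex state with a curved core in the medial plane,
a medial domain wall, no Bloch point, and a net remanent moment of
~1×10⁻¹⁴ A·m² oriented ~9° from the long axis.

## Command line

```bash
giantmag phantom --voxel-size 40nm --out phantom.vtk
giantmag project --field phantom.vtk --axis 1 --angles -30:43:1 --out s1
giantmag recon --series1 s1 --series2 s2 --mask phantom.vtk --iters 10 --out rec.vtk
giantmag topology --field rec.vtk --report report.json
giantmag reception mb --moment 1e-14
giantmag micromag relax --voxel-size 40nm --out relaxed.vtk
```

Vector fields are written as ASCII legacy-VTK structured-points files
(readable in Paraview); tilt series as multipage TIFF with a JSON
sidecar.

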