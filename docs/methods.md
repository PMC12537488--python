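# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `giantmag`. It is written for a reader who
wants to know exactly what the package computes and what its passing
tests do and do not establish.

## Coordinate and unit conventions

Right-handed axes with `z` along the particle long axis (base at low
`z`, tip at high `z`) and `x` along the X-ray beam at zero tilt. Voxel
indices are 0-based; the physical center of voxel `(i, j, k)` is
`origin + (index + 0.5) · voxel_size`. All lengths are in meters,
magnetization in A/m, fields in tesla, energies in joules; the
torque-transducer module works in thermal units (k\_BT, radians). Every
stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`); there is no global random state.

## Spearhead geometry

The particle is a stack of `n` frustrum slabs with an elliptical cross
section (semi-major axis along `x`, minor/major ratio 0.85 by default).
Defaults: base radius 0.55 µm, tip radius 0.058 µm, length 2.25 µm,
90 slabs of 25 nm. Because the original radial profile was traced from
micrographs and no analytic form for it is published, the idealized
profile must be fixed by a convention: a cylinder over the first 55 %
of the length, then a linear taper to the tip radius, with the knee
smoothed by two passes of a clamped [1, 2, 1]/4 kernel (an effect
confined to about two slabs). Voxelization marks a voxel inside iff its
center lies inside the solid; the rasterized volume agrees with a
rejection-sampling Monte-Carlo estimate to within 2 % at 20 nm voxels
and changes by < 3 % between 40 nm and 20 nm.

## Vortex phantoms

Phantoms provide ground truth with exactly `|M| = M_s` inside the mask.
With core path `(c_x(z), c_y(z))` (cubic spline through control
points), in-plane polar coordinates `(ρ, θ)` about the core, and
Gaussian core profile `c(ρ) = exp(−ρ²/r_c²)`:

* `m_z = p(z)·c + A·(1 − c)·sin(θ − φ(z))`, clipped to [−1, 1];
* the in-plane part is tangential with magnitude `sqrt(1 − m_z²)` and
  sign set by the circulation sense.

`p(z)` is the core polarization (±1), flipped smoothly (tanh over one
slab height) at each prescribed fractional position — each flip is a
constructed Bloch point. The background term gives lateral halves of
opposing `m_z` separated by a medial `M_z = 0` wall through the core
(wall plane `y = c_y(z)`); the wall orientation `φ(z)` rotates by 180°
over the tip region (smoothstep between 78 % and 94 % of the length)
when the tip reversal is enabled, producing the wall twist. The tilt
amplitude `A = 0.4` encodes that the observed magnetization is
predominantly in-plane with a moderate length-parallel component; it is
a phantom parameter, not a fitted value.

Angular noise is an isotropic Gaussian kick in the local tangent plane
with per-component scale `sd·sqrt(2/π)`, so the *mean* angular
deviation equals the requested `sd` in the small-angle regime.

A note on topology: reversing the circulation sense of a vortex does
*not* change its winding number (negating a tangential field adds π to
every angle; the index stays +1). The circulation sense is therefore
measured separately, from the sign of the mean tangential component
about the core.

## Forward model (phase-XMCD projection)

A projection at tilt `α` about a series axis is computed by resampling
the scalar volume `b·M` (with `b` the beam direction in the sample
frame) onto the laboratory grid by trilinear interpolation and summing
along the beam axis, times the voxel size. The first series tilts about
the lab `y` axis; the second series first rotates the sample by 90°
about the sample normal (the beam direction at zero tilt), then tilts
about `y`. Positive tilt is a right-handed rotation about the named
axis — the underlying acquisition publishes no sign convention, so one
had to be fixed.

Rotate-and-sum was chosen over per-ray marching because its adjoint is
exact by construction: back-projection scatters with the *same*
trilinear corner weights that the forward gather uses, and the pair
passes an adjoint identity test at 10⁻⁶ relative tolerance. Accuracy
against an independent dense ray march at 4× step sampling is better
than 1 % of the image maximum. The pixel size equals the voxel size;
detector quantization and polarization-dependent absorption physics are
not modelled (the XMCD map is taken as the linear pre-edge phase
signal, scale constant 1).

Simulated misalignment adds a per-image integer shift (uniform in
±2 px) plus a Gaussian subpixel shift, and Gaussian signal noise; the
true shifts are recorded so alignment can be validated.

## Alignment and registration

Tilt-series alignment walks outward from the image nearest 0°,
registering each image to its angular neighbor by (upsampled) phase
cross-correlation on the charge images, then refines the component
parallel to the tilt axis by aligning each image's center of mass to
the series median — that coordinate is invariant under tilt. On
simulated series the residual is below ~0.3 px along the tilt axis; the
perpendicular component accumulates a slow drift (≤ 1 px over ±20°),
an intrinsic property of neighbor-chain alignment. The dual-axis
registration cross-correlates the two near-0° projections after an
in-plane 90° rotation, trying both rotation signs and keeping the one
with the lower registration error; the recovered offset is exact for
constructed displacements when the images have enough margin, and the
returned offset is expressed in the second series' own frame.

## Vector reconstruction

Starting from a zero-filled three-component field, each iteration:
forward-projects the guess at every angle of both series; accumulates
the sum-squared-difference error; forms the gradient by back-projecting
each residual and weighting by the per-angle beam-direction components;
takes an exact line-search step along the negative gradient (the
objective is quadratic, so the optimal step has a closed form); and
re-applies the material mask. Ten iterations by default; the two series
are weighted equally; no regularization is applied beyond the mask.
The error history is non-increasing by construction.

On a noiseless dual-axis series of the curved-core phantom with ±70°
coverage in 2° steps at 40 nm voxels (a grid of about 30×26×59), the
masked relative vector error after 10 iterations is 0.135 and the core
path is recovered to well within one voxel. With the restricted
experimental ranges (−30°…+43° and −42°…+34°) the point response
elongates along the beam axis `x` — the classic missing-wedge
signature — which is demonstrated on a single-voxel impulse.

## Voxel micromagnetics

Magnetite at room temperature: `M_s = 4.80768×10⁵ A/m`,
`K₁ = −1.32658×10⁴ J/m³`, `A_ex = 1.33487×10⁻¹¹ J/m` (exchange length
≈ 9.6 nm). The crystal orientation is a proper rotation built from two
crystal directions; the spearhead default places [113] along `z` with
the [111] easy axis in the `x–z` plane.

Discretization is finite-difference on cubic voxels rather than the
finite elements used in the original study — the FFT demagnetizing
convolution and the absence of a mesh generator keep the problem
desk-scale. Terms:

* **Exchange**: 6-neighbor Laplacian; a neighbor outside the mask
  contributes zero difference (free/Neumann boundary).
* **Cubic anisotropy**: `K₁(a₁²a₂² + a₂²a₃² + a₃²a₁²)` evaluated in the
  crystal frame.
* **Demagnetization**: convolution with the Newell cell-averaged tensor,
  evaluated on one octant (the tensor components have definite
  parities) and applied by zero-padded FFT at twice the grid size, so
  there is no wraparound. A uniformly magnetized cube and sphere both
  reproduce the demagnetizing factor 1/3 to well under 2 %.
* **Zeeman**: uniform applied field in tesla.

The default minimizer is projected L-BFGS on the parameterization
`m = u/|u|` (exactly unit-norm at every evaluate), with up to four
restarts when the line search stagnates before the torque target; a
damped gradient flow with backtracking is available as an alternative
method and reaches the same minima on small systems, but needs many
times more field evaluations on the spearhead. Energies are scaled by
the per-voxel demagnetizing scale `½µ₀M_s²h³` to keep the optimizer's
stopping tests meaningful. Convergence is reported as the maximum
reduced torque `|m × h|/|h|`; non-convergence within the iteration cap
is a warning plus a flag on the result, never a silent failure. The
spearhead at 40 nm voxels (~20 000 interior voxels) relaxes in well
under a minute on one CPU.

At 40 nm the vortex core (width a few exchange lengths) is
under-resolved; this is the accepted trade-off for test-budget-scale
runs, and it is why the coarse-grid remanent moment
(1.37×10⁻¹⁴ A·m², 9° from `z`) is quoted with a factor-two acceptance
band around 1×10⁻¹⁴ A·m². The susceptibility protocol (central
difference of the induced moment under ±1 mT, warm-started from the
ground state) gives `χ_z ≈ 6.3×10⁻¹² A·m²/T` with a `z`-to-transverse
anisotropy of ≈2.2–2.5 at this resolution.

Backfield behaviour at 40 nm: a reverse field of 10–14 mT nucleates a
Bloch point on the core (visible in the in-field state); by 18 mT the
reversal runs to completion, and after a −26 mT field plus relaxation
the remanent state has a fully reversed core with no trapped Bloch
point — the coarse grid provides no pinning to arrest the Bloch point
mid-particle, so the package demonstrates the reversal *process* (core
polarity flips; the mediating singularity appears in-field) rather than
a Bloch-point-bearing remanent state.

Hysteresis loops minimize from the previous state at each field step;
the coercivity is the interpolated zero crossing of the descending
branch, and the coercivity of remanence comes from a separate
backfield-remanence protocol. Full loops at meaningful resolution are
outside the test budget; the loop machinery is validated on a
single-domain cube (squareness ≈ 1, loop inversion symmetry).

Growth simulations add one slab at a time (base-up or tip-down), give
new voxels seeded random directions, and re-minimize the whole body;
both directions reach states of equal energy on the small test body.

## Torque-transducer model

Planar rotor with energy `u(ψ) = −MB·cos(θ − ψ) + ½Kψ²` on
ψ ∈ (−π, π], no small-angle truncation. Moments of the Boltzmann
distribution are computed by adaptive quadrature (relative tolerance
10⁻¹⁰) with the energy minima passed as break points so that narrow
wells at large K are never stepped over; halving the tolerance changes
Δψ by < 10⁻⁶ relative.

Two fluctuation measures are exposed, because the choice matters at the
bifurcation:

* `delta_psi_total` — the standard deviation of ψ over the full
  (possibly bimodal) distribution. This is the measure with clean
  closed-form limits: `(K − MB)^(−1/2)` in the harmonic regime and
  `[(24/K)^{1/2}·Γ(3/4)/Γ(1/4)]^{1/2}` in the quartic well at
  `MB = K`, both reproduced to < 1 %.
* `delta_psi_equilibrium` — the standard deviation of |ψ|, i.e. the
  fluctuation about the (sign-degenerate) equilibrium deflection. This
  is the measure used by the sensitivity analysis, on the physical
  argument that a gating filament responds to the magnitude of pivot
  deformation, and it is the one that places the sharpness maximum at
  `MB/K ≈ 1`.

With the equilibrium measure, the maximum of `d(Δψ)/d(MB/K)` at
θ = 180° sits at `MB/K = 1.007` for K = 121 k\_BT (approaching 1 from
above as K grows: 1.004 at K = 10³, 1.001 at K = 10⁴), the peak
sharpness grows as `K^{1/4}` (fitted log–log slope 0.26 over
K ∈ [10², 10⁴]), and the K = 121 / K = 6 peak-sharpness ratio is 2.48.
With the total measure the maximum instead sits near `MB/K = 1.10` and
the ratio near 3.0 — the equilibrium measure is the default precisely
because it reflects the fluctuation amplitude about the equilibrium
deflection rather than the well separation.

The minimum detectable deviation angle η uses a declared
signal-exceeds-noise criterion: the smallest η such that
`|⟨ψ⟩(180° − η)| ≥ Δψ(180°)` (noise factor 1, exposed as a parameter),
found by bisection to 0.01°. At the critical point this gives
η = 0.73° for K = 121 k\_BT and η = 8.9° for K = 6 k\_BT; both should
be read as order-of-magnitude quantities since the detectability
criterion itself is a modelling choice.

Fossil-energy statistics (`MB/k_BT` over user-supplied moment tables)
recompute every energy from the raw moment via `mb_ratio`; the
morphology sweep table itself is consumed as CSV, not reproduced.

## What the synthetic data do and do not show

The phantoms reproduce the *topological* features of the observed state
(curved core, polarity reversal, medial wall, tip twist) but are
analytic idealizations: real reconstructions carry ptychographic phase
noise, residual misalignment, missing-wedge anisotropy and a ~50 nm
resolution floor that the noiseless round trip does not emulate
(noise and misalignment can be injected, but no claim of experimental
fidelity is made). Passing the round-trip test shows the
projection/reconstruction/analysis chain is self-consistent and
accurate on well-sampled synthetic data — not that it would achieve the
same error on beamline data. Likewise the 40 nm micromagnetics
reproduces the state *class* and integral quantities of the published
simulations, not fine core structure. Out of scope entirely:
ptychographic phase retrieval, instrument control, finite-element
meshing, the nudged-elastic-band barrier calculation (the barrier for
Bloch-point nucleation is described only qualitatively in the source
study; no numeric target exists), and thermal (Langevin) dynamics.
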