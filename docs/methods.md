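# Methods

This note records the conventions, models and numerical choices behind
diffct, in enough detail to reproduce or audit every number the test suite
and `scripts/acceptance.py` compute.

## Coordinate and geometry conventions

All lengths are millimetres. The world frame is right-handed with the
isocenter at the origin; circular orbits lie in the z = 0 plane. The view
angle β rotates counterclockwise; at β = 0 rays travel along +y, the
in-plane detector axis points along +x, and the fan/cone source sits at
−SID·d(β) with central ray d(β) = (−sin β, cos β). Volume arrays are
C-ordered with x fastest ([iy, ix] in 2D, [iz, iy, ix] in 3D); the default
origin puts the grid centre at the isocenter. Detector pixels are centred:
pixel i of an n-pixel row sits at s = (i − (n−1)/2)·spacing + offset, and
continuous pixel coordinates are 0-based pixel centres. View angles cover
the half-open interval [start, start + range), so the angular increment is
range/n_views. These conventions are fixed here because the literature does
not standardise them; every operator, matrix and weight in the package is
consistent with this single frame.

Cone-beam geometry is carried entirely by 3×4 projection matrices K[R|t]
mapping homogeneous world points to (u·w, v·w, w). Generated circular-orbit
matrices keep the third row unnormalised so that w is the metric distance of
a point from the source along the central ray (w = SID at the isocenter);
the FDK distance weight is then simply (SID/w)². Calibrated matrices from
real systems can be loaded from plain text; the projector derives the source
position and per-pixel ray directions purely from the matrix (null space and
inverse of the left 3×3 block), so no separate geometry description is
needed.

## Projectors

The forward projector is ray-driven: for each detector pixel a ray is
clipped against the volume's support slab, marched in fixed steps of
`step_fraction · min(voxel spacing)` (default 0.5; the convergence tests use
0.25), sampled with bi/trilinear interpolation at step midpoints, and the
samples are summed times the step length, giving true line integrals in
value·mm. Samples outside the grid contribute zero (zero-padding
semantics). Interpolation at exact grid points returns the grid value.

The back projector is voxel-driven: each voxel's continuous detector
coordinate is computed per view (orthogonal projection for parallel beam,
source–voxel ray intersection for fan, perspective division through the
projection matrix for cone), the projection row/image is linearly
interpolated, and contributions are accumulated and scaled by the angular
increment Δβ. Out-of-range detector coordinates contribute zero. With
`fbp_weighting` enabled, fan/cone contributions are multiplied by the FDK
weight (SID/depth)² inside the kernel; the unweighted mode is the
adjoint-like operator used for gradients. The Δβ scaling means parallel FBP
needs no further normalisation; the raw adjoint-like sum is the result
divided by Δβ.

These two operators form the classic *unmatched* pair: the voxel-driven back
projector is close to, but not exactly, Aᵀ. `explicit_system_matrix`
materialises A column by column for tiny problems (≤ 2²² entries) and is the
oracle for this statement: on a 16² volume with 24 views × 23 pixels the
normalised dot-product discrepancy |⟨Ax, y⟩ − ⟨x, By⟩/Δβ| / (‖Ax‖‖y‖) is
measured at ~0.1–0.2%, comfortably bounded by the 5% the tests assert.

## Differentiable layers

Each layer registers the *exact algebraic transpose* of its own forward
kernel as its gradient operator: the projector's gradient is a ray-driven
splatting pass that distributes upstream sinogram gradients along the
identical sample trajectory with the identical interpolation weights, and
the back projector's gradient is the corresponding voxel-driven scatter into
detector bins. Pairing a layer with the *unmatched* counterpart instead
(back projection as a stand-in for Aᵀ) was considered and rejected: a
finite-difference check then plateaus at the pairing error (percent level),
and every downstream optimisation inherits that bias, whereas the exact
transposes pass central-difference gradient checks at the rounding floor
(~1e-12 measured, < 1e-5 asserted) while the unmatched-pair discrepancy
remains separately quantified in the projectors module. Gradient checks
scalarise a layer as L(x) = ⟨w, f(x)⟩ with a seeded Gaussian w, probe ≥ 32
seeded random coordinates with central differences (h = 1e-4 × input scale),
and report max |analytic − numeric| / max |numeric|.

## Filtering and weights

The frequency-domain ramp assigns weight |ω_k| = k/(n_pad·τ) cycles/mm up to
Nyquist (1/2τ). Rows are zero-padded to the next power of two ≥ twice the
row length before the FFT, which suppresses circular-convolution wrap; with
this scale and the Δβ-weighted back projection, a [0, π) parallel scan
reconstructs absolute attenuation values with no further constant. The
band-limited spatial Ram-Lak kernel h(0) = 1/4τ², h(odd k) = −1/(k²π²τ²),
h(even k) = 0 is the transform pair of the ramp: τ·DFT of the kernel matches
the ramp to 0.3% away from DC (asserted < 1%; the DC bin itself reflects the
kernel's finite length).

Fan-beam reconstruction follows the flat-detector (equispatial) formulation
with detector coordinates rescaled to the isocenter plane (filter spacing
τ·SID/SDD), cosine pre-weight cos γ = SDD/√(SDD² + s²), and distance-weighted
back projection. Short scans over π + 2γ_max apply Parker's piecewise sin²
weights; in this package's frame (γ signed along +u, counterclockwise
rotation) the redundant partner of ray (β, γ) is (β + π − 2γ, −γ), and the
weights are sin²((π/4)·β/(γ_max+γ)) on the entering wedge, 1 in the
interior, and sin²((π/4)·(π+2γ_max−β)/(γ_max−γ)) on the exiting wedge, with
pair sums equal to one to rounding. γ_max is computed from the full detector
half-width (n·spacing/2). The Parker-weighted short scan integrates each ray
with unit total weight, which replaces the ½-kernel convention of the full
2π formulation; the absolute scale was validated numerically against the
parallel pipeline (fan short-scan RMSE 1.7% on the 256² head phantom, with
correct absolute grey values). FDK applies the same machinery per detector
image: 3D cosine weight, row-wise ramp on the rescaled spacing, Parker
weights along u, matrix-based (SID/w)² back projection. On a 64³
z-symmetric phantom the FDK central plane agrees with the 2D fan
reconstruction of the central slice to 0.14% (asserted < 2%).

## Phantoms and the analytic oracle

Primitives (ellipses/ellipsoids rotated about z, axis-aligned boxes) are
additive and rasterised by centred supersampling (k² or k³ sub-samples per
voxel), so voxel values converge to exact coverage fractions. The
Shepp-Logan phantom uses the canonical ten-ellipse table in both the
original low-contrast and the widely used high-contrast ("modified")
intensities, scaled isotropically to the grid's smallest half-extent; the 3D
variant extends the table with the conventional z semi-axes and centres
(a documented convention — the z parameters are not derivable from the 2D
table). The parallel-beam oracle evaluates the closed-form Radon transform
of ellipses: chord length 2ab√(r² − t²)/r² with r² = a²cos²(θ−φ) +
b²sin²(θ−φ), exact to rounding, mass-conserving per view.

## Accuracy floor at object tangents

Comparing the discrete projector against the continuous closed form in the
max norm is dominated by the tangent rays of sharp-edged objects: a hard
ellipse boundary is not representable on a voxel grid, and the projected
edge is smoothed over roughly one voxel, which near a tangency of radius r
produces an error that scales like √(spacing/r) — about 1.6% of the sinogram
peak for a generic-position disk on a 256² grid, independent of ray-march
step (0.5/0.25/0.125 agree to three digits) and of supersampling. This is a
property of grid discretisation, not of the projector: an established
independent implementation (scikit-image's `radon`) shows a 12% tangent
error on the same task. Away from a ±2 mm tangency band the projector
agrees with the closed form to 0.31%. The acceptance suite asserts the
strict 1%-of-peak global bound regardless, so that test documents the floor
by failing; the acceptance script reports both the global and the
off-tangent number.

## Iterative reconstruction

`iterative_tv` minimises ‖Ax − p‖² + λ·TV_ε(x) by gradient descent with the
registered gradient (∇ = 2Aᵀ(Ax − p) + λ∇TV_ε), fixed step with halving
backtracking whenever a trial step increases the objective, so the returned
trace is non-increasing by construction. TV_ε is the smoothed isotropic
total variation Σ√(Σ_axes d² + ε²) − ε·n with forward differences and zero
difference across the far boundary; TV of a constant is exactly zero, the
gradient is the exact analytic one (finite-difference checked), and ε
(default 1e-6 of the value scale) trades smoothing bias against conditioning.
The sparse-view demonstration uses 30 views of the 128² head phantom with
λ = 1.0, step 2e-3 and 100 iterations from an FBP warm start, chosen as a
representative sparse-sampling regime where the TV prior visibly beats FBP
(6.6% vs 9.0% RMSE); plain gradient descent rather than accelerated schemes
is a deliberate simplicity choice, so iteration counts are what they are.

## Filter learning

`learn_fbp_filter` optimises the per-frequency weights K of the chain
x̂ = B F⁻¹ K F p against reference volumes under the quadratic loss
½‖x̂ − target‖², differentiated through the back-projection layer and the
(self-adjoint, real-symmetric) padded filtering operator. The loss is an
exact convex quadratic in K, but badly conditioned — plain steepest descent
stalls orders of magnitude above the optimum — so the default optimiser
takes conjugate-gradient directions with analytically optimal step lengths,
using Hessian-vector products read off the affine gradient (one extra
pipeline pass per iteration); a numeric `step_size` falls back to fixed-step
gradient descent with backtracking. From zero initialisation the iterates
stay in the data-supported Krylov subspace, the implicit regularisation that
keeps data-starved high frequencies near zero; the converged filter reaches
the normal-equations floor (verified against an explicitly materialised
design matrix on an 8² geometry, loss ratio 1.001) and has cosine similarity
0.96 to the analytic ramp on the 90-view 32² training problem. Learned
weights are clamped to be non-negative on export.

## Problem sizes and study conditions

The validation experiments run at the sizes quoted throughout: 256² slices
with 360 views for FBP self-consistency (parallel RMSE 2.7% < 5%, fan
short-scan 1.7% < 7%), 64³ volumes with a 128×128 detector and 180-view
short scan for FDK, 16² grids for gradient and adjointness checks, 128² with
30 views for the sparse-view TV study, and a 32²/90-view training set for
filter learning. Synthetic data throughout are noiseless line integrals of
analytic phantoms: passing these tests demonstrates correctness of the
operators, weights and gradients, and the internal consistency of the
pipelines, but says nothing about photon noise, beam hardening, scatter,
motion or detector non-idealities of real scanners, which the package does
not model (calibrated projection matrices can be ingested, but raw-data
corrections are out of scope).

## Other limitations

Only circular trajectories are generated (arbitrary matrices can be loaded);
detector tilt/skew intrinsics, helical scans, apodised filter windows
(Hann/Hamming/Shepp-Logan), matched Joseph/Siddon traversal, ordered
subsets and accelerated or statistical iterative schemes are out of scope.
The CPU kernels are compiled with numba on first use (a few seconds, cached
afterwards); computations are float64 in memory and float32 on disk.
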