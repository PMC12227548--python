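# Methods

## The mechanical model

The anterior neural plate (ANP) neuroectoderm is modelled as an infinite
two-dimensional incompressible viscous fluid experiencing linear friction
against the overlying enveloping layer (EVL). With the viscosity
normalized to µ = 1, the momentum and mass balances are

    ∇²u − γ² u = ∇p − f,        ∇·u = s,

where γ² (1/µm²) is the EVL–neuroectoderm friction coefficient, `f` a
superposition of in-plane point forces and `s` the source density of
sinks representing cells leaving the tissue plane during internalisation.
Both kinds of singularity sit on the dorsal midline (x = 0) at a distance
`d` from the anterior tissue limit and are regularized by an isotropic
Gaussian kernel whose standard deviation is the singularity's `extent`,
representing the physical area over which the force or flux is applied.
The friction term screens the logarithmic divergence of the 2D Stokeslet
(the Stokes paradox), so a bounded solution exists for any γ² > 0; the
γ² → 0 limit is meaningful only for velocity *differences*.

Coordinates: x mediolateral (midline at 0, positive right), y
anteroposterior (0 at the anterior tissue limit, positive posterior).
Force direction 0 points posterior (+y), π anterior. Magnitudes, sink
strengths and γ² are in arbitrary units consistent with µ = 1.

### Solution method

The point-force response is the screened Stokeslet

    u_i = (F_j / 2π) [A(γr) δ_ij + B(γr) r̂_i r̂_j],
    A(s) = K₀(s) + K₁(s)/s − 1/s²,
    B(s) = 2/s² − 2K₁(s)/s − K₀(s),

derived from a stream-function scalar φ with (∇² − γ²)φ = −Π, ∇²Π = g.
For the Gaussian-regularized force the solution splits exactly into

* a smoothed-log potential part, known in closed form (its radial
  derivative follows from Gauss's theorem over the Gaussian source), and
* an exponentially screened part evaluated by Gauss–Legendre quadrature
  of smooth Hankel integrals.

This split matters because the regularization correction to the potential
part decays only algebraically, like (extent/r)² — the pressure tail of
the Brinkman force response is unscreened — so a naive "point form beyond
a few extents" approximation is 10% wrong at 5 extents. The screened part
is negligible beyond max(12, 8·γ·extent) screening units and is replaced
there by the point Bessel form. Dimensionless profiles P₁(γr, γ·extent),
P₂(γr, γ·extent) are tabulated once per process on a 280×40 log-log grid
and interpolated with bivariate splines; table accuracy against adaptive
quadrature is ~1e−5 relative.

A Gaussian-regularized sink is radial potential flow, unaffected by
friction (the friction force on a gradient field is itself a gradient,
absorbed by the pressure):

    u_r(r) = −(Q / 2πr) (1 − exp(−r²/2a²)),

with peak inflow speed `u_sink` at r ≈ 1.585 a. All fields are finite
everywhere, linear in force vectors and sink strengths, and superpose.

### Independent verification

`pde_oracle` solves the same system by a second-order finite-difference
discretisation, independent of the closed forms: a stream-function/
vorticity solve for the solenoidal (force) part, with far-field dipole
boundary values ψ ≈ (F×r)_z / (2πγ²r²) derived only from the total force
vector, and a Poisson solve for the potential (sink) part with monopole
(net-flux) boundary values. Agreement with the closed-form route is
~0.1% relative L2 outside two regularization extents at 192² resolution,
with observed grid-convergence order ≈ 2.

## Flow-topology discrimination

Stagnation points are located by sign changes of both velocity components
followed by Newton refinement on spline interpolants, and classified from
the local Jacobian: saddles (extension points), centers (vortices, with
rotation sense = sign of the local curl), attracting nodes (sinks).
A rotational fixed point counts as a center when |trace|/|eigenvalue| <
0.1 — discretised frictional fields make off-axis centers weakly spiral.
The Poincaré index is +1 for det J > 0 and −1 for saddles, cross-checked
in tests against winding numbers.

The turning flow posterior to the axis sink is quantified as the mean
velocity component tangential to rays from the sink, normalized by the
mean speed, over a probe band posterior of and lateral to the sink. A
lone sink is exactly radial (fraction 0); force-bearing configurations
produce tangential fractions of ±0.3–0.4 whose sign is the turning
orientation. The presence threshold is 0.15. The sign of the plain
lateral velocity cannot make this distinction — radial inflow is also
laterally inward everywhere — which is why the tangential projection is
used.

The eight canonical candidate configurations (single anterior force,
two parallel forces, antiparallel pairs with either force dominant, lone
sink, sink + posterior pull, sink + anterior drag, sink + drag + smaller
pull) share one geometry chosen to resemble the tissue: a ~300 µm AP
domain, forces/sink at d = 40–190 µm, extents 20–25 µm, and γ² =
1.5e−3/µm² (screening length ~26 µm), which places lateral vortices
~50 µm off the midline as observed. Reference regimes for the two
developmental stages are *derived* from the configurations that reproduce
the observations, so the truth table tests consistency between
configurations rather than an absolute vortex sense.

## Fitting

`SingularityFlowModel(observed).fit()` minimises the relative RMS
residual ‖u_model − U_obs‖₂/‖U_obs‖₂ over masked grid points. Because
the flow is linear in the force components (Fx, Fy) and sink strengths Q,
those are solved exactly by linear least squares at every evaluation
(variable projection; Q ≥ 0 enforced by refitting offending sinks at
zero), and the nonlinear search — seeded Latin-hypercube multi-start
L-BFGS-B in a normalized unit cube — runs only over positions, extents
and log₁₀γ². Force magnitude and direction are recovered from (Fx, Fy),
so magnitudes are non-negative by construction and directions free in the
plane. Positions are constrained to the midline by default (off-axis
fitting available for sensitivity analysis). Local optima are
deduplicated at 10% of the bound range; near-ties (within 20% of the best
score) are kept as alternates. Forces are canonically ordered by axial
position for comparability across timepoints.

`fit_series` fits each timepoint independently (optionally warm-started
from the previous best), normalizes the fitted `u_sink` and γ²
trajectories by their series maxima, and reports per-singularity `d`
trajectories. A mechanical transition is flagged at the first timepoint
whose per-force AP-direction sign pattern differs from the initial
pattern and persists to the end of the series.

### Identifiability and the recovery study conditions

The recovery study truth is two opposing axial forces (anterior-directed
dominant), one sink, and γ² = 1.5e−3/µm², on a 24×24 grid spanning
±150 µm × [−30, 270] µm (~13 µm spacing, the 30 µm-box class of the
experimental fields). Two conditions matter:

* the screening length 1/γ (~26 µm) must exceed the grid spacing — with
  sub-grid screening the friction is unobservable and magnitude and γ²
  drift together by tens of percent along a flat likelihood ridge;
* fits operate on *window-averaged* flows, as in the experimental
  protocol (velocities averaged over 15 min): each fitted timepoint is
  the average of 8 synthetic frames at 2-min spacing, each carrying
  i.i.d. Gaussian noise of the stated fraction of the RMS speed. Fitting
  single raw 5%-noise snapshots instead leaves a maximum-likelihood
  estimate 25–35% along the magnitude/γ² ridge (the fit then genuinely
  scores better than the truth), so the ±15% recovery band is a property
  of the averaged-flow protocol, not of single snapshots.

Under these conditions, noiseless fits recover all parameters essentially
exactly (relative errors < 1e−6) and 5%-noise fits recover positions to
well under one extent and magnitudes/γ² to a few percent in most seeds.

## Surface projection

The implementation follows the experimental image-processing chain:
mean-intensity z-projection of the tissue-marker channel → Otsu threshold
→ largest component → boundary contour → chords of 20–200 px binned by
unsigned direction (bin π/10) → modal + adjacent bins define front
connectivity → the largest connected point set is the front. The new
x-direction is the average signed chord direction along the sorted front;
the perpendicular y-direction points away from the marker region, and the
start of the sorted front is chosen to preserve the handedness of the
axes. One robustness choice: only modal-bin chords enter the direction
*average* (adjacent bins still define connectivity); on strongly curved
outlines the adjacent-bin chords hug the region rim and bias the front
direction by ~0.1 rad. The default 20–200 px chord range presumes
full-size embryo images; analyses of the ~190 px phantom pass a range
scaled to the image (20–60 px).

Whole-embryo segmentation is Gaussian smoothing (s = 3 px) + Phansalkar
adaptive thresholding (radius 30 voxels; k = 0.25, r = 0.5, p = 2,
q = 10 — the standard published constants) + largest component.
Phansalkar thresholding is implemented in-package (mean/variance via
uniform filters); it is not available in scikit-image. The outer-surface
side of the z-stack is auto-detected by comparing, per z-half, the median
over slices of the mean in-plane voxel distance to the origin (the
narrower half holds the outer surface; ties take min-z with a warning).

The planar map sends each origin-translated surface point p = (x, y, z)
to q = r(p)(x, y) with |q| = |p| exactly (on a sphere of radius R through
the origin, a point at polar angle φ lands at planar radius 2R·sin(φ/2)).
The inverse map interpolates z linearly onto integer planar coordinates,
Gaussian-smooths the z-values (s = 20 px, NaN-aware normalized
convolution), and rescales (x, y) along each planar ray so |p| = |q|
holds again — the radial-rescaling convention for "preserving lengths as
in the forward mapping". Layers below the surface are sampled at
surface − k·Δz·n̂ with nearest-neighbour interpolation (linear behind a
flag); out-of-volume samples become NaN sentinels with a mask.

Smoothing sigmas are applied in pixel units as specified, without
anisotropy correction; the forward z-lookup uses linear interpolation of
the scattered projected points.

## Flow quantification and strain

The PIV surrogate is normalized cross-correlation template matching: the
template is the interrogation window shrunk by the search margin and
matched inside the full second-frame window, so no content is lost at any
lag (same-size-window correlation carries a triangular overlap bias of
~0.2 px toward zero displacement). The default search margin is
window/4 + 2 so that displacements up to a quarter window sit strictly
inside the search range. Subpixel refinement is a 3-point Gaussian fit
per axis, skipped when the peak correlation is 1 (a perfect match is an
exactly integer displacement). Single-pass only; window deformation and
outlier interpolation are out of scope, and externally computed fields
are accepted via CSV.

Domain averaging uses boxes with sides of 30 µm spanning from the origin
(the phrase "30 µm² boxes" elsewhere in the experimental description is
read as side length, consistent with its own "boxes with sides of
30 µm"), over a 15-min window centred on the target time. Symmetrisation
is the parity-respecting projection u_sym = (u(x) − u(−x))/2,
v_sym = (v(x) + v(−x))/2 — linear, idempotent, non-expansive — with
resampling (and a warning) for grids not symmetric about the midline.
Strain rates are central differences (one-sided at borders) of the
gridded velocities; only the two diagonal components are computed. Strain
maps reuse the 15-min averaging window when time-averaged.

## Morphometry

Cell segmentation is Gaussian smoothing followed by watershed on
intensity, seeded at h-minima of the smoothed image (the closest standard
analogue of the MATLAB default); seeds and depth are configurable. The
library default smoothing is s = 3 px, matching the experimental pixel
scale (0.8 µm/px); phantom analyses at 1 µm/px use s = 1 and h = 4% of
the intensity range. Ellipse metrics come from second central moments
(with the 1/12 pixel-integration correction); orientations are axial,
reported in (−π/2, π/2], and a circle's orientation is flagged undefined
at aspect ratios below 1.02. Axis endpoints are back-projected through
the surface map to correct mapping distortion. Domain orientation
statistics use doubled-angle circular means over 30 µm boxes and 20-min
windows; antipodal orientation sets (resultant ~0) are flagged undefined.
Tissue width averages five transects at 10/30/50/70/90% of the AP extent.
Internalisation depth is the minimum 3D distance from the track point to
the surface, computed in original coordinates (invariant to the planar
parameterisation). The validation protocol matches predicted to truth
cells by best overlap, counts successes at IoU > 0.6, and reports
per-metric correlations, size-relative differences, and the mean axial
angle difference for the successes.

## The synthetic data and what it does not cover

The phantom is a spherical cap (default R = 100 µm, half-angle 60°,
1 µm voxels) with a 12 µm cellular shell: membrane intensity is a
Gaussian ridge on Voronoi boundaries of cells seeded uniformly on the cap
(default 140 cells ≈ 17 µm diameter, the deep-cell scale), blurred by
1 voxel with 5% additive noise; the marker channel covers the shell on
one side of a vertical plane, so its anterior front projects to an
exactly straight line at a known angle. Flow fields are model evaluations
plus i.i.d. Gaussian noise scaled to the RMS speed; tracks are RK2
midpoint advections; PIV image pairs are Gaussian-blurred speckle
(σ = 1 px, the standard particle-image scale — larger speckles starve
32 px windows of texture) warped by the known displacement with linear
interpolation. All generators draw from one seeded generator per call and
are bit-reproducible.

Limitations: no photorealistic microscopy (PSF, photobleaching, depth
attenuation), no deformable tissue boundary or time-dependent flow in
the model, no 3D single-cell segmentation, and the phantom tissue simply
ends at the cap rim — rim cells lack a closing membrane ridge, so
segmentation benchmarks score interior cells. Passing tests therefore
demonstrate correctness of the geometry, kinematics, solvers and
estimators under controlled conditions, not robustness to microscopy
artefacts.

## Numerical choices and degenerate inputs

* Kernel table: s ∈ [1e−4, 400] (280 log nodes), γ·extent ∈ [0.06, 30]
  (40 log nodes); outside the table the hybrid far form is used directly.
* Sink flux at exactly 3 extents retains 1.1% of −Q (1 − e^{−4.5}); flux
  conservation is asserted from 3.5 extents outward.
* Newton refinement drops non-converged candidates with a log entry;
  fixed points are deduplicated within one grid cell.
* Degenerate inputs raise typed errors naming the failing step: empty
  marker channels (alignment), constant images (segmentation),
  single-slice masks (surface extraction), empty regions (strain
  extrema), all-masked fields (fitting), empty truth (validation).
* Zero observed fields fit zero magnitudes exactly (the linear
  subproblem returns zeros); zero-strength singularities evaluate to
  exactly zero flow.
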