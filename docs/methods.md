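# Methods

## The measurement model

Along a ray leaving a femoral surface vertex through the joint, the
underlying CT density is modelled as five constant levels separated by four
edges `x0 < x1 < x2 < x3` (all positions in mm along the ray, t = 0 at the
vertex, positive outward):

| segment | meaning | density |
|---|---|---|
| t < x0 | femoral interior (trabecular) | `y0`, free |
| x0–x1 | femoral cortex | `y_peak`, fixed |
| x1–x2 | joint tissue (cartilage) | `y_js = 35` HU, fixed |
| x2–x3 | acetabular cortex | `y_peak`, fixed |
| t > x3 | far side | `y3`, free |

The imaging system blur is treated as Gaussian with a per-ray standard
deviation σ; direction-dependent (anisotropic) blur is absorbed into σ
because each ray has its own value. The observed profile is the step
profile convolved with that Gaussian, which is the closed-form sum
`y(t) = y0 + Σ Δyᵢ Φ((t − xᵢ)/σ)` over the four edges, with Φ the standard
normal CDF. Joint space width is `x2 − x1`.

Holding `y_peak` and `y_js` fixed is what makes the inverse problem
well-posed below the resolution limit: when the gap is narrower than the
blur, peak height and gap width are strongly confounded for a free-peak
model, but with the peak pinned the gap is identifiable. `y_peak` is
estimated once per bone (below); `y_js = 35` HU is a fixed property of
cartilage on the CT scale.

## Fitting

Free parameters are `(x0, w_f, g, w_a, y0, y3, σ)` with `x1 = x0 + w_f`,
`x2 = x1 + g`, `x3 = x2 + w_a`. Fitting positive widths rather than raw
edge positions makes the ordering constraint structural. The optimiser is
scipy's bounded trust-region least squares with an analytic Jacobian;
bounds: cortical widths 0.2–8 mm, gap 0–12 mm, σ 0.1–3 mm, interior/far
densities ≤ `y_peak`; tolerances 1e-8, at most 200 residual evaluations.

Initialisation detects prominent profile peaks (3-sample median filter,
prominence ≥ 150 HU, minimum separation 0.8 mm so one cortex cannot
register twice through noise ties). The femoral cortex is the *first*
prominent peak walking outward — not the peak nearest the vertex, which can
be the acetabulum when the segmentation sits inside the true surface. With
two peaks, edges seed at the half-amplitude flanks on either side of the
inter-peak dip. With a single maximum the blur may have merged the two
cortices, so two seeds are tried — a merged small-gap hypothesis spanning
the half-amplitude support, and a lone-cortex hypothesis with the
acetabulum beyond the profile — and the lower-cost fit wins. A fit that
wins with the merged seed is still declared `no_opposing_bone` if a
single-cortex model (free peak) explains the data equally well
(within `1.02 × rms + max(0.5, 0.15 × noise)` HU, noise estimated from
successive differences): a genuine merged double peak leaves a dip no
single plateau can reproduce.

Plausibility: fits whose acetabular edge is pinned at the outward end of
the profile are `no_opposing_bone`; fitted femoral offsets beyond 2.5 mm
are rejected (`out_of_bounds`). The 2.5 mm acceptance limit deliberately
exceeds the 2 mm segmentation tolerance the method guarantees, so that
surfaces displaced by the full tolerated amount remain measurable despite
fit noise; on accurately segmented inputs fitted offsets stay well inside
2 mm.

## Peak cortical density

At ≤ 1,000 randomly sampled vertices of the whole bone surface, a
single-cortex blurred-plateau model with *free* peak density is fitted to
the profile (t ∈ [−4, 4] mm). Fits are kept when they converge with peak
amplitude ≥ 150 HU above the flanking levels and residual below
`0.2 × amplitude + 50` HU; at least 50 survivors are required. The global
`y_peak` is the 75th percentile of the surviving peaks — deliberately
toward the upper tail, since joint-facing vertices mis-fit low and true
cortical density is closer to the sample maximum than its centre. The σ
floor for these fits is 0.02 mm (below the joint-fit bound) so the
estimator also works on near-unblurred high-resolution data without
pinning. The estimate must come from the whole bone mesh, not the joint
patch: patch vertices all face the joint, where the single-cortex model is
wrong. On phantoms the estimator lands within ~1 % of truth at clinical
noise.

## Surface processing

Geometry and normals are decoupled in `mesh_from_mask`. The surface comes
from marching cubes on the mask smoothed by one voxel, keeping it within a
fraction of a voxel of the true boundary. Normals come from the gradient
of a separate, heavily smoothed field (2 mm world-space Gaussian, at least
one voxel per axis). The split matters at 1.5 mm slices: the surface only
anchors the sampling frame and the fit forgives millimetre offsets, but
staircase artefact in the *normals* tilts every sampling ray, and a tilt δ
inflates a measured gap by ≈ g·δ²/2 — at the 15–20° tilts raw thick-slice
meshes exhibit, that alone would exceed 0.1 mm. With field-gradient
normals the tilt is ~2°.

The joint margin polyline snaps to mesh vertices, consecutive snaps are
joined by shortest edge paths, and the enclosed side (chosen by seed point
or higher mean opposing-bone value) is flood-filled with the loop removed.
A loop that splits the surface into more than two regions is rejected as
self-intersecting; a loop that does not separate the surface encloses
everything. Re-triangulation to the target vertex count (~4,000 for a hip
patch) alternates longest-edge splits, shortest-edge collapses and
tangential Laplacian relaxation with re-projection onto the source surface;
boundary vertices are preserved exactly (the count tolerance of ±10 %
absorbs the fixed boundary). Normals of the remeshed patch are barycentric
interpolations of the source's field-gradient normals.

## Outlier removal and smoothing

Steep-gradient outlier removal flattens false peaks in the fitted femoral
surface: vertices whose femoral offset deviates from their 1-ring median by
more than 1 mm are refilled from neighbour medians, capped at 10 % of valid
vertices (worst first), so smooth maps pass through unchanged. Smoothing is
10 iterations of error-weighted Laplacian diffusion with per-vertex weight
`w = 1/(1 + (rms/median rms)²)` and step `0.5·(1 − w)`: unreliable vertices
contribute little to their neighbours and are pulled strongly toward the
reliable neighbourhood average. Every update is a convex combination, so
the value range cannot expand and constants are fixed points. The same
smoothing is applied to the femoral offsets; the femoral surface is the
patch displaced by the offsets along the normals and the acetabular surface
a further JSW beyond.

## High-resolution reference (half-maximum threshold)

When the blur is an order of magnitude finer than the joint space (0.082 mm
isotropic voxels), the half-amplitude crossing of a blurred step coincides
with the true edge, so thresholding replaces deconvolution. The threshold
is `(peak + y_js)/2` — half the peak amplitude *above the joint tissue
level*, which is the reading of "half-maximum" that makes the crossing
exact for a step between `y_js` and the cortical plateau. The femoral peak
is the prominent maximum nearest the vertex; the search continues outward
for the next peak above the femoral threshold, whose inward crossing is the
acetabular surface. Technical failures are removed by fixed limits
(positional: femoral edge within 2 mm of the patch; value: JSW in
[0.2, 10] mm) and no smoothing is applied, so the filter is idempotent.
Bias grows as gap or plate thickness approaches the blur width — the
degradation that motivates deconvolution at clinical resolution.

## Registration

Volumes: Mattes mutual information (64 bins), 7-DOF similarity transform,
3-level multiresolution pyramid (SimpleITK backend). Constant volumes yield
the identity with a warning; a result is never accepted with lower MI than
its initialisation. Surfaces: scaled iterative-closest-point (Umeyama
solve) with a coarse untrimmed phase followed by refinement that discards
correspondences landing on the target's open boundary and the worst-distance
decile — rim sliding otherwise biases open-patch alignment. Then a 3D
thin-plate spline (biharmonic kernel U(r) = r) on ~200 farthest-point
control correspondences, regularisation λ = 0.01 by default (λ = 0
interpolates exactly; coplanar control points are rejected as degenerate).

The average template surface seeds from the first contributor and refines
twice: register every contributor to the current reference, sample each at
the reference vertices by closest point, and move the reference by the
*smoothed mean offset field* (surface passes everywhere, extra passes along
the boundary chain). Averaging offsets rather than positions makes a set of
identical contributors an exact fixed point of the smoothing. Registration
during averaging is optional (`register=False`) for inputs already in a
common frame — note that ICP deliberately removes exactly the kind of
systematic normal offset one might want to average over. Per-vertex values
transfer to the template by nearest transformed source vertex with an
optional value-smoothing pass.

## Agreement statistics

Bias = mean(A − B), precision = sample SD (n−1) of A − B, Bland-Altman
limits of agreement = 1.96 × SD, per-pair CV = SD/mean with the two-value
SD `|a − b|/√2`, RMSCV = 100 × √(mean CV²). Central-95 % trimming masks
values strictly outside the [2.5, 97.5] linear-interpolation percentiles,
removing at most ⌊0.025·n⌋ per side with already-missing entries counted
against the budget — this makes the trim idempotent and leaves all-equal
samples untouched. Per-vertex 3D maps apply the same formulas down the
subject axis on a common template, masking vertices with fewer than three
contributing subjects.

## The phantom generator

Two-bone geometries with analytic ground truth: parallel plates, and a
ball-and-socket joint (spherical femoral head of radius 20 mm with a 1.5 mm
cortical shell over a 300 HU interior; a concentric acetabular shell
subtending a 60° polar cap; a radially measured gap g(θ, φ) of 35 HU joint
tissue; 35 HU soft-tissue background; cortex 1400 HU). Defaults emulate the
clinical hip CT regime: 0.31 × 0.31 mm pixels, 1.5 mm slices, Gaussian PSF
of FWHM 0.87 mm in-plane and 1.00 mm out-of-plane (a `psf_is_fwhm` switch
covers the alternative reading of those figures as σ directly — the
convention is not standardised, so it is a flagged option rather than a
silent assumption), and 20 HU iid Gaussian noise. The high-resolution
regime is 0.082 mm isotropic with a 0.089 mm FWHM PSF.

Rendering: the continuous geometry is evaluated on a 3× per-axis
supersampled grid, blurred with the PSF, and box-averaged back to voxels
(detector partial volume). Material boundaries are antialiased with a
one-sub-voxel linear ramp along the local edge normal; a hard threshold
would land edges on the sub-grid with a systematic half-sub-voxel
(~0.05 mm) shift — intolerable for a sub-voxel method's ground truth —
whereas the ramp is symmetric at every alignment and its small extra blur
(w/√12 ≲ 0.15 mm) is absorbed by the fitted σ. Volumes are rendered in
slabs so peak memory stays near one float32 supersampled volume. Identical
spec and seed give bit-identical volumes.

What the phantom does not emulate: trabecular texture, beam hardening,
correlated CT noise, cartilage structure beyond a uniform 35 HU layer, and
real anatomical shape variation. Passing the phantom studies therefore
demonstrates the correctness and noise behaviour of the measurement chain
under known geometry and blur, not clinical performance on real joints.
Note also that stacking the stated PSF *and* a full 1.5 mm box average
makes the phantom's out-of-plane blur harsher than the ~1 mm total blur the
PSF figures describe for real reconstructions, so the synthetic z-direction
regime is conservative.

## Problem sizes and defaults

The validation studies use a 20 mm femoral head with gaps spanning
1.5–4.5 mm (the validated range), a ~4,000-vertex patch for accuracy runs
and ~1,500–2,000 vertices for the perturbation and reproducibility runs —
enough for stable medians while keeping a full study at a few minutes on
one CPU. Statistics are reported over interior vertices (three edge-hops
from the patch boundary) because the outermost rings mix joint and
non-joint profiles by construction. Profiles sample t ∈ [−6, 10] mm at
0.1 mm steps with tricubic interpolation (trilinear available via
`interp_order=1`): the inward extent covers the femoral cortex under ±2 mm
segmentation error and the outward extent covers the largest expected gap
plus the acetabular cortex.

## Known limitations

- The Gaussian blur model cannot fully absorb the box-like component of
  thick-slice sampling; residual overestimation of ~0.05–0.1 mm remains for
  sub-2 mm gaps measured along the slice axis (mirrored by the method's
  known slight overestimation at low JSW).
- The 75th-percentile peak density is deliberately simple; a bone with
  strongly non-uniform cortical density will bias all gaps at joints whose
  local density differs from the global estimate.
- The remesher assumes a reasonably clean open patch; pathological
  self-intersecting inputs are not repaired.
- ICP-based surface registration needs shape features; on near-symmetric
  surfaces the azimuthal degree of freedom is only weakly determined (it
  converges, but slowly — the default is 100 iterations).
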