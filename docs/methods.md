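# Methods

`remodel3d` implements a three-stage analysis of longitudinal HR-pQCT
density images of peripheral joints: (1) alignment of the three
overlapping acquisition stacks of one scan into a contiguous volume,
(2) rigid registration of a follow-up scan to its baseline, and (3)
voxel-wise quantification of bone formation and resorption from the
registered pair. All images are calibrated density volumes in
mgHA/cm³ on regular grids with physical spacing and origin in mm;
transforms act on physical coordinates.

## Acquisition model

Second-generation HR-pQCT images peripheral joints at a nominal
isotropic resolution of 60.7 µm. A joint scan consists of three 10.2 mm
axial sections ("stacks") acquired separately with a 25 % (2.55 mm)
overlap, for a total length of 25.5 mm. The reconstruction accounts for
the average position of each stack, so patient motion *between* stack
acquisitions appears as a rigid misalignment of adjacent stacks — the
stack-shift artifact. Motion *within* a stack blurs the reconstruction
and cannot be corrected by rigid registration; it is handled by the
manufacturer's visual 1–5 motion grading, and scans with a stack graded
4 or 5 are excluded from quantitative analysis.

## Rigid registration

All registrations share one engine (`remodel3d.registration`):

- **Model.** A proper rigid transform `x ↦ R(x − c) + c + t` mapping
  moving-image physical space into fixed-image space, parameterized by
  three extrinsic Euler angles and three translations.
- **Initialization.** Translation from the intensity-weighted mass
  centers of the two images (foreground at 125 mgHA/cm³, which excludes
  soft tissue and noise); rotation from the principal axes of the
  intensity-weighted moment-of-inertia tensors when the implied rotation
  is a modest (< 10°) proper rotation, identity otherwise. The guard
  protects against eigenvector sign/ordering ambiguities in
  near-symmetric geometry.
- **Metric.** Pearson correlation of voxel intensities sampled on the
  fixed grid (restricted to the foreground bounding box plus a 3-voxel
  margin); voxels whose pre-image lies outside the moving extent are
  *excluded* from the correlation rather than filled, because fill
  values bias it.
- **Optimizer.** Nelder–Mead simplex over the six parameters, scaled so
  1° is commensurate with 0.1 mm; initial simplex steps 1° / 0.5 mm,
  convergence at 1e-4 on scaled parameters, 500 iterations overall
  (60 % on the coarse level). A 2-level multi-resolution pyramid (2×
  downsampling with matched Gaussian smoothing) precedes the
  full-resolution search.
- **Metric smoothing.** At the finest level, the metric is evaluated on
  copies of both images smoothed with a 0.5-voxel Gaussian. With
  uncorrelated acquisition noise, interpolating the raw moving image
  averages its noise most strongly at half-voxel offsets, so a
  raw-intensity correlation rewards spurious sub-voxel offsets — in
  practice a rotation of up to ~1° about the bone's long axis, whose
  true-structure penalty is smallest. Light smoothing suppresses the
  noise term and restores the optimum at the true pose; the final
  resampling still uses the raw images.
- **Output.** The transform, the final correlation, a convergence flag
  (simplex tolerance reached within the iteration budget), and the
  iteration count. Transforms serialize as plain-text 4×4 homogeneous
  matrices with a JSON sidecar (center, metric, convergence).

Registration accuracy on noise-free phantoms is ~0.01 voxel /
~0.02°; with σ = 30 mgHA/cm³ noise on both scans it remains well under
0.5 voxel / 1° (the acceptance suite checks 20 seeded repositionings of
up to 3 mm / 5°).

## Multi-stack alignment

Each stack pair is registered on the nominal overlap slab only
(`round(overlap_fraction · stack_length / spacing)` slices — 42 slices
at default geometry), but the resulting transform is applied to the
whole stack. The distal and proximal stacks are registered to the
middle stack, resampled into middle-stack space with cubic (B-spline)
interpolation, stripped of their overlap slabs, and concatenated with
the full middle stack (which keeps both overlap regions and is copied
without interpolation). Fractional-voxel boundaries round toward the
middle stack. The stitched volume's axial extent is `3L − 2fL` within
one voxel. A final correlation below 0.5 flags the stitch as "review
required" in the provenance record, mirroring the visual-inspection
step of practical workflows.

Only relative inter-stack motion matters, so simulated motions are
expressed relative to the middle stack (its own motion defines the
reference frame).

## Longitudinal registration and the largest common volume

Per bone, the periosteal mask is dilated (ball structuring element,
default radius 5 voxels — the radius is a free parameter of the
method) and used to crop the bone with a 5-voxel background border,
zeroing voxels outside the dilated mask. The follow-up crop is
registered to the baseline crop and resampled with cubic interpolation.

Two interpolation modes are supported. `moving_only` (default)
resamples only the follow-up onto the baseline grid. `both` places the
common grid half a voxel off the baseline grid and resamples *each*
image onto it exactly once, so both images carry the same one-pass
interpolation low-pass; any realization satisfying "each image is
interpolated exactly once" is conformant. On negative-control pairs the
two modes agree to within 0.1 percentage points of remodeling fraction.

The largest common volume (LCV) is the set of common-grid voxels whose
pre-image under the transform lies inside the follow-up extent,
intersected with the crop region (and optionally the dilated periosteal
mask). The LCV shrinks monotonically with transform magnitude.

The periosteal mask is an *input* (from the scanner's standard
evaluation, or ground truth for phantoms). A convenience auto-mask
(threshold 125 mgHA/cm³, ball closing of radius 5, hole filling) is
provided for data without one; it is non-canonical.

## Remodeling quantification

Within the LCV, `resorption_diff = baseline − followup` and
`formation_diff = followup − baseline`. Each difference is segmented
with a *strictly greater* threshold of 125 mgHA/cm³ (the
second-generation-scanner value; the first-generation literature value
225 is available as a preset), then cleaned with a connected-component
filter removing clusters of fewer than 5 voxels at 26-connectivity
(6/18/26 configurable). "Connected by fewer than 5 voxels" is read as
component-size filtering; bridge-width filtering is out of scope.

Fractions are reported as
`100 · |mask| / |baseline bone ∩ LCV|`, with the baseline bone
segmented at 320 mgHA/cm³ (a conventional bone threshold; the
denominator and threshold are configurable, `lcv_total` being the
alternative denominator, and both are echoed in the output provenance).
A 3-label overlay (1 = baseline bone, 2 = formation, 3 = resorption,
remodeling taking precedence over bone) supports visual review.

With σ = 30 mgHA/cm³ noise on both scans the voxel-wise difference has
σ ≈ 42; the 125 threshold sits at ≈ 3σ and the cluster filter removes
the surviving isolated voxels, which is why repositioning-plus-noise
negative controls yield fractions of 0.0 % (the scan–rescan behaviour
the method is designed to have).

## Synthetic phantoms

The generator (`remodel3d.phantom`) emulates the features the pipeline
is sensitive to, with full determinism under a seed:

- An elliptic-tube long bone (default semi-axes 1.3 × 1.0 mm) with a
  cortical shell whose thickness varies smoothly around the
  circumference and along the axis (random seeded phases), because a
  perfectly uniform shell would leave in-plane rotation nearly
  unconstrained — unlike real metacarpals.
- A trabecular interior generated by thresholding a smoothed Gaussian
  random field; the smoothing length is set by `rod_spacing_mm`
  (default 0.6 mm) and the strut volume fraction by
  `rod_width_mm / rod_spacing_mm`. An aperiodic network is essential: a
  periodic lattice hands the registration spurious self-matches at
  multiples of the period that real anatomy does not have.
- Frozen Gaussian density jitter inside the bone (anatomical texture,
  identical across simulated scans of one subject), distinct from
  per-scan acquisition noise.
- A Gaussian point-spread blur (default σ = 0.08 mm) emulating the
  scanner's band limit. Without it the piecewise-constant phantom has
  voxel-scale step edges that no interpolating resampler can
  reproduce, and resampling error — not registration error — dominates
  every comparison.
- Optional hemispherical cortical erosions (center, radius), carving
  bone down to a low density; voxelized volume within ~10 % of the
  analytic value for radii of ~4 voxels on gently curved cortex.
- Stack acquisition: three slabs cut at nominal offsets, each resampled
  under its own rigid motion, with independent Gaussian noise
  (default σ = 30 mgHA/cm³, sub-threshold by construction).
- Follow-up simulation: spherical formation regions raise eligible
  low-density voxels to bone density and resorption regions lower
  eligible bone voxels to marrow density, so every changed voxel moves
  by ≥ 250 mgHA/cm³ and the truth masks record exactly the changed
  voxels in baseline space. The whole volume is then repositioned —
  the follow-up grid's origin follows the translation, as an operator
  re-centers the anatomy — resampled once cubically, and noise is
  added.

Default sizes: the acquisition-length phantom is 80 × 80 × 428 voxels
(≈ 4.9 × 4.9 × 26 mm) — the in-plane field of view leaves > 1 mm of
background margin so that ≤ 1 mm stack motion never pushes bone outside
the acquired volume; longitudinal experiments use an 80 × 80 × 200
segment with the bone capped 3 mm inside the volume so the LCV boundary
stays in background under ≤ 3 mm repositioning.

### What the phantoms do not emulate

CT projection physics (beam hardening, scatter, scanner-specific PSF
anisotropy), intra-stack motion blur, soft-tissue heterogeneity, and
true trabecular microarchitecture. Passing the phantom suites therefore
demonstrates the *registration and quantification machinery* — not the
biological validity of the 125 mgHA/cm³ change threshold on patient
data, which requires cadaveric or clinical validation.

## Validation experiments and measurement choices

`remodel3d.validation` packages the seeded experiments the test suite
and `scripts/acceptance.py` run:

- **Stitching recovery** (10 seeds, per-stack motions ≤ 1 mm / 2°,
  noise off so the experiment isolates stitching error from the
  independent noise floor): mean absolute density error over bone
  voxels in the axial interior (a ~1 mm margin at the volume ends can
  lack source data under 1 mm motion) relative to mean bone density,
  and the seam discontinuity ratio of naive vs registered
  concatenation. Seam discontinuity is the mean |Δ| across the seam
  plane over foreground voxels, measured as the *excess* over the
  motion-free phantom's natural inter-slice variation at that plane —
  the floor no stitching can go below.
- **Longitudinal recovery** (20 seeds, repositioning ≤ 3 mm / 5°,
  σ = 30 noise on both scans): target-registration error at the bone
  center in voxels, and the residual rotation angle.
- **Remodeling recovery** (multifocal formation and resorption spheres,
  each region ≥ 10 voxels and |Δ| ≥ 250 mgHA/cm³, with repositioning
  and noise): Dice overlap of detected vs true masks and the fraction
  error in percentage points. Simulated change is multifocal because
  that is the RA pattern and because a single compact focus of ~4 % of
  bone volume measurably biases any correlation-based registration
  (~1° about the bone axis in the worst-case geometry we measured).
- **Negative control** (repositioning + noise only, both interpolation
  modes): the scan–rescan analog; median fractions are 0.0 %.

## Known limitations

- Correlation registration is biased by large focal change; the
  multifocal experiments bound this at realistic change fractions, but
  a single massive erosion adjacent to thin cortex remains the worst
  case.
- The convergence flag reports simplex tolerance within the iteration
  budget; accurate solutions routinely exhaust the budget first, so
  `converged=False` with a high metric is common and benign.
- Stack stitching assumes rigid inter-stack motion; intra-stack motion
  is out of scope and must be handled by motion grading.
- The `both` interpolation mode changes the output grid by half a
  voxel; masks and overlays from different modes are not
  voxel-comparable.
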