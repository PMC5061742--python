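# Methods

## Coordinate conventions

Everything inside the package speaks one language: streamline points are
world millimetres in RAS orientation, voxel indices are 0-based, and a
grid's 4×4 affine maps a voxel index to the **center** of that voxel.
Format-specific conventions (TRK's corner-origin voxel-mm frame) are
converted at the I/O boundary by nibabel, never downstream. TCK files carry
no reference grid and no per-point data; a tractogram loaded from TCK gets
a placeholder unit grid until a caller (or the pipeline, which borrows the
subject's segmentation grid) attaches a real one. TRK round-trips both
coordinates (to float32 precision, ≈1e-6 mm at head-size coordinates) and
embedded scalars.

## ROI queries

Filter masks are built from an integer label volume with a small set
algebra: union `|`, intersection `&`, difference `-`, complement `!`, and
`dilate(expr, k)`. Precedence is `!` > `&` > `-` > `|`, parentheses
override, label names match the lookup table case-insensitively, and names
containing hyphens (FreeSurfer's `ctx-lh-precentral`) must be quoted
because bare `-` is the difference operator. This grammar is this package's
own design: a minimal algebra sufficient to express waypoint, exclusion and
gray/white boundary masks, the latter compositionally as
`dilate(cortical_label, k) & white_matter_label` rather than via a special
primitive. Dilation is k iterations of 26-neighborhood binary dilation
(scipy), matching the permissiveness of the point-membership intersection
test; the complement is taken within the grid.

## Streamline–mask intersection and rasterization

Both filtering and rasterization test subdivided polyline points against
voxels: each segment is resampled so consecutive samples are at most half
the smallest voxel size apart, which guarantees a segment cannot jump over
a one-voxel-thick mask (a sphere of radius half-min-spacing around every
sample covers the segment). This is point-membership rasterization, not
exact 3D voxel traversal; the test suite bounds the discrepancy against a
0.01 mm dense-sampling oracle and verifies that a straight axis-aligned
streamline marks exactly the voxel centers it passes through and that
marked voxel sets are 26-connected. An `endpoints` mode tests only the
first/last points, for protocols that filter on termination regions.

A streamline is kept iff it intersects **every** inclusion mask (AND
semantics — waypoint style; a per-anatomy `include_logic: any` flag relaxes
this) and **no** exclusion mask. Empty mask lists impose no constraint, so
`include=[], exclude=[]` is exactly the unfiltered condition.

## Scalar embedding and warping

Diffusion scalars (FA/AD/RD) are sampled with trilinear interpolation at
the stored streamline points **in the native DWI space, before any
deformation**, so tensor-derived metrics are never interpolated through a
registration warp. The sampler is exact on affine fields and returns stored
values at voxel centers; points within half a voxel beyond the border use
clamped (edge) values, and farther points either raise (strict mode) or
take a fill value (lenient).

Warping composes an affine with an optional dense displacement field:
y = A·x, then y + D(y), with D trilinearly sampled at the affinely
transformed point — the usual deformable-registration composition where the
field lives in target-space world coordinates. Registrations that export
source-space fields are handled by `field_space="source"` (sample D at x).
Points landing outside the field are clamped to its border and counted in a
warning (or raise in strict mode). Streamlines are **not** resampled to
uniform step length before warping; point counts and scalars pass through
unchanged.

## Conjunction image and level sets

Per-subject binary masks are summed voxel-wise. The conjunction image
stores integer counts k together with N (never the float ratio), so the
overlap fraction s = k/N and all super-level sets can be computed in exact
integer arithmetic. Level masks at 10% steps use s ≥ j/10 (≥ rather than >,
so the 100% level is non-empty under perfect overlap) and are nested by
construction. Serialization is an int32 NIfTI plus a `{n_subjects}` JSON
sidecar, with a float-fraction NIfTI as a convenience export.

## The normalized overlap score

With n bins (default 10) and v_i = |{voxels : s > i/n}|,

    NOS = (1/n) · Σ_{i=0}^{n-1} ln(v_i)/ln(v_0).

Numerical choices, each flagged in the API:

* **Strict bins** (`bin_rule="gt"`, default): v_0 then reduces exactly to
  the support |{s > 0}| and the i = 0 term is always 1, giving the bounds
  1/n ≤ NOS ≤ 1 whenever v_0 ≥ 2. A `ge` rule is provided for protocols
  that prefer closed level sets.
* **Natural log**; the ratio ln(v_i)/ln(v_0) makes the score independent of
  the log base only when v_i = v_0, so the base is part of the definition.
* **Empty bins contribute 0**, not −∞: an agreement level that no voxel
  reaches adds no evidence of reproducibility, and the score stays in
  [0, 1].
* **Exact integer thresholds**: s > i/n is evaluated as k·n > i·N, which
  matters when N is not a multiple of n (e.g. N = 42, n = 10 — k = 21 of 42
  gives s = 0.5, correctly *not* exceeding the i = 5 bin).
* v_0 = 0 raises an empty-conjunction error and v_0 = 1 a
  degenerate-support error (ln 1 = 0). The benchmark studies map these to a
  score of 0 — an algorithm that produces no surviving streamlines has no
  reproducible support — but the metric itself refuses to silently invent a
  number.

NOS depends on the conjunction image only through the histogram of k, so it
is invariant under voxel permutations; it is monotone in voxel-wise overlap
at fixed support.

## Rater statistics

Rater scores are min–max scaled to [0, 1] within each (anatomy, condition)
stratum — anatomies differ in intrinsic difficulty, and a bounded
normalized score is the natural scale for cross-anatomy pooling. A constant
stratum carries no ordering information and maps to 0.5 with a warning.
Regression pairs the mean normalized rating across raters per (anatomy,
algorithm, condition) with that cell's NOS (per-rater pooling is available
as an option) and fits ordinary least squares with a two-sided t test of
zero slope. The suite cross-checks slope, intercept, p and R² against
statsmodels OLS and verifies the test's type-I error calibration by
simulation.

## Synthetic cohorts

The generator emulates the statistical structure of a group tractography
study, not its imaging physics. Each subject's bundle is a set of parallel
copies of an analytic arc centerline (quadratic Bezier, imitating curved
central pathways), each copy offset by a per-streamline isotropic Gaussian
(radial dispersion, mm), the whole subject by a rigid Gaussian jitter
(inter-subject variability plus registration error), and a configurable
fraction of streamlines rerouted to a decoy curve 10 mm off the bundle
plane (false positives). Defaults: 1 mm isotropic 40×40×30 template grid,
6–10 subjects, 15–20 streamlines per subject, dispersion and jitter of
0.3–0.5 mm for tight cohorts and 2–3 mm for dispersed ones — chosen as
representative of, respectively, sub-voxel tracking coherence and the
few-millimetre anatomical spread seen across registered cohorts on a
millimetre-resolution grid. The benchmark's tightness scale t ∈ [0, 1] maps
linearly onto these knobs (dispersion = jitter = 0.3 + 2.2·(1−t) mm,
false-positive rate = 0.5·(1−t)), so "algorithm archetypes" are single
points on one axis.

What this does **not** model: curvature-dependent dispersion, streamline
length variation, partial-volume and susceptibility artifacts, correlated
(non-rigid) inter-subject deformation, and raters who respond to anatomy
rather than to tightness. Passing tests therefore demonstrate that the
pipeline machinery is correct and that the score orders cohorts by
reproducibility under a known noise model — not that any particular real
algorithm will score in any particular range.

The studies in `grouptract.study` use 20 seeded cohort pairs for the
tight-vs-dispersed contrast and 6 anatomies × 4 algorithm archetypes
(24 cells, 5 raters) for the rating regression; these sizes give stable
results (the contrast ranking is unanimous and the filtered regression
p-value is well below 0.05 across seeds) while keeping a full run in the
tens of seconds on one CPU.

## Reports

Per-anatomy reports are 2D maximum-intensity-projection montages
(sagittal/coronal/axial) of the overlap fraction with a perceptually
uniform colormap (viridis), so equal overlap steps read as equal brightness
steps; 3D isosurface rendering is deliberately out of scope.

## Known limitations

* Rasterization marks voxels by subdivided-point membership; a segment
  grazing a voxel corner between samples can in principle be missed (the
  dense-sampling oracle test bounds this in practice).
* TCK cannot carry embedded scalars; use TRK (or keep tractograms in
  memory) when scalars matter.
* Fiber-density (non-binary) conjunctions, Dice-style pairwise overlap
  statistics, displacement-field inversion and registration estimation are
  out of scope.
* The rating regression treats cells as independent observations; no
  mixed-effects structure over anatomies or raters is modelled.
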