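# Methods

## Images and conventions

All measurements operate on `VoxelImage`: a 3-D scalar grid indexed
`(z, y, x)` (the multi-page-TIFF layout) with isotropic voxel spacing in μm.
Binary images use foreground = 255, background = 0; thresholding is
inclusive (`value ≥ t` is foreground), so the conventional cut at 128 is a
no-op on 0/255 binaries.  The IsoData threshold iterates
`t ← (mean(values ≤ t) + mean(values > t))/2` from mid-range to a fixed
point and reports the floor of the converged value on integer images,
matching integer-histogram implementations.  Voxels are centered on integer
indices; the physical position of voxel `(k, j, i)` is
`(k+0.5, j+0.5, i+0.5) · spacing`.

## Meshing

Surfaces are extracted by marching cubes with linear vertex interpolation
(scikit-image), optionally after block-resampling the image by an integer
factor (each output voxel is the mean of a factor³ block; spacing scales by
the factor).  Two boundary modes:

* **capped** (default): the volume is padded with one background layer, so
  structures cut by the stack faces are closed by cap faces and the mesh is
  a closed 2-manifold.  This is the realistic mode for cropped volumes of
  interest — the cut ends of plates and rods are real, convex surface.
* **open**: the volume is meshed as-is; structures spanning the full stack
  keep their cut sections open.  This is the validation mode in which the
  analytic values of infinite plates and rods are recovered without edge
  terms.

Smoothing is per-vertex Laplacian relaxation: each vertex moves `factor` of
the way toward the centroid of its edge-connected neighbors, for a given
number of passes (defaults: factor 0.5, one pass, mirroring the reference
meshing protocol for trabecular stacks; both are exposed).  Degenerate
faces are dropped and unreferenced vertices removed at construction.
Winding is canonicalized outward (positive signed volume for closed
meshes).

## SMI, SMI⁺/SMI⁻ and concave fraction

`compute_smi` meshes the binary image, computes unit vertex normals as the
normalized area-weighted mean of incident face normals, translates every
vertex by `r` along its normal, and takes per-triangle area differences
`s′ᵢ`.  Then

* `SMI = 6·(S′/r)·V/S²` with `S′ = Σ s′ᵢ`;
* `SMI⁺`/`SMI⁻` sum the strictly positive / strictly negative `s′ᵢ`
  (zero-change faces contribute to neither, so the partition identity
  `SMI = SMI⁺ + SMI⁻` holds to rounding);
* `U` is the sum of *original* areas of faces with `s′ᵢ < 0` and
  `CF = U/S`;
* `V` is foreground-voxel count × voxel volume (consistent with BV/TV); a
  mesh-enclosed-volume option exists for closed meshes.

**Dilation distance.** `r` defaults to 0.005 × voxel spacing: small enough
that `S′/r` approximates the area derivative (halving `r` moves SMI by
< 10⁻³ on the analytic phantoms), large enough that the per-triangle area
differences are far above float cancellation.

**Curvature classes.** For visualization, faces are classed by the
normalized change `s′ᵢ/(r·Aᵢ)` against a flat band ε (default 10⁻⁶):
convex (yellow), concave (blue), flat (white), with saturation scaled by
magnitude.  The band affects display classes only; CF itself uses the
strict sign, so it is ε-independent.

**Validation protocol.** The analytic calibration (sphere SMI = 4,
full-span cylinder 3, full-span plate 0) is computed with resample factor 3
and smoothing 0.  Raw marching cubes on a binary image produces a staircase
surface whose local curvature noise is catastrophic for a
dilation-derivative measurement (a voxelized ball reads SMI ≈ 3.5 with a
spurious 40% concave fraction); block resampling turns the binary image
grayscale, and linear iso-surface interpolation then reconstructs a smooth
surface (ball 3.974, cylinder 3.027, plate 0 exactly).  Additional
Laplacian smoothing is *not* applied in this protocol because it shrinks
thin structures — curvature flow contracts a radius-10/3 tube noticeably in
a few passes — and biases the cylinder value up to ≈ 3.17.  For real
trabecular stacks the default pipeline (resample 3, smoothing 0.5 × 1,
capped) mirrors the standard protocol.

## Ellipsoid factor

`EF = a/b − b/c` for sorted semi-axes of the largest inscribed ellipsoid
containing a point.  The pipeline:

1. **Seeding** on the medial axis: the 3-D thinning skeleton
   (scikit-image), subsampled reproducibly to `max_seeds` (default 1000).
   Cross-sections symmetric about half-integer centers can thin away
   completely (parallel thinning has no unique center voxel to keep); the
   fallback is the locus of local maxima of the Euclidean distance
   transform — the centers of maximal inscribed balls, i.e. the medial axis
   by definition.
2. **Fitting** by stochastic hill climb from a 0.5-voxel seed sphere.
   Proposals — dilate one random semi-axis by 0.5 voxel (p = 0.5), rotate
   by up to 5° (p = 0.25), translate by up to 0.5 voxel (p = 0.25) — are
   accepted iff all 100 quasi-uniform (Fibonacci-lattice) surface sample
   points remain on foreground voxels (nearest-voxel lookup; outside the
   stack counts as background), volume never decreases, and the seed stays
   inside.  The search stops after 100 consecutive proposals without a
   volume increase (a rotation or translation that keeps containment is
   applied but does not reset the stall counter, since it does not grow the
   ellipsoid), with a hard cap of 5000 proposals.  All constants live in
   `FitConfig`.
3. **Mapping**: each foreground voxel takes the EF of the largest-volume
   fitted ellipsoid containing it.  Voxels reached by no ellipsoid are
   excluded from the mean and reported via the coverage fraction — with
   sparse seeding, coverage of 0.5–0.8 is typical on junction-rich
   phantoms, so mean EF is an estimate over the covered volume, not a
   census.

Sparse surface sampling means features smaller than the inter-sample
spacing can be overlooked as an ellipsoid grows; this finds dominant local
structure and is not analytically exact.

## Phantoms

Foreground membership is decided on voxel centers, so every phantom is
brute-force checkable.  Sphere, cylinder and plate carry the analytic
calibration.  The lattice (plates normal to z repeating every
`cell_spacing`, rods along z on a square x–y grid) produces concave saddle
junctions.  The pseudo-trabecular phantom is seeded Gaussian white noise,
low-pass filtered with σ = `correlation_length` voxels and thresholded at
the quantile that yields the target BV/TV exactly.

Defaults (160³, BV/TV 0.44, σ = 16) emulate the substrate of a resorption
simulation: thick elements (diameter ≈ 2σ ≈ 32 voxels) at high volume
fraction, chosen so that no element vanishes over an 8-step single-voxel
erosion — the same property for which a thick-strutted, high-BV/TV
specimen is the natural choice in erosion experiments on real trabeculae.
What the generator does **not** emulate: level sets of a Gaussian random
field are saddle-rich and isotropic, so the phantom starts near SMI ≈ 2.6
rather than the low, plate-like values of real high-BV/TV bone, and it has
no marrow-space anisotropy, no cortical shell, no osteonal porosity.
Passing direction checks on it therefore demonstrates the *mechanism*
(erosion drives SMI through SMI⁻ while SMI⁺ stays put), not quantitative
agreement with any real specimen.

## Resorption simulation

`erode3d` removes every foreground voxel with a background face-neighbor
(6-connected structuring element by default, 26 optional); the stack border
counts as background so cut surfaces erode too, mirroring resorption across
the entire bone surface.  `resorption_simulation` records
(step, BV/TV, SMI, SMI⁺, SMI⁻, CF) from step 0, stopping early if the
foreground vanishes.

The trace measurements in the acceptance suite use resample 1 with
smoothing 0.5 × 10 passes rather than the resample-3 default: the eroding
surface advances 1 voxel per step and beats against a 3-voxel block grid,
which injects period-3 aliasing jitter (≈ ±0.04 in SMI) large enough to
mask the monotone trend between adjacent steps; meshing at full resolution
removes the grid phase, and the heavier relaxation suppresses the staircase
instead.

## Statistics

Ordinary least squares (via statsmodels) in three forms: linear, quadratic,
and quadratic through the origin — the last for the negative SMI component,
which must vanish when the concave fraction does.  R² follows the `lm`
convention (centered total sum of squares with an intercept, uncentered
without); p-values are model F-tests.  The Wilcoxon–Mann–Whitney rank-sum
test is exact by enumeration for combined n ≤ 20 without ties, otherwise a
tie-corrected normal approximation with continuity correction.  No
multiple-comparison adjustment is applied: the analyses characterize
specific pairwise relationships, collinearity included.

## Design notes and limitations

* The lattice cohort used to demonstrate the confound varies packing
  density (driving BV/TV and junction surface) while alternating rod/plate
  emphasis independently of it, because EF is *supposed* to track the
  rod/plate mix: a cohort that only thickens one fixed topology makes EF
  follow BV/TV legitimately as junctions round off, which is a different
  regime from a population of specimens with diverse architecture.
* Mesh generation is a genuinely uncontrolled variable across
  implementations (case tables, smoothing schemes, resampling); absolute
  SMI values are comparable only within one pipeline.  The calibration
  phantoms bound the systematic error of this one (≲ 0.03 on the analytic
  values at the sizes used).
* Ellipsoid fitting is stochastic; with a fixed RNG seed it is exactly
  reproducible, and mean EF is stable to ≈ ±0.03 under 90° stack rotations
  at 150 seeds on lattice phantoms.
* Runtime targets desk scale (≤ 200³ phantom stacks); the full test suite
  runs in about a minute on one CPU, the acceptance script in seconds.
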