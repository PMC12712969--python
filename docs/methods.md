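# Methods

## The centroid iterative model

The femoral neck is treated as a stack of planar cross-sections whose
area-weighted centroids trace the neck axis. The fit alternates two
steps: (i) slice the mesh with equally spaced parallel planes and take
each section's polygon centroid; (ii) fit a total-least-squares (TLS)
line to the centroid cloud and re-orient the slicing planes
perpendicular to it. The TLS line minimises the sum of squared
*orthogonal* distances (principal direction of the centred cloud), which
is the correct objective for an axis with no preferred parametrising
coordinate. After the final iteration a cylinder is fitted to the
centroid cloud and its axis is taken as the femoral neck axis (FNA); a
sphere is fitted to the femoral-head vertices, and the perpendicular
distance from its centre to the FNA (DBHF) is the accuracy metric, under
the assumption that an ideally determined head centre lies on the axis.

Assumptions: the input mesh is a watertight 2-manifold in mm; the neck
region is roughly convex around its axis so each slicing plane cuts it
in a single closed loop; the three seeding landmarks span a plane near
the neck base whose normal points broadly along the neck.

### Protocol parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `n_sections` | 10 | – | sections per stack |
| `spacing` | 1.0 | mm | distance between sections |
| `n_iterations` | 5 | – | re-slicing passes |
| `early_stop_tol_deg` | off | deg | optional stop when successive axes agree |
| `cylinder_source` | centroids | – | cylinder fitted to centroids or contour points |
| `head_axial_margin` | 14 | mm | head-selection clearance past the last section |
| `head_radial_factor` | 1.5 | – | radial gate (× 75th percentile) for head vertices |
| `head_trim_mm` | 0.75 | mm | sphere-fit residual trim threshold |

The first three defaults are the published protocol of the method; the
head-selection values were chosen on the phantom so that the selected
set covers the spherical part of the head while excluding the blended
head–neck junction (see *Numerical choices*).

### Design choices in the iteration

* **Translation direction.** The stack advances along the initial-plane
  normal oriented toward the head hint; the landmark plane sits at the
  neck base, so toward-head is the only anatomically sensible direction.
* **Anchoring.** Each subsequent stack is anchored at the previous
  stack's first centroid, perpendicular to the fresh axis. Because a
  section centroid lies exactly in its section plane, the stack advances
  one spacing per iteration, which also walks it out of the irregular
  base region.
* **Contour selection.** A plane through the neck can also cut the
  trochanter or the head. Each section keeps the closed contour whose
  centroid is nearest the previous section's centroid (the first uses
  the head hint projected onto the base plane); loops below 1% of the
  largest loop's area are discarded first, since surface noise creates
  sliver loops that would otherwise hijack the nearest-centroid rule.
* **Orientation.** All fitted directions are sign-fixed toward the
  femoral head via the explicit `head_hint` landmark; the geometric
  primitives themselves stay sign-agnostic.

## Slicing

A slice computes signed vertex distances, interpolates the crossing
point on every unique mesh edge that changes sign, and chains the
per-triangle segments into loops keyed by unique-edge identity — no
coordinate rounding, so chaining needs no epsilon tuning. On a
watertight mesh every crossing edge is shared by exactly two crossing
triangles and every chain closes; an open chain raises an error naming
the gap size. Vertices lying exactly on the plane (a measure-zero event)
are handled by nudging the plane 1e-7 mm along its normal and retrying
once. Winding is normalised counter-clockwise viewed from the +normal
side so shoelace areas are positive. Non-watertight inputs are rejected
up front rather than repaired: silent hole-filling would corrupt
centroids, and repair belongs to preprocessing.

## Geometric fits

* **Line (TLS):** cloud mean + leading right-singular vector. Raises if
  the two leading principal values coincide (direction not unique).
* **Cylinder:** Levenberg–Marquardt on `(direction ⊥-offsets, axis-point
  ⊥-offsets, radius)` minimising `Σ(distᵢ − r)²`, initialised at the
  final iteration axis with the mean radial distance as radius. A
  centroid cloud carries no radius information — its radial RMS is a few
  tenths of a millimetre of facet noise — so clouds with radial RMS
  < 0.5 mm skip the optimisation and return the TLS line with the RMS as
  nominal radius. (With surface contour points instead of centroids the
  cylinder is well-posed and `cylinder_source="contours"` exercises that
  path, at the cost of absorbing the neck's taper and ellipticity into a
  circular model.)
* **Sphere:** the linear algebraic system `|p|² = 2c·p + (r² − |c|²)`,
  exact on noiseless spherical caps. The head fit trims residuals with
  an annealed threshold (4× → 2× → 1× `head_trim_mm`) and refits, which
  keeps the centre stable against junction-blend vertices and flattened
  (collapse-like) caps; a geometric orthogonal-distance refinement is
  available as an independent cross-check.

## The synthetic femur

The phantom is an implicit solid, isosurfaced with marching cubes at
`voxel_pitch` (default 0.8 mm), which guarantees watertightness — the
property the slicer depends on. Its parts, in a CT-like frame
(+x lateral, +y anterior, +z superior; all lengths mm):

* **Shaft**: vertical capsule, radius 14, its cap kept 16 mm below the
  neck base so sections perpendicular to the neck clear the medial
  shaft;
* **Neck**: elliptical cone along the axis direction set by the
  neck-shaft angle (130°) and anteversion (15°), radius tapering
  17 → 14 mm over 35 mm, minor/major ratio 0.85; the cone is extrapolated
  16 mm below its base so the intertrochanteric region is solid;
* **Head**: sphere of radius 24 mm whose centre sits past the neck tip
  (at `neck_length + 0.3·head_radius` along the axis) and, optionally,
  a perpendicular offset δ off the axis — δ is then the ground-truth
  DBHF;
* **Trochanter bumps**: two compactly supported quartic bumps
  (`amp·(1−r²/R²)²`, R = 6 mm) raising the greater- and
  lesser-trochanter apices. Compact support matters: a Gaussian tail
  reaches the sliced neck span and drags section centroids off the
  construction axis, which would corrupt the ground truth the tests
  rely on.

Parts are blended with a polynomial smooth-minimum (k = 6 mm, maximum
inflation k/4), so the head–neck junction resembles anatomy and never
pinches to zero thickness. Landmarks are constructive: the bump apices
(root of the implicit field along each bump's outward ray) and the
anterior surface point midway between them; `head_hint` is the head
centre. These stand in for the anatomical definitions as a simulation
convention. Ground truth (axis, head centre, landmarks, head-vertex
tags) is recorded from the construction before meshing.

Stressors: per-vertex Gaussian jitter (`vertex_noise_sigma`) emulates
segmentation/surface noise; `head_flatten_frac` removes a spherical cap
to mimic head collapse and stress the sphere fit. Landmark perturbation
(isotropic Gaussian, default σ 0.5 mm — a simulation choice, as no
observer-variability magnitude is available) emulates observer
variability.

**What the phantom does not capture:** real cortical/trabecular density
structure, osteophytes, true trochanteric shape variation, segmentation
topology errors, or a population shape model. Passing tests therefore
demonstrate correctness of the *algorithm* against exact ground truth
and its qualitative robustness to noise, not clinical accuracy on
patient anatomy.

### Reliability simulation

`simulate_reliability_study` draws cases by jittering the head offset
(sd 1.0 mm — the dominant between-case DBHF variance) and mildly
jittering neck angles, then runs the full pipeline per (case, rater,
repetition) with landmark noise. With between-case variance much larger
than rater noise the estimated ICC(2,1) concentrates near 1, the high-
reliability regime; with rater-independent noise only, it centres on 0.
The simulated studies use `voxel_pitch = 2.5 mm` — the coarsest grid
that still resolves the neck — because a study sweep runs the pipeline
1 500 times; at that pitch the single-fit axis error is ≈ 0.02°, well
below the effects being measured.

## Statistics

ICC(2,1) is computed from the two-way mean squares, which are reported
alongside the estimate for auditability; the 95% CI uses the standard
F-distribution bounds with Satterthwaite degrees of freedom. A table
with zero total variance raises an error rather than returning 1
silently. The two-way ANOVA is delegated to an OLS fit with type-II sums
of squares (appropriate default for the mildly unbalanced cohorts this
serves); exact-zero designs (zero residual or zero effect) are reported
as F = ∞/p = 0 and F = 0/p = 1 respectively instead of NaN. p-values
come from the F-distribution CDF; no permutation option in v1.

## Numerical choices and degenerate inputs

* Degeneracy guards are fixed constants, not knobs: triangle area
  1e-6 mm², unit-norm 1e-9, polygon area 1e-9 mm².
* A truncated section stack (plane leaves the mesh) is an error below
  3 completed sections, a logged warning otherwise.
* Head selection keeps vertices beyond the last section plane by
  `head_axial_margin` (clears the blended junction: at 14 mm the
  selection covers 100% of the tagged head-sphere vertices with ≈ 1%
  off-sphere stragglers, which the trimmed sphere fit removes) and
  below 1.5× the 75th radial percentile; an empty selection ("no head")
  is a hard error.
* The deviated-axis scenario rotates the FNA direction about a
  user-chosen normal (3-D has no canonical "clockwise"); the rotation
  preserves the axis point.
* All coordinates stay in the input frame; the pipeline is rigid-
  equivariant to machine precision, so no re-orientation is ever
  applied.

## Known limitations

* The cylinder radius reported for a centroid-cloud fit is a nominal
  RMS, not the neck radius (use `cylinder_source="contours"` for a
  physical radius).
* Sections that merge neck and trochanter into one contour (very
  proximal cuts on stubby anatomies) bias that section's centroid; the
  iteration's advance usually walks out of them, but extreme landmark
  placements far below the neck base can defeat it.
* The ICC confidence interval assumes the usual normal-theory two-way
  model; heavy-tailed measurement error will distort coverage.
* `fit()` is deterministic; seeds only matter to the synthetic data
  and simulations.
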