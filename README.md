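# femaxis

Fitting the **femoral neck axis (FNA)** of a proximal-femur surface mesh by
the **centroid iterative method**, with the head-centre distance as its
accuracy metric and ICC / two-way ANOVA reliability statistics.

## The problem

Femoral neck rotational osteotomy is a hip-preservation procedure for
early femoral-head necrosis: the neck is cut at its base and the head is
rotated about the neck axis so the necrotic region leaves the
weight-bearing zone. The rotation axis — the FNA — must be determined
precisely from the pre-operative CT reconstruction; a mis-determined axis
changes anteversion and neck-shaft angle after rotation and concentrates
stress at the osteotomy surface. This package implements an automatic,
rigid-motion-equivariant FNA fit for triangulated proximal-femur surfaces
(STL/PLY, mm units), for surgical-planning and biomechanics workflows.

## The method

Let the three anatomical landmarks be the greater-trochanter tip, the
lesser-trochanter tip and the midpoint of the intertrochanteric line.

1. The plane through the three landmarks is the **initial section**.
2. **10 parallel sections** at **1 mm** spacing are taken from it along
   the neck (toward the head).
3. Each section's closed mesh–plane contour gets an area-weighted
   (shoelace) **polygon centroid**:
   `A = ½ Σ (xᵢ y₍ᵢ₊₁₎ − x₍ᵢ₊₁₎ yᵢ)`,
   `Cx = (1/6A) Σ (xᵢ + x₍ᵢ₊₁₎)(xᵢ y₍ᵢ₊₁₎ − x₍ᵢ₊₁₎ yᵢ)` (likewise `Cy`).
4. A **total-least-squares line** through the 10 centroids (principal
   direction of the centred cloud) gives a new axis; the sections are
   rebuilt perpendicular to it.
5. After **5 iterations**, a cylinder is fitted to the final centroid
   cloud; its axis is the FNA. (A centroid cloud is nearly collinear, so
   the cylinder fit falls back to the TLS line whenever the radial RMS is
   below 0.5 mm — the axis, the only quantity used downstream, is
   unchanged by the fallback.)
6. The femoral head is fitted as a **sphere** (algebraic least squares
   with robust residual trimming). Under the mechanical-equilibrium
   assumption the ideal head centre lies on the neck axis, so the
   **distance between head centre and FNA (DBHF, mm)** measures the
   fitting accuracy.

Reliability of repeated measurements is quantified by **ICC(2,1)**
(two-way random effects, absolute agreement, single measure)

```
ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)
```

with 95% CI from the F-distribution, and cohort effects (gender × side)
by a **two-way ANOVA** with type-II sums of squares.

Because patient CT data cannot ship with the package, a **synthetic
femur generator** builds watertight proximal-femur phantoms (implicit
smooth union of shaft, tapered elliptical neck, head sphere and two
trochanter bumps, isosurfaced by marching cubes) with *exactly known*
neck axis, head centre, head offset, landmarks, surface noise and
head-collapse flattening — so every claim is testable against ground
truth.

## Worked example

```python
from femaxis import FemoralNeckAxisModel, FemurSpec, generate_femur

# phantom whose head centre is built 2 mm off the neck axis
mesh, truth = generate_femur(FemurSpec(head_offset=2.0))
results = FemoralNeckAxisModel(mesh, truth.landmarks).fit()
print(results.summary())
```

```
Femoral neck axis fit (centroid iterative method)
======================================================
sections per stack     : 10 @ 1 mm
iterations             : 5 (requested 5)
FNA point [mm]         : (-4.385,  1.175,  3.809)
FNA direction          : (-0.7399,  0.1983,  0.6428)
cylinder radius [mm]   :  0.000
head centre [mm]       : (-29.946,  8.025,  28.603)
head radius [mm]       :  24.028  (14605 vertices)
DBHF [mm]              :  1.982
successive axis angles : 3.223, 0.049, 0.001, 0.003 deg
```

The fitted axis is within 0.002° of the construction axis; the DBHF of
1.98 mm recovers the built-in 2 mm head offset (an on-axis phantom gives
DBHF ≈ 0.002 mm). The successive-axis angles show the iteration
converging after the second pass; `results.plot_convergence()` plots
them. The near-zero cylinder radius indicates the collinear-cloud
fallback: the centroids lie on a line, as they should.

The same pipeline runs from the shell:

```bash
fna synth --head-offset 2 -o femur.stl --truth truth.json --landmarks lm.json
fna fit femur.stl --landmarks lm.json -o fit.json
fna eval fit.json truth.json
fna stats icc table.csv
fna stats anova cohort.csv
```

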