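# Methods

## Model and assumptions

The quantity computed is a *radial* measure of acetabular bone loss. Both
surfaces — deficient and reconstructed — are treated as unoriented triangle
soups in a common millimeter frame; the method assumes the reconstruction
is a plausible "what the bone should look like" overlay of the deficient
bone, and that the joint center of the reconstruction is a meaningful
origin for radial probing. Bone presence is judged purely by whether a ray
from that center intersects each surface, and by the distance between the
two first entry points. The measure is therefore insensitive to thin
residual bone layers beyond the first intersection (deliberately so: a
thin shell provides no structural support), and it cannot see tangential
or closest-point distances — only radial ones.

### Coordinate frame

- Joint center: least-squares sphere on the user-outlined acetabular
  region of the reconstructed mesh. An algebraic (linear) fit initializes
  a geometric Gauss–Newton refinement of Σ(|p−c|−r)²; the geometric stage
  makes the fit unbiased under anisotropic sampling of the cup.
- Acetabular axis `n`: total-least-squares plane through the rim outline;
  the plane normal carries no sign, so `n` is oriented laterally using the
  direction from the ASIS midpoint to the sphere center projected on the
  normal — a midline proxy that is always available from the required
  landmarks.
- Anteroposterior axis: from the pelvic landmarks, ISB-style. The
  mediolateral axis runs from left to right ASIS; the anterior axis is the
  in-plane (ASIS–ASIS–pubis plane) direction orthogonal to it, toward the
  pubis; the superior axis completes the right-handed triad. The anterior
  axis is projected into the rim plane (`ap_axis`); construction fails if
  it lies within 1° of `n`. The in-plane superior reference is
  `n × ap_axis`, sign-flipped for a left hip; if that disagrees with the
  projected ISB superior axis (side flag inconsistent with geometry), a
  warning is recorded rather than an error.

### Ray grid and deviation

Directions `d(φ,θ) = −cos φ·n + sin φ(cos θ·ap + sin θ·sup)` with φ
sampled uniformly and closed on [0, π] (poles retained for grid
regularity) and θ uniform, half-open on [−π, π) so the antipodal column is
not duplicated. Default sampling is the fixed 100 × 100 grid used for
inter-case comparability.

The first entry point is the smallest intersection parameter t > 1e-6 mm,
irrespective of triangle orientation; hits duplicated on shared edges or
vertices collapse under the minimum. If more than 1 % of rays first hit a
surface within that guard distance, the origin likely lies on the surface
and a warning is attached to the result. Rays where the deficient bone
lies beyond the reconstruction (protrusion/overgrowth) keep their unsigned
deviation, and deficient-only hits count toward A_def: the deficient
surface may legitimately grow outside the reconstructed outline.

All rays of an analysis share one origin, so the Möller–Trumbore scalar
triple products that do not involve the ray direction are precomputed per
triangle, reducing a block of rays to three matrix products plus
elementwise tests. This replaces a spatial acceleration structure; the
contract is that results are *identical* to an exhaustive per-ray loop,
which the test suite enforces ray-for-ray against an independently written
brute-force implementation (`trabl.oracle`).

### Planar areas, regions and the ratio

Areas are measured on the azimuthal equidistant projection (`r = r_u·φ`) —
the same distorted planar metric in which the color graph is drawn — not
on the sphere; a spherical-metric variant is available behind the
`metric="spherical"` switch but is never the default. Discrete areas sum
per-cell shoelace areas of the projected quadrilaterals (the azimuth is
periodic, so the last column closes the seam against the first) weighted
by masked-corners/4. The fractional rule converges to the continuous area
without boundary bias; the stricter all-corner membership rule is kept as
an option for sensitivity checks and is what the independent oracle uses.

Each *cell* is assigned to exactly one region by evaluating the label at
the cell centroid, so the six region areas partition the global area
exactly (a point-wise all-corner region filter cannot partition, because
boundary cells straddle two labels). Point labels: medial cap where
sin φ ≤ 1/2 on the medial branch φ ≤ π/2 (both boundaries inclusive); the
five 72° sectors are keyed by the in-plane angle ψ measured from `ap_axis`
toward `sup_axis`, with the anterior direction as the AntSup/AntInf
boundary — the exact angular offset of the sector fan is a convention and
is configurable (`sector_offset_deg`). The lateral cap (φ near π) keeps
sector labels. The ratio is not clamped: A_def > A_rec yields a negative
ratio, reported as computed with a warning; a region with A_rec = 0 is
flagged not assessable instead of dividing by zero.

## Phantoms

The phantom generator emulates the defect typology seen in deficient
acetabula — uncontained wedges, medial perforation, cavity erosion, and
the detached "needle-head" strip that healthy anatomy produces when rays
slip through the obturator foramen and re-detect the pubic ramus. It does
*not* emulate realistic pelvic shape, segmentation noise, metal artifact,
or reconstruction error; passing phantom tests therefore validates the
geometry pipeline, not the clinical preprocessing chain.

A phantom is a hemispherical cup shell (inner radius 24 mm — a typical
adult acetabulum — wall 5 mm) closed by a rim annulus, tessellated on a
structured latitude/longitude grid (level L: 6L × 24L per surface; default
L = 2, ≈ 2300 faces per mesh). The structured tessellation was chosen over
icosphere subdivision so the rim circle and angular defect windows fall
exactly on mesh edges, making analytic loss fractions exact. Defects are
face deletions (wedge, cap hole) or radial vertex displacement (erosion);
deletion rather than boolean CSG leaves no cut walls, so radial rays see
exactly the analytic angular fractions. Landmarks are placed so the
derived frame is axis-aligned with the construction frame; an optional
rigid rotation moves the whole case for invariance testing.

The shipped wedge fixture spans azimuth 45°–135°: endpoints lie on mesh
column edges (clean cut) and midway between 100 × 100 grid meridians,
where fractional corner weighting integrates the cut without bias and no
ray grazes the cut plane exactly. The shipped perforation uses a hole of
φ < π/4 that engulfs the whole medial cap; a hole boundary coinciding
exactly with the Med region boundary (φ = π/6) makes the coarse-grid
medial ratio depend on how half-covered boundary cells are counted — that
configuration is exercised against the dense oracle in the tests instead
of being a comparison fixture. A "total loss" phantom pairs the cup with
an explicitly empty deficient mesh (every deviation infinite, ratio
100 %). Phantom generation is deterministic: a fixed seed yields
byte-identical meshes.

## Verification strategy

Two fully independent routes compute every fixture's ratios: the pipeline
(fast shared-origin casting, fractional areas, 100 × 100) and
`trabl.oracle` (textbook per-ray Möller–Trumbore over all triangles,
all-corner areas, label logic re-derived, 400 × 400). They agree within
1.3 percentage points on all six fixtures, globally and per region, and
the analytic expectations recorded in each preset's ground-truth record
bound both. Problem sizes were chosen to keep a full verification run at
roughly ten minutes on one CPU: tessellation level 2 keeps the faceting
sagitta below 0.06 mm at the 24 mm cavity radius, well under every
distance tolerance used.

## Numerical choices

- Vertex merge tolerance 1e-6 mm; zero-area face threshold 1e-12 mm²
  (arbitrary small constants; STL float32 round-trips preserve
  coordinates to ≤ 1e-5 mm).
- Self-hit guard ε = 1e-6 mm on the ray parameter; ray–triangle barycentric
  tolerances are scaled by the determinant so edge and vertex hits are
  inclusive at any mesh scale.
- Sphere fit convergence `xtol` 1e-12 via Levenberg–Marquardt with
  analytic Jacobian; degeneracy (coplanarity/collinearity) is tested on
  singular values relative to the largest.
- Med and sector boundaries inclusive as stated; the azimuth modulus is
  guarded against the floating-point `mod` landing exactly on 360°.
- Color ramp: linear-in-distance green→yellow→orange→dark-red between
  0 and 10 mm, clamped above; grey for rays without deficient-bone
  support, base blue for deficient-only hits.

## Known limitations

- Radial-only: bone behind the first intersection, tangential defects and
  volumetric loss are invisible by construction.
- Areas are compared in the distorted planar metric; ratios therefore
  weight medial directions slightly differently than spherical areas
  would (the opt-in spherical metric quantifies the difference).
- The rim outline and landmarks are inputs; their placement variability
  propagates directly into the axis, the region layout and the ratios.
- If a ray crosses the reconstructed shell more than once before reaching
  deficient bone, only the first crossing of each mesh is used.
- The reference cohort ships as published ratios only; per-specimen meshes
  are not available, so cohort-level numbers are recomputed from the
  table, not from geometry.
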