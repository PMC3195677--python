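# trabl — total radial acetabular bone-loss quantification

`trabl` quantifies how much acetabular bone stock a deficient hemipelvis
has lost, relative to an anatomical reconstruction of the same bone. It is
aimed at 3D surgical planning for complex (revision) hip arthroplasty,
where qualitative defect gradings such as the Paprosky classes suffer from
poor inter-observer reliability: the package turns two surface meshes into
an objective percentage and a planar color map that can be compared across
patients and time points.

## Method

Inputs are two triangle meshes in the same millimeter coordinate frame —
the **deficient** bone (segmented from CT) and the **reconstructed** bone
(from contralateral mirroring or a statistical shape model; producing it is
outside this package's scope) — plus a small JSON case file giving the
user-outlined acetabular rim, the acetabular-region points for sphere
fitting, the pelvic landmarks (both anterior superior iliac spines and a
pubis point) and the side.

1. A least-squares sphere fitted to the reconstructed acetabular region
   locates the joint center; a total-least-squares plane through the rim
   outline defines the **acetabular axis** `n` (rim-plane normal through
   the sphere center, pointing laterally).
2. Radial rays are cast from the joint center on a uniform spherical grid:
   polar angle `φ ∈ [0, π]` from the inward axis `−n`, azimuth
   `θ ∈ [−π, π)` from the anteroposterior axis, 100 × 100 samples by
   default, on a unit sphere `r_u = 1 mm`.
3. Each ray records its first entry point into either mesh. The Euclidean
   distance between the two entry points measures the severity of bone
   loss along that ray; a ray that misses the deficient bone entirely has
   an infinite deviation — the defect is uncontained in that direction.
4. The spherical grid is unfolded by the azimuthal equidistant projection
   (`r = r_u·φ`, `x = r·cos θ`, `y = r·sin θ`) and the planar areas
   enclosed by the hit points of each mesh are compared:

   **ratio = (1 − A_def / A_rec) · 100 %**

   evaluated globally and in six anatomical subregions: a medial cap (all
   unit-sphere points within half the unit radius of the acetabular axis)
   and five 72° sectors around the projected anteroposterior axis
   (PostInf, Inf, AntInf, AntSup, PostSup).

Since no patient meshes can ship with the package, a phantom module
generates hemispherical-cup pairs with exactly known defects (wedge,
medial perforation, erosion, detached "needle-head" band), and a packaged
twelve-specimen reference table feeds the cohort-summary stage.

## Worked example

```sh
trabl phantom --preset wedge25 --out fx      # synthetic case with a known
                                             # quarter-turn full-thickness wedge
trabl run --deficient fx/deficient.stl --reconstructed fx/reconstructed.stl \
          --case fx/case.json --out out
```

prints

```
global ratio: 25.0%
   PostInf: 0.0%
       Inf: 0.0%
    AntInf: 0.0%
    AntSup: 37.5%
   PostSup: 87.5%
       Med: 25.0%
```

The wedge spans the azimuth range 45°–135°, i.e. a quarter of every
azimuthal circle: globally a quarter of the reconstructed area has no
radial bony support (25 %). The wedge covers 27° of the 72° AntSup sector
(37.5 %) and 63° of PostSup (87.5 %); the medial cap loses the same
quarter of its azimuth. `out/` also contains the per-ray deviation grid
(`deviation_grid.csv`), the color graph (green = 0 mm deviation, dark red
= 10 mm or more, grey = no radial support), a radar plot of the sector
ratios and a JSON run log with the fitted sphere and axes.

Cohort summaries over a table of per-region ratios:

```sh
trabl summarize --thresholds 15,25,50 --out summ
```

which, on the packaged reference cohort of twelve highly deficient
hemipelves, reports posterosuperior loss as the most frequent at every
threshold and five specimens with at least three regions above 25 %.

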