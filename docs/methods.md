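# Methods

## Coordinate conventions and units

All physical quantities are millimetres (lengths), mm² (areas) and
Hounsfield units (intensities). The anatomical frame is `x` mediolateral,
`y` anteroposterior, `z` superoinferior with +z superior; coronal slices
are constant-`y` planes. A voxel's world position is `index × spacing`
(no origin offset); STL is unit-less, and this package fixes mm throughout.

## Phantom model

The phantom emulates the imaging input of the clinical problem: a thin bone
lamella (the orbital floor) separating orbital soft tissue (above, default
40 HU) from the air-filled maxillary sinus (below, −1000 HU), pierced by a
defect. Three floor geometries are supported:

* **flat** — horizontal plane;
* **tilted_plane** — rotated by `tilt_deg` about the mediolateral axis; the
  defect is an ellipse (semi-axes `a`, `b`) in the floor's intrinsic plane,
  removed perpendicular to the floor, so the intrinsic removed area is
  exactly π·a·b while the axial footprint shrinks by cos(tilt);
* **spherical_cap** — the lower cap of a sphere of radius `R`; a vertical
  cylindrical defect of base radius `a` removes a cap of area 2πRh with
  h = R − √(R² − a²). Only circular defects are supported on spheres: an
  oblique ellipse on a sphere has no closed-form area, and an analytic
  ground truth is the whole point of the phantom.

The bone shell occupies signed distance [−t, 0] *below* the analytic
surface (`t` = shell thickness, default 1 mm), so the superior shell face —
the surface the 3D measurement operates on — coincides exactly with the
analytic surface carrying the ground-truth rim and area. Herniation bumps
and trap-door flaps are deliberately not modelled; a clean removal keeps
the truth closed-form.

Defaults are chosen as realistic study conditions: bone 1200 HU, tissue
40 HU, air −1000 HU; voxel spacing (0.4, 0.75, 0.4) mm so the coronal slice
thickness along `y` is the clinical 0.75 mm; volume extent
(40, 40, 32) mm; noise off for unit tests and Gaussian σ = 25 HU (seeded)
for cohort runs — at a 300 HU bone threshold this leaves the segmentation
unambiguous, which matches the clean bone windows the clinical workflow
starts from. The defect centre snaps to the coronal slice grid, so
phantom geometry is symmetric about a slice plane.

Cohort sampling draws floor kind (flat / tilted / cap, equal weights by
default), a target true area uniform on [60, 620] mm² (the observed
clinical spread of defect areas, tens to ~650 mm²), tilt uniform on
[5°, 45°], cap radius uniform on [15, 30] mm, and planar aspect ratio b/a
on [0.8, 1.25]; geometry that does not fit the volume is redrawn. All
sampling is deterministic under the seed.

## 2D measurement

`area_2d` evaluates A = n·d·(Σl/n) = d·Σl exactly. `slice_widths` produces
the per-slice `l` values from a defect rim loop: coronal slice `k` images
the plane y = k·d, and the width on it is the mediolateral chord of the
rim at that plane, computed from exact polygon/plane crossings with the
half-open scanline rule (y_lo ≤ y_k < y_hi).

This *centre-plane chord* convention was chosen over counting every slab
that geometrically intersects the defect because (i) it makes the
estimator exact for an axis-aligned rectangular defect whose length is a
multiple of d — the natural calibration case for a Riemann-sum formula —
and (ii) it reproduces the analytic chord 2√(r² − y²) per slice for
circular defects. A defect thinner than one slice spacing that straddles
no plane is assigned its full extent on the single nearest slice,
mirroring the fact that any visible defect appears in at least one image.
Widths are single max-extent rulers per slice (not sums of disjoint
segments), matching the manual ruler protocol; multi-fragment slices would
therefore over-count gaps.

In the paired pipeline the 2D route reads chords off the *analytic*
ground-truth rim — an idealized examiner reading the original images with
zero reader error (inter-rater noise can be simulated by seeded jitter on
the widths). Reading chords off the detected mesh rim instead is possible
(`slice_widths` accepts any boundary) but carries a mesh-specific artifact:
at high tilt the oblique defect-channel wall projects into the axial
footprint and biases the footprint, which is a property of the surface
model, not of the 2D formula being studied.

## 3D measurement

1. **Segmentation** — global threshold at 300 HU (the software threshold
   used clinically is vendor-dependent and unreported; 300 HU separates
   cortical bone from soft tissue with wide margin) and largest connected
   component (26-connectivity, preserving thin oblique shells; size ties
   break to the component with the lowest raster-order voxel).
2. **Surface model** — marching cubes at level 0.5 of the binary mask,
   one-voxel zero pad so boundary-touching bone closes, vertices scaled to
   mm, duplicate vertices merged, degenerate faces dropped. No smoothing.
3. **Rim detection** — superior-facing vertices (outward normal n_z > 0.1,
   i.e. local slope below ~84°) are binned onto an axial occupancy grid
   (cell 0.75 mm, morphological closing to remove sampling gaps); the
   defect is the connected empty region at the hint point, its 0.5-level
   contour is the rim footprint. Two corrections matter: mesh normals are
   oriented outward via the signed volume (marching-cubes winding is not
   guaranteed), and each contour point is pushed half a cell outward along
   its local normal, because the 0.5-contour of a binary occupancy grid
   sits half a cell inside the true edge in expectation (without this the
   measured areas are ~2·(g/2)/r low — about 7% for a 10 mm defect).
   Footprint points are lifted to 3D by local least-squares planes through
   the 10 nearest superior vertices, then ordered by angle about the
   centroid in the loop's own best-fit plane.
4. **Polynomial patch** — local frame from a PCA of the rim alone (w-axis
   = smallest-variance direction, sign superior, lexicographic
   tie-break); least-squares fit of w = Σ_{i+j≤deg} c_ij u^i v^j over the
   rim plus superior vertices in a band outside the rim. Degree defaults
   to 2: it captures floor concavity without oscillating through rim
   noise; degrees 1–4 are available. Consistent rank-deficient designs
   (e.g. an exactly circular planar rim under degree 2) take the
   minimum-norm solution, which for planar data *is* the plane; only
   collinear-in-projection geometry is rejected.
5. **Area integration** — the rim's projection onto the fit plane is
   triangulated (Delaunay over the polygon vertices plus an interior
   Steiner grid at 0.25 mm), each triangle lifted onto the patch, 3D areas
   summed. This discretizes ∫∫ √(1 + w_u² + w_v²) du dv and converges as
   the grid shrinks; at 0.25 mm the discretization error is far below the
   geometric error terms.

**Support band width.** The band defaults to 1.5 mm, set by two opposing
error terms measured on the spherical-cap benchmark (R = 20, a = 10): a
degree-2 patch fit supported only near the rim extrapolates into the
unsupported footprint interior, and this bias grows with band width
(+0.9% area at 1 mm, +1.55% at 3 mm on ideal noise-free samples), while
very narrow bands amplify rim-detection noise on real meshes (measured
+2.6% at 1.0 mm vs +1.7% at 1.5 mm through the full pipeline). The
degree-2 extrapolation also has an irreducible height-deviation floor of
~0.25–0.3 mm at the footprint centre for this geometry (degree 4 reaches
~0.06 mm); the integrated area, which depends on the fitted gradients
rather than the offset, stays within 2% of 2πRh.

## Paired statistics

Per cohort the package reports mean (MV), median (MED), sample SD (n−1),
min and max for the 2D areas, 3D areas and per-case fold ratios
a3D/a2D — the mean of per-case folds is reported separately from the ratio
of mean areas, which is a different quantity. Larger/smaller/tie counts
use an absolute tie tolerance of 1e-9 mm².

The default test is the two-sided Wilcoxon signed-rank test, the standard
nonparametric paired comparison (a literally "paired Mann–Whitney U" is a
contradiction in terms — the MWU is unpaired — so the signed-rank test is
the faithful reading of a paired design, and an unpaired MWU remains
available behind a flag). Zero differences are discarded; |differences|
are midranked; W = min(W+, W−). For n ≤ 25 the p-value is exact: the null
distribution of W+ over all 2^n sign assignments is built by dynamic
programming on doubled midranks (identical to literal enumeration, which
the tests use as an oracle up to n = 10, alongside a scipy cross-check);
beyond that a normal approximation with tie and continuity corrections is
used, which agrees with the exact p within 0.02 by n = 20.

## What the phantoms do and do not show

Passing tests demonstrate that the 2D estimator converges to the axial
footprint (hence the cos θ underestimation law), that the 3D pipeline
recovers analytically known areas within a few percent at clinical voxel
sizes (median ~1% over a mixed 50-phantom cohort), and that on a
177-case synthetic cohort the 3D measurement exceeds the 2D estimate in
the majority of cases with a signed-rank p far below 0.001 — the
directional clinical finding. They do **not** show that the absolute
clinical cohort summaries are reproduced: real fractures have irregular
comminuted rims, herniated soft tissue, partial-volume blur and human
rim-marking variability, none of which the clean-removal phantom models.
Synthetic fold ratios (mean ≈ 1.06–1.09 under the default geometry mix)
are accordingly smaller than the clinical 1.53.

## Problem sizes and runtime choices

Default phantoms are 100×53×80 voxel grids (~0.4 M voxels, ~0.2 s per
case end-to-end). The recovery benchmark uses 50 phantoms and the
directional replication 177 (matching the clinical cohort size); both are
the sizes reported by `scripts/acceptance.py`. The rotation-isometry check
runs at 0.25/0.4/0.25 mm spacing, where the flat-vs-rotated discrepancy is
0.6–1.0% (1.6% at default spacing), limited by the fixed-size rim-search
grid.

## Known limitations

* Rim detection assumes a roughly star-shaped single aperture on a
  surface that is nowhere steeper than ~84°; fragmented multi-hole
  defects are out of scope.
* The 2D width is the straight mediolateral chord; measuring the oblique
  in-plane trace of a tilted floor within the coronal image would give a
  different (larger) width and is not implemented.
* The spherical-cap ground truth requires circular defects.
* Areas are measured on the superior shell face; measuring the inferior
  face would differ by O(t/R) on curved floors.
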