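# Methods

This note documents the models, conventions, parameters and numerical
choices behind `scutoid3d`, and what the synthetic phantoms do and do not
establish about real imaging data.

## Coordinate and data conventions

Volumes are integer arrays in (z, y, x) order with physical voxel spacing
(dz, dy, dx) in µm, stored per volume (confocal stacks are routinely
anisotropic). z index 0 is the slice closest to the objective; "apical"
always refers to the surface first encountered scanning down z. Labels
are positive integers, 0 is background, and no operation ever relabels:
scutoid calls, morphometrics and event tracking are invariant under any
permutation of label ids (tested). Voxel membership in generated
geometry is decided by the voxel-centre physical coordinate, the same
convention used by the Voronoi tiling, so generator and null model agree
exactly.

## Scutoid detection

Layer maps come from directional scans: per (y, x) column, the first
labelled voxel from the top is the apical surface, from the bottom the
basal surface (depths recorded as heightfields). Neighbour sets on each
2D map are computed by dilating each cell's footprint and recording the
labels the dilation overlaps, then symmetrizing by union. The
structuring element is the Chebyshev disk (a (2r+1)² square): at the
default radius 1 it is 8-connected, so corner-only contact counts as
neighbourhood — a stated, testable convention. Label maps from
segmentation are gap-free, so radius 1 finds all contacts; the radius is
config-exposed for maps with thin gaps.

A cell is scutoidal iff its apical and basal neighbour sets differ as
sets. Two truncation guards keep this honest at image edges:

- cells whose apical or basal footprint touches the image boundary are
  border-flagged;
- cells missing from one surface map altogether (their footprint on that
  surface lies outside the cropped field of view) are border-flagged as
  the limiting case — otherwise a cropped cell would masquerade as a
  scutoid via an empty neighbour set.

Under the default `border_policy="exclude"`, flagged cells leave both
numerator and denominator of the scutoid proportion. The policy is
config-switchable because truncated neighbour sets otherwise inflate
scutoid counts.

The analysis band selects cells whose centroid lies within `band_depth`
(default 30 µm, the typical depth of good confocal signal) of the apical
heightfield at the centroid's column, measured along z. Measuring along
the objective axis rather than 3D distance-to-mesh matches how imaging
depth degrades; for shallow caps the difference is second order.

`transition_depth` localizes an AB-T1 along z by recomputing the 2D
adjacency pattern of the four involved cells per slice and returning the
normalized index of the first slice whose pattern differs from the
apical one. Cells with more than two distinct configurations along z are
out of scope (scutoid state is binary apical-vs-basal).

## Morphometrics

- **Volume**: voxel count × dx·dy·dz; conservation (Σ cells + background
  = grid) is exact in integer voxel counts.
- **Convexity**: cell volume over the volume of the convex hull of the
  *corners* of the cell's voxels (only boundary-voxel corners are fed to
  the hull). Corner hulls contain the voxel union, so the ratio never
  exceeds 1 and axis-aligned cuboids score exactly 1. A consequence of
  the corner convention is a resolution-dependent floor for curved
  bodies: a digitized ball of radius r voxels scores ≈ (r/(r+½))³
  (0.86 at r = 10), approaching 1 only as resolution grows. Comparisons
  should therefore be made at matched resolution. Corner sets are never
  coplanar, so no degenerate-hull case arises.
- **Height**: Euclidean distance between the centroids of a cell's
  apical-surface and basal-surface pixels (at their depths). For tilted
  cells the scan surfaces include side-wall ramp pixels, which bias the
  estimate low by roughly drift/width; at monolayer-typical tilts this
  is ≲ 10%.
- **Density**: selected cells divided by the basal area they occupy.
  Basal area is the basal-layer pixel area corrected per pixel by the
  heightfield slope factor √(1 + (∂z/∂x)² + (∂z/∂y)²) (gradients of
  physical height; pixels whose stencil crosses an undefined pixel fall
  back to factor 1). The *selected* set is used rather than the
  border-excluded set so the covered region is the stable full footprint
  across stages.
- **Openings**: enclosed background components of the full z-projection
  of the labels. Enclosure (flood-fill) rather than a convex-hull test
  avoids reporting the 1–3 px slivers between a digitized round
  footprint and its hull as openings. `min_opening_area` (default 0,
  i.e. report everything enclosed) is a documented config choice, not a
  value inferred from data.

## Tissue geometry

Apical and basal surface pixel clouds (subsampled to ≤ 20k points) are
fitted with general rotated ellipsoids by algebraic least squares
(xᵀMx + bᵀx = 1 solved by `lstsq` after centring/scaling for
conditioning; non-positive-definite solutions are rejected as fit
errors). Principal curvatures at a point (radially projected onto the
fitted surface) are the tangential eigenvalues of the shape operator
P H P / |∇F| of the implicit quadric — exact for the fitted surface, and
matching the closed-form spheroid values (c/a² at poles; a/c² and 1/a at
the equator) to 1e-6 on noiseless fits.

Surface ratio anisotropy: at each selected cell centroid, per-surface
principal curvatures give radii R = 1/k, classed per point into h (axis
of greater curvature) and w (axis of lesser curvature). Radii are
averaged per surface and class, then ratioed: SR_h = R̄_a,h/R̄_b,h,
SR_w = R̄_a,w/R̄_b,w, and sra = |SR_h − SR_w|. The absolute value makes
sra ≥ 0 with 0 for isotropic curvature (concentric spheres) — note that
*similar* surfaces (one a uniform scaling of the other) also give 0 even
when each is anisotropic, since both ratios equal the scale factor.
Whether radii are averaged before or after the ratio is config-switchable
(`radii_average_order`) for sensitivity checks; the default averages
radii first.

Tissue surface ratio integrates each depth heightfield as a triangulated
surface (two triangles per fully-defined pixel quad). When a label set is
supplied, both integrals are restricted to those cells' footprints so the
two surfaces cover the same tissue (same solid angle); comparing the same
*image region* instead would bias the ratio below 1 for curved shells,
because the basal surface of a smaller sphere is steeper over a fixed
lateral window. The pipeline passes the counted cell set.

Embryo axes fit an ellipsoid to the outer surface voxels of the full
foreground; lengths are twice the semi-axes, aspect ratio is
longest/shortest and major-axes ratio longest/second-longest.

## Voronoi null model

The construction re-tiles the observed frame's own mask by proximity to
its own 3D cell centroids, in physical distance with anisotropic spacing,
ties broken to the lowest label (deterministic, no RNG). The assignment
is computed as an explicit chunked argmin over per-axis squared
differences so it is bit-identical to a per-voxel brute-force oracle,
ties included; a k-d tree was deliberately avoided because its
tie-breaking is unspecified. Seeds falling in mask holes are kept
unprojected. The construction is then measured by the byte-identical
layer-extraction, band-selection (recomputed by default;
`recompute_band_on_voronoi=False` reuses the observed selection) and
detection path, so the observed-minus-null excess is attributable to
geometry-independent causes only.

Re-tiling a construction from the *centroids of its own regions* is a
Lloyd relaxation step and does not reproduce the diagram (measured
excursions of a few percent in the proportion); idempotence — excess
exactly 0 — holds when a construction is rebuilt from its *defining
seeds*, which `VoronoiConstruction` carries and `null_comparison`
accepts. This also serves as an end-to-end check that both measurement
paths are identical code.

## Event timing

Interphase bounds (end of cytokinesis to mitotic rounding) are inputs —
from the division simulator or a user track table; detecting them from
images is out of scope. Within each cell's interphase, frames with the
scutoid flag are grouped into contiguous runs; onset is the first frame
of a run, end the last. Multiple runs in one interphase are anomalous
and are all reported with a flag, never merged. Onset is normalized by
interphase length; duration counts frames inclusively ((end − onset + 1)
/ length), so a single-frame scutoid has nonzero duration — at the cost
of a one-frame term that breaks exact invariance of the duration under
frame-clock rescaling (the onset is exactly invariant). A run reaching
the end of the interphase is marked censored rather than silently
treated as resolved. Classification uses a strict threshold: onsets
strictly below 15% of interphase count as "after mitosis"; the boundary
value is mitosis-independent.

The developmental clock takes a division log (cell, stage, time);
relative time 0/1 are the first divisions of the reference early/late
stages (defaults "64-cell" and "512-cell"). A stage's mitotic wave runs
from its first division until at least 50% of its cells have divided
(the ⌈n/2⌉-th division); the remainder, until the first division of the
next stage, is its interphase period.

## The phantom generator

The main phantom emulates the imaged patch of a spheroidal blastula-like
epithelium. Geometry: an ellipsoidal shell (defaults: outer semi-axes
80 µm, inner 55 µm — a 25 µm monolayer), restricted to the view around
the objective-facing pole by a z-cut at the equator plus a vertical
cylinder of radius inner·sin(cap_angle) (default cap_angle 1.1 rad).
Both cuts are parallel or perpendicular to the scan axis, so the z-scans
always see the outer/inner surfaces of the near monolayer and never a
cut face, exactly as in a laterally cropped confocal stack; cells cut by
the crop touch the image boundary and are border-flagged downstream.

Cells are Voronoi regions of seeds on the mid-surface ellipsoid: a
golden-angle spiral lattice (quasi-uniform, deterministic) plus Gaussian
jitter (default 1 µm) re-projected onto the mid-surface. The jitter is
deliberately tangential: cell centres of a monolayer lie in its
mid-plane, and an off-surface radial offset would tilt Voronoi walls
through the whole shell thickness — a far stronger, unphysical
perturbation that drives the scutoid fraction to ~1 and strips cells of
their apical footprints.

Default cell numbers (~150 per patch, i.e. a few hundred per
hemisphere) and the division series starting at 48 patch cells and
doubling three times span the densities of cleavage-to-blastula stages.
With ~9–15 µm wide, 25 µm tall cells on a curved shell, proximity
tilings are strongly scutoidal (proportions 0.4–0.9); the phantoms are
therefore suited to *relative* and *directional* statements (density
doubling, compression raising the proportion, observed-vs-null
comparisons), not to reproducing absolute scutoid frequencies of any
particular tissue.

`compression < 1` squashes one *lateral* semi-axis, making the embryo an
oblate spheroid whose short axis is perpendicular to the viewing axis.
This choice reproduces, in a purely static tiling, the two measurable
signatures of a mechanically confined embryo's imaged region: higher
curvature anisotropy and higher areal density at matched cell count.
Squashing along the viewing axis instead only flattens the imaged pole
patch and lowers both (verified on generated instances), so it cannot
serve as the compressed condition for a geometric model.

The division simulator replaces each dividing seed with two daughters
offset ±displacement/2 along a random mid-surface tangent (then
re-projected), regenerating the tiling on the static shell; divisions
are in-plane, as oriented divisions in a lateral-expanding monolayer.
The event table records parentage and interphase bounds. The default
displacement (6 µm) is roughly half a cell diameter at the default
density; daughters' summed volume stays within ~15% of the parent for
displacements well below the local cell diameter and drifts above that
as the offset grows.

What the phantoms do *not* emulate: membrane-tension mechanics (they are
geometric, not biophysical — no vertex model), segmentation errors,
anisotropic point-spread blur, cell-size variability beyond Voronoi
irregularity, and temporal drift between divisions (frames between waves
are static). Passing tests on phantoms therefore validates the
measurement machinery and its conventions, not biological effect sizes.

## Problem sizes and runtime choices

Tests and the acceptance script run phantoms at 2 µm voxels (1 µm where
discretization matters, e.g. the isotropy check, whose sra discretization
floor is ~0.04 at 2 µm but ~0.01 at 1 µm), patches of 24–384 cells, 20
random 32³ tiling instances against the exhaustive oracle, and 10
generator seeds for the stochastic directional comparisons. These sizes
were chosen to keep the whole suite in tens of seconds while leaving each
property's signal far above its tolerance.

## Known limitations

- Scutoid calls are binary apical-vs-basal; multi-transition cells along
  z are not subdivided.
- The ellipsoid model is global per surface; local curvature estimation
  (mesh-based differential geometry) is out of scope.
- Cell height and convexity carry the scan-surface and corner-hull
  discretization biases quantified above.
- Tracking assumes persistent label ids (as produced by the simulator or
  an upstream tracker). For untracked inputs a greedy nearest-centroid
  matcher (`dynamics.nearest_centroid_tracks`) is provided; it is
  adequate for slowly moving epithelia between divisions but performs no
  global assignment optimization and does not resolve lineage at
  divisions beyond opening a new track for one daughter.
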