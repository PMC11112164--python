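# scutoid3d

Analysis of 3D epithelial packing in curved monolayers from labelled
segmentation volumes: detection of **scutoids** (cells that change
neighbours between their apical and basal surfaces, the footprint of an
apico-basal T1 intercalation), a full cell/tissue morphometric panel,
matched **3D Voronoi null models**, and timing of scutoid formation
relative to cell division.

The package targets spheroidal monolayered epithelia — e.g. early
blastula-stage embryos imaged live on a confocal microscope and segmented
into one integer label per cell — and is aimed at quantitative
developmental biologists who already have labelled stacks (from any
segmentation tool) and want reproducible packing statistics.

## What it computes

Given a labelled volume (z, y, x; 0 = background) with voxel spacing in
µm:

- **Layer extraction.** Scanning each (y, x) column along z, the first
  labelled voxel from the top is the apical surface, from the bottom the
  basal surface, giving 2D label maps plus depth heightfields.
- **Scutoid calls.** Per-surface neighbour sets are built by dilating
  each cell footprint and recording overlaps; a cell is scutoidal iff its
  apical and basal sets differ. Analysis is restricted to cells whose
  centroid lies within a configurable band (default 30 µm) of the apical
  surface, and image-border cells are excluded by default. The proportion
  of scutoids among counted cells is the headline statistic.
- **Morphometrics.** Cell volume (voxel count × voxel volume), convexity
  (volume / convex-hull volume, hull over voxel corners so the ratio is
  ≤ 1), cell height (distance between apical and basal surface
  centroids), areal cell density (selected cells / slope-corrected basal
  area), and opening areas (enclosed background components of the
  projected footprint).
- **Tissue geometry.** Ellipsoids are fitted to the apical and basal
  surface clouds by algebraic least squares; principal curvatures
  (k_h ≥ k_w) at each selected cell follow in closed form from the
  quadric. With R = 1/k, the surface ratios SR_h = R̄_a,h / R̄_b,h and
  SR_w = R̄_a,w / R̄_b,w give the **surface ratio anisotropy**
  sra = |SR_h − SR_w| (0 for isotropic curvature). The tissue surface
  ratio (apical area / basal area over the same cells) and whole-embryo
  axis lengths and aspect ratios complete the panel.
- **Voronoi null model.** The frame's own mask is re-tiled by proximity
  to the frame's own cell centroids (anisotropic spacing honoured, ties
  to the lowest label) and measured by the identical detection path; the
  excess of observed over Voronoi scutoid proportion isolates
  non-geometric (dynamic) contributions.
- **Division-relative timing.** For tracked cells, scutoid onset and end
  within each interphase are normalized by interphase duration; onsets
  before 15% of interphase (strictly) classify as "after mitosis".
  A developmental clock normalizes time across embryos by reference-stage
  first divisions and computes mitotic-wave windows (until ≥ 50% of a
  stage's cells have divided).

A built-in phantom generator produces spheroidal-shell epithelia with
known ground truth (Voronoi cells of quasi-uniform mid-surface seeds,
optional lateral compression, openings, synchronous division waves), plus
exact oracles (prism lattices: zero scutoids; a four-cell motif: exactly
four), so the entire pipeline is testable without any imaging data.

## Worked example

```python
from scutoid3d import phantoms, pipeline
from scutoid3d.volume_io import RunConfig

spec = phantoms.default_phantom_spec(n_cells=150, rng_seed=0)
volume, seeds = phantoms.make_voronoi_epithelium(spec)
summary, cells = pipeline.run_frame(volume, RunConfig())
print(f"scutoid proportion: {summary.scutoid_proportion:.3f}")
```

Output of the full summary for this phantom (a ~150-cell patch of a
spherical shell, outer radius 80 µm, 25 µm thick, 2 µm voxels):

```
stage:              128-cell
selected cells:     150 (120 counted)
scutoid proportion: 0.608
Voronoi null:       0.743  (excess -0.135)
cell density:       0.01504 cells/um^2
mean cell volume:   1430 um^3
mean convexity:     0.628
mean cell height:   23.3 um
surface ratio:      1.81
sra:                0.0199
```

Reading this: 120 interior cells enter the statistics; 61% of them change
neighbours between surfaces — dense proximity tilings on thick curved
shells are strongly scutoidal, and the matched Voronoi re-tiling is even
slightly more so (negative excess: this phantom *is* a static geometry,
with no dynamic component for the null model to miss). Mean height 23.3 µm
recovers the 25 µm shell thickness minus discretization; the surface
ratio 1.81 reflects the apical surface of a curved monolayer being larger
than its basal surface; sra ≈ 0.02 confirms the spherical (isotropic)
shell.

A command-line interface mirrors the library:

```sh
scutoid3d phantom --n-cells 150 --seed 0 --out phantom.tif
scutoid3d analyze-frame phantom.tif --out-prefix results/frame
scutoid3d voronoi-null phantom.tif
scutoid3d analyze-series frame_*.tif --track-table tracks.csv
```

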