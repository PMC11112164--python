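"""Apical/basal layer extraction, neighbour graphs and scutoid calling.

A scutoid is a cell whose set of neighbours on the apical surface differs
from its set on the basal surface — the signature of an apico-basal
intercalation (AB-T1). The detection strategy works directly on labelled
voxel volumes:

1. scan each (y, x) column of the volume along z, top to bottom, to find
   the first labelled voxel (the apical surface) and bottom to top for the
   basal surface, producing two 2D label maps plus depth heightfields;
2. on each 2D map, dilate every cell footprint and record which other
   labels the dilation overlaps — the per-surface neighbour sets;
3. flag cells whose apical and basal sets differ.

Cells are restricted to an analysis band within a configurable z-distance
of the apical surface (emulating the well-imaged region closest to the
objective), and cells touching the image boundary can be excluded since
their neighbour sets are truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, RunConfig

__all__ = [
    "LayerMaps",
    "ScutoidCalls",
    "extract_layers",
    "neighbour_sets",
    "select_band",
    "detect_scutoids",
    "scutoid_proportion",
    "transition_depth",
    "label_centroids",
]


@dataclass(frozen=True)
class LayerMaps:
    """Paired apical/basal 2D label maps with per-pixel depth.

    Depth maps hold the z slice index of the surface pixel, or -1 where the
    column contains no cell (label 0 in the maps there). Wherever both are
    defined, ``apical_depth <= basal_depth``.
    """

    apical_labels: np.ndarray
    basal_labels: np.ndarray
    apical_depth: np.ndarray
    basal_depth: np.ndarray
    spacing: tuple[float, float, float] | None = None


@dataclass
class ScutoidCalls:
    """Per-cell scutoid/border/selection flags plus the neighbour sets."""

    apical_sets: dict[int, frozenset]
    basal_sets: dict[int, frozenset]
    scutoid: dict[int, bool]
    border: dict[int, bool]
    selected: frozenset
    counted: frozenset  # selected cells entering numerator/denominator

    def n_scutoids(self) -> int:
        return sum(self.scutoid[l] for l in self.counted)


def extract_layers(volume: LabelVolume) -> LayerMaps:
    """Directional z-scans: first labelled voxel from the top is apical,
    from the bottom is basal."""
    vox = volume.voxels
    if not np.any(vox):
        raise ValueError("cannot extract layers from an empty volume")
    occupied = vox > 0
    has_cell = occupied.any(axis=0)
    top = np.argmax(occupied, axis=0)
    bottom = vox.shape[0] - 1 - np.argmax(occupied[::-1], axis=0)

    yy, xx = np.indices(has_cell.shape)
    apical_depth = np.where(has_cell, top, -1)
    basal_depth = np.where(has_cell, bottom, -1)
    apical_labels = np.where(has_cell, vox[top, yy, xx], 0)
    basal_labels = np.where(has_cell, vox[bottom, yy, xx], 0)
    return LayerMaps(
        apical_labels=apical_labels,
        basal_labels=basal_labels,
        apical_depth=apical_depth,
        basal_depth=basal_depth,
        spacing=volume.spacing,
    )


def _footprint(radius: int) -> np.ndarray:
    # Chebyshev disk: at radius 1 this is the 3x3 square, so diagonal
    # (corner) contact counts as neighbourhood.
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def neighbour_sets(layer: np.ndarray, dilation_radius: int = 1) -> dict[int, set]:
    """Per-label neighbour sets of a 2D label map by footprint dilation.

    Each cell's pixel set is dilated by a square footprint of the given
    radius; the labels overlapped by the dilation (excluding self and
    background) are its neighbours. The relation is symmetrized by union,
    so it is symmetric and irreflexive.
    """
    if dilation_radius < 1:
        raise ValueError("dilation_radius must be >= 1")
    layer = np.asarray(layer)
    labels = np.unique(layer)
    labels = labels[labels > 0]
    sets: dict[int, set] = {int(l): set() for l in labels}
    if len(labels) == 0:
        return sets
    fp = _footprint(dilation_radius)
    slices = ndimage.find_objects(layer)
    r = dilation_radius
    for l in labels:
        sl = slices[l - 1]
        if sl is None:
            continue
        y0 = max(sl[0].start - r, 0)
        y1 = min(sl[0].stop + r, layer.shape[0])
        x0 = max(sl[1].start - r, 0)
        x1 = min(sl[1].stop + r, layer.shape[1])
        crop = layer[y0:y1, x0:x1]
        dil = ndimage.binary_dilation(crop == l, structure=fp)
        touched = np.unique(crop[dil])
        for t in touched:
            if t != 0 and t != l:
                sets[int(l)].add(int(t))
    # symmetrize by union
    for a in list(sets):
        for b in sets[a]:
            sets[b].add(a)
    return sets


def label_centroids(volume: LabelVolume) -> dict[int, np.ndarray]:
    """Physical (z, y, x) centroids in µm, origin at voxel (0, 0, 0) centre."""
    vox = volume.voxels
    labels = volume.labels()
    if len(labels) == 0:
        return {}
    maxl = int(labels.max())
    counts = np.bincount(vox.ravel(), minlength=maxl + 1).astype(float)
    idx = np.indices(vox.shape)
    out = {}
    sums = np.stack(
        [
            np.bincount(vox.ravel(), weights=idx[a].ravel(), minlength=maxl + 1)
            for a in range(3)
        ],
        axis=1,
    )
    spacing = np.asarray(volume.spacing)
    for l in labels:
        out[int(l)] = sums[l] / counts[l] * spacing
    return out


def select_band(volume: LabelVolume, band_depth: float) -> set[int]:
    """Select cells whose centroid lies within ``band_depth`` µm (along z)
    of the apical surface heightfield at the centroid's (y, x) column."""
    if band_depth <= 0:
        raise ValueError("band_depth must be > 0")
    if not np.any(volume.voxels):
        return set()
    layers = extract_layers(volume)
    dz = volume.spacing[0]
    centroids = label_centroids(volume)
    selected = set()
    for l, c in centroids.items():
        cz_idx = c[0] / dz
        iy = int(round(c[1] / volume.spacing[1]))
        ix = int(round(c[2] / volume.spacing[2]))
        iy = min(max(iy, 0), layers.apical_depth.shape[0] - 1)
        ix = min(max(ix, 0), layers.apical_depth.shape[1] - 1)
        depth = layers.apical_depth[iy, ix]
        if depth < 0:
            # concave cell whose centroid column is empty: fall back to the
            # cell's own shallowest voxel
            depth = int(np.argwhere(volume.voxels == l)[:, 0].min())
        if (cz_idx - depth) * dz <= band_depth:
            selected.add(l)
    return selected


def _border_labels(layer: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [layer[0, :], layer[-1, :], layer[:, 0], layer[:, -1]]
    )
    return {int(l) for l in np.unique(edge) if l != 0}


def detect_scutoids(
    layers: LayerMaps,
    config: RunConfig,
    selected: set[int],
) -> ScutoidCalls:
    """Call scutoids among the selected cells.

    A cell is scutoidal iff its apical and basal neighbour sets differ.
    Cells whose apical or basal footprint touches the image boundary — or
    is missing from one surface altogether, the limiting case of a
    footprint cropped by the field of view — carry a border flag; under
    ``border_policy="exclude"`` they are dropped from both numerator and
    denominator of the scutoid proportion, since a truncated neighbour set
    would masquerade as an apico-basal difference.
    """
    if not selected:
        raise ValueError("no selected cells to analyse")
    apical = neighbour_sets(layers.apical_labels, config.dilation_radius)
    basal = neighbour_sets(layers.basal_labels, config.dilation_radius)
    border_apical = _border_labels(layers.apical_labels)
    border_basal = _border_labels(layers.basal_labels)

    all_labels = set(apical) | set(basal)
    apical_sets = {l: frozenset(apical.get(l, set())) for l in all_labels}
    basal_sets = {l: frozenset(basal.get(l, set())) for l in all_labels}
    scutoid = {l: apical_sets[l] != basal_sets[l] for l in all_labels}
    border = {
        l: (
            l in border_apical
            or l in border_basal
            or l not in apical
            or l not in basal
        )
        for l in all_labels
    }

    present_selected = frozenset(l for l in selected if l in all_labels)
    if config.border_policy == "exclude":
        counted = frozenset(l for l in present_selected if not border[l])
    else:
        counted = present_selected
    return ScutoidCalls(
        apical_sets=apical_sets,
        basal_sets=basal_sets,
        scutoid=scutoid,
        border=border,
        selected=present_selected,
        counted=counted,
    )


def scutoid_proportion(calls: ScutoidCalls) -> float:
    """Fraction of counted cells that are scutoids, in [0, 1]."""
    if not calls.counted:
        raise ValueError("no counted cells: cannot form a proportion")
    return calls.n_scutoids() / len(calls.counted)


def call_scutoids(volume: LabelVolume, config: RunConfig) -> ScutoidCalls:
    """Convenience: layers → band selection → scutoid calls for a volume."""
    layers = extract_layers(volume)
    selected = select_band(volume, config.band_depth)
    return detect_scutoids(layers, config, selected)


def _pair_pattern(slice_map: np.ndarray, quartet: tuple[int, ...]) -> frozenset:
    masked = np.where(np.isin(slice_map, quartet), slice_map, 0)
    sets = neighbour_sets(masked, 1)
    return frozenset(
        frozenset((a, b)) for a in sets for b in sets[a] if a < b
    )


def transition_depth(volume: LabelVolume, quartet) -> float:
    """Normalized z of the slice where the shared wall of an AB-T1 flips.

    The adjacency pattern among the four labels is computed per slice; the
    transition is the first slice whose pattern differs from the apical
    (slice 0) pattern. Raises if the four labels never change pattern
    (no AB-T1 between these cells).
    """
    quartet = tuple(int(q) for q in quartet)
    if len(set(quartet)) != 4:
        raise ValueError("quartet must contain 4 distinct labels")
    vox = volume.voxels
    nz = vox.shape[0]
    patterns = [_pair_pattern(vox[z], quartet) for z in range(nz)]
    apical_pattern = patterns[0]
    for z in range(1, nz):
        if patterns[z] != apical_pattern:
            return z / nz
    raise ValueError("no apico-basal neighbour flip found among these labels")
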