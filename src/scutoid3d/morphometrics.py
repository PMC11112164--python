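"""Per-cell and per-region morphometrics on labelled volumes.

All quantities are physical (µm, µm², µm³), honouring anisotropic voxel
spacing. Volumes are voxel counts times the voxel volume; convexity is the
cell volume over the volume of the convex hull of the cell's voxel
*corners* (corner hulls always contain the voxel union, so the ratio
cannot exceed 1); heights are Euclidean distances between apical- and
basal-surface centroids; densities relate selected cell counts to the
slope-corrected basal area they occupy; opening areas are background
components of the projected tissue footprint.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .volume_io import LabelVolume
from .topology import LayerMaps, ScutoidCalls

__all__ = [
    "cell_volume",
    "cell_volumes",
    "cell_convexity",
    "cell_height",
    "basal_areas",
    "cell_density",
    "opening_areas",
]


def cell_volumes(volume: LabelVolume) -> dict[int, float]:
    """Volume in µm³ of every labelled cell (voxel count x voxel volume)."""
    counts = np.bincount(volume.voxels.ravel())
    vv = volume.voxel_volume
    return {int(l): counts[l] * vv for l in volume.labels()}


def cell_volume(volume: LabelVolume, label: int) -> float:
    """Volume of one cell in µm³."""
    count = int(np.count_nonzero(volume.voxels == label))
    if count == 0:
        raise ValueError(f"label {label} absent from volume")
    return count * volume.voxel_volume


def _corner_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Unique physical corner coordinates of the voxels in a binary mask.

    A voxel at index i spans [i-1/2, i+1/2] in index units; only corners of
    boundary voxels are needed for the hull, so the interior is eroded away
    first.
    """
    boundary = mask & ~ndimage.binary_erosion(mask)
    idx = np.argwhere(boundary)
    offsets = np.array(
        [[a, b, c] for a in (-0.5, 0.5) for b in (-0.5, 0.5) for c in (-0.5, 0.5)]
    )
    corners = (idx[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    corners = np.unique(corners, axis=0)
    return corners * np.asarray(spacing)


def cell_convexity(volume: LabelVolume, label: int) -> float:
    """Cell volume divided by the volume of its convex hull, in (0, 1].

    The hull is taken over the eight physical corners of every cell voxel,
    never the voxel centres, which guarantees hull ⊇ voxel union and hence
    a ratio of at most 1 (up to hull arithmetic tolerance). Axis-aligned
    cuboids score exactly 1. Values near 1 indicate a convex, uncrowded
    cell; lower values indicate deformation by packing.
    """
    mask = volume.voxels == label
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError(f"label {label} absent from volume")
    corners = _corner_points(mask, volume.spacing)
    try:
        hull = ConvexHull(corners)
    except QhullError as exc:  # pragma: no cover - corners are never coplanar
        raise ValueError(f"degenerate cell {label}: {exc}") from exc
    return nvox * volume.voxel_volume / hull.volume


def _surface_centroid(
    layers: LayerMaps, which: str, label: int, spacing
) -> np.ndarray:
    maps = layers.apical_labels if which == "apical" else layers.basal_labels
    depth = layers.apical_depth if which == "apical" else layers.basal_depth
    pix = np.argwhere(maps == label)
    if len(pix) == 0:
        raise ValueError(f"label {label} missing from the {which} layer")
    dz, dy, dx = spacing
    z = depth[pix[:, 0], pix[:, 1]] * dz
    y = pix[:, 0] * dy
    x = pix[:, 1] * dx
    return np.array([z.mean(), y.mean(), x.mean()])


def cell_height(volume: LabelVolume, layers: LayerMaps, label: int) -> float:
    """Euclidean distance (µm) between the centroids of the cell's apical
    and basal surface pixels."""
    a = _surface_centroid(layers, "apical", label, volume.spacing)
    b = _surface_centroid(layers, "basal", label, volume.spacing)
    return float(np.linalg.norm(a - b))


def _slope_factor(depth: np.ndarray, spacing) -> np.ndarray:
    """Per-pixel area correction of a depth heightfield.

    factor = sqrt(1 + (dz_phys/dx)² + (dz_phys/dy)²) where the gradients are
    of the physical height z = depth·dz. Undefined pixels (depth < 0) and
    pixels whose finite-difference stencil crosses an undefined pixel fall
    back to 1 (no correction). Flat tissues have factor 1 everywhere.
    """
    dz, dy, dx = spacing
    z = np.where(depth >= 0, depth * dz, np.nan)
    gy, gx = np.gradient(z, dy, dx)
    factor = np.sqrt(1.0 + np.nan_to_num(gx) ** 2 + np.nan_to_num(gy) ** 2)
    factor[~np.isfinite(gx) | ~np.isfinite(gy)] = 1.0
    return factor


def basal_areas(layers: LayerMaps, spacing) -> dict[int, float]:
    """Slope-corrected basal surface area (µm²) per cell.

    Each basal-layer pixel contributes dx·dy times the local heightfield
    slope factor, so curved basal caps measure more than their projection.
    """
    dz, dy, dx = spacing
    factor = _slope_factor(layers.basal_depth, spacing)
    labels = np.unique(layers.basal_labels)
    labels = labels[labels > 0]
    areas = ndimage.sum_labels(factor * dy * dx, layers.basal_labels, labels)
    return {int(l): float(a) for l, a in zip(labels, areas)}


def cell_density(calls: ScutoidCalls, areas: dict[int, float]) -> float:
    """Cells per µm² of basal surface: selected cells over the sum of the
    basal areas they occupy.

    Uses the full selected set (not the border-excluded one): the covered
    basal region then spans the whole analysed footprint and stays stable
    across stages, whereas the border-excluded collar shifts with cell
    size.
    """
    cells = [l for l in calls.selected if areas.get(l, 0.0) > 0]
    total = sum(areas[l] for l in cells)
    if not cells or total <= 0:
        raise ValueError("no selected cells with basal area")
    return len(cells) / total


def opening_areas(
    volume: LabelVolume, min_opening_area: float = 0.0
) -> list[float]:
    """Areas (µm²) of openings: enclosed background components of the
    projected tissue footprint.

    The full z-projection of the labels gives the tissue footprint; holes
    are background components fully enclosed by the footprint (the
    exterior does not count, and neither do the sliver pixels a convex
    hull of a digitized round footprint would add along its rim).
    Components smaller than ``min_opening_area`` are dropped. Returns an
    empty list for a sealed tissue.
    """
    if not np.any(volume.voxels):
        raise ValueError("empty volume")
    footprint = (volume.voxels > 0).any(axis=0)
    holes = ndimage.binary_fill_holes(footprint) & ~footprint
    lab, n = ndimage.label(holes)
    if n == 0:
        return []
    _, dy, dx = volume.spacing
    pix_area = dy * dx
    counts = np.bincount(lab.ravel())[1:]
    areas = sorted(
        (float(c * pix_area) for c in counts if c * pix_area >= min_opening_area),
        reverse=True,
    )
    return areas
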