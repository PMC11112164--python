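"""Voronoi constructions as steady-state null models of epithelial packing.

A Voronoi construction matched to a segmented frame re-tiles the frame's
own tissue mask by proximity to the frame's own cell centroids. It
reproduces the static geometry (tissue shape, cell density, cell
positions) but contains none of the dynamics — no divisions, no active
rearrangement. Running the identical scutoid-detection pipeline on the
observation and on its construction therefore attributes any excess
scutoid proportion to dynamic, non-geometric causes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume, RunConfig
from . import topology

__all__ = [
    "VoronoiConstruction",
    "NullComparison",
    "nearest_seed_labels",
    "voronoi_construct",
    "null_comparison",
]

# voxels per chunk of the vectorized nearest-seed assignment
_CHUNK = 16384


@dataclass(frozen=True)
class VoronoiConstruction:
    """A proximity tiling of a mask from given seeds."""

    volume: LabelVolume
    seeds: dict[int, np.ndarray]  # label -> (z, y, x) µm
    source_frame: int | None = None


@dataclass(frozen=True)
class NullComparison:
    """Observed vs Voronoi-null scutoid proportions for one frame."""

    observed_proportion: float
    voronoi_proportion: float
    excess: float
    n_observed: int
    n_voronoi: int


def nearest_seed_labels(
    seeds: np.ndarray,
    mask: np.ndarray,
    spacing,
    origin: str = "corner",
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Assign every in-mask voxel to its nearest seed in physical distance.

    Parameters
    ----------
    seeds
        ``(n, 3)`` seed coordinates in µm, ``(z, y, x)`` order.
    mask
        Boolean volume defining the territory to tile.
    spacing
        Voxel size ``(dz, dy, dx)`` in µm.
    origin
        ``"corner"``: coordinates measured from the centre of voxel
        (0, 0, 0); ``"center"``: from the geometric centre of the grid.
    labels
        Optional label per seed (default ``1..n``). Ties in distance go to
        the lowest label: seeds are ordered by ascending label and the
        first minimum wins.

    Notes
    -----
    Distances are the plain sum of squared per-axis differences, so the
    result is bit-reproducible and matches a per-voxel brute-force
    computation exactly, including equidistant voxels.
    """
    seeds = np.asarray(seeds, dtype=float)
    if seeds.ndim != 2 or seeds.shape[1] != 3 or len(seeds) == 0:
        raise ValueError("seeds must be a non-empty (n, 3) array")
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if labels is None:
        labels = np.arange(1, len(seeds) + 1)
    else:
        labels = np.asarray(labels)
        order = np.argsort(labels, kind="stable")
        labels = labels[order]
        seeds = seeds[order]

    coords = np.argwhere(mask).astype(float) * spacing
    if origin == "center":
        coords -= (np.asarray(mask.shape) - 1) / 2.0 * spacing
    elif origin != "corner":
        raise ValueError(f"unknown origin {origin!r}")

    nearest = np.empty(len(coords), dtype=np.int64)
    for start in range(0, len(coords), _CHUNK):
        block = coords[start : start + _CHUNK]
        d2 = (block[:, None, 0] - seeds[None, :, 0]) ** 2
        d2 += (block[:, None, 1] - seeds[None, :, 1]) ** 2
        d2 += (block[:, None, 2] - seeds[None, :, 2]) ** 2
        nearest[start : start + _CHUNK] = np.argmin(d2, axis=1)

    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask] = labels[nearest]
    return out


def voronoi_construct(
    centroids,
    mask: np.ndarray,
    spacing,
    source_frame: int | None = None,
) -> VoronoiConstruction:
    """Tile a binary mask by proximity to the given seeds.

    ``centroids`` is a mapping ``label -> (z, y, x) µm`` (coordinates from
    the centre of voxel (0, 0, 0)) or an ``(n, 3)`` array (labels 1..n).
    Seeds falling outside the mask are kept, with a warning.
    """
    if isinstance(centroids, dict):
        labels = np.array(sorted(centroids))
        seeds = np.array([centroids[l] for l in labels], dtype=float)
    else:
        seeds = np.asarray(centroids, dtype=float)
        labels = np.arange(1, len(seeds) + 1)
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds for a Voronoi construction")
    spacing_arr = np.asarray(spacing, dtype=float)
    idx = np.rint(seeds / spacing_arr).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    in_mask = np.zeros(len(seeds), dtype=bool)
    in_mask[inside] = mask[tuple(idx[inside].T)]
    if not in_mask.all():
        warnings.warn(
            f"{int((~in_mask).sum())} seed(s) fall outside the mask; kept as-is",
            stacklevel=2,
        )
    vox = nearest_seed_labels(seeds, mask, spacing, origin="corner", labels=labels)
    volume = LabelVolume(
        voxels=vox, spacing=tuple(float(s) for s in spacing_arr),
        frame_index=source_frame,
    )
    return VoronoiConstruction(
        volume=volume,
        seeds={int(l): s for l, s in zip(labels, seeds)},
        source_frame=source_frame,
    )


def null_comparison(
    observed: LabelVolume,
    config: RunConfig,
    seeds: dict[int, np.ndarray] | None = None,
) -> NullComparison:
    """Compare a frame's scutoid proportion with its matched Voronoi null.

    The construction reuses the observed frame's own mask (union of its
    labels) and its cell centroids as seeds, then is measured by the
    byte-identical layer-extraction, band-selection and scutoid-detection
    path, so the excess proportion is attributable to geometry-independent
    causes only.

    When the observed volume is itself a Voronoi construction, pass its
    defining ``seeds`` explicitly: the null then rebuilds the identical
    tiling (the tie rule is deterministic) and the excess is exactly 0.
    Re-deriving seeds as centroids of Voronoi regions would instead take a
    Lloyd relaxation step and perturb the diagram.
    """
    centroids = seeds if seeds is not None else topology.label_centroids(observed)
    mask = observed.voxels > 0
    construction = voronoi_construct(
        centroids, mask, observed.spacing, source_frame=observed.frame_index
    )

    calls_obs = topology.call_scutoids(observed, config)
    if config.recompute_band_on_voronoi:
        calls_vor = topology.call_scutoids(construction.volume, config)
    else:
        layers = topology.extract_layers(construction.volume)
        calls_vor = topology.detect_scutoids(layers, config, set(calls_obs.selected))
    p_obs = topology.scutoid_proportion(calls_obs)
    p_vor = topology.scutoid_proportion(calls_vor)
    return NullComparison(
        observed_proportion=p_obs,
        voronoi_proportion=p_vor,
        excess=p_obs - p_vor,
        n_observed=len(calls_obs.counted),
        n_voronoi=len(calls_vor.counted),
    )
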