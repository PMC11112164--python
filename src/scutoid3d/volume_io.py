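"""Labelled-volume containers, run configuration and file input/output.

This module owns the coordinate conventions used throughout the package:

* volumes are integer arrays in ``(z, y, x)`` order, label 0 is background;
* ``spacing`` is the physical voxel size in micrometres, ``(dz, dy, dx)``,
  matching the axis order of the array;
* z index 0 is the slice closest to the objective, i.e. the apical side of
  a monolayer imaged from above.

Volumes travel as multi-page TIFF stacks (one page per z slice) with the
voxel spacing recorded in a JSON sidecar next to the image file; per-cell
feature tables are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LabelVolume",
    "RunConfig",
    "read_label_volume",
    "write_label_volume",
    "write_cell_table",
    "read_cell_table",
    "CELL_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class LabelVolume:
    """A labelled 3D segmentation with physical voxel spacing.

    Parameters
    ----------
    voxels
        Integer array in ``(z, y, x)`` order; one positive label per cell,
        0 for background.
    spacing
        Voxel size in µm, ``(dz, dy, dx)``.
    frame_index
        Optional index of the volume in a time-lapse series.
    stage_label
        Optional developmental stage tag such as ``"256-cell"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    frame_index: int | None = None
    stage_label: str | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={vox.ndim}")
        if not np.issubdtype(vox.dtype, np.integer):
            raise TypeError(f"labels must be integers, got dtype {vox.dtype}")
        if vox.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present in the volume."""
        lab = np.unique(self.voxels)
        return lab[lab > 0]

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        return dataclasses.replace(self, voxels=voxels)


@dataclass
class RunConfig:
    """Tunable parameters of the analysis pipeline.

    Attributes
    ----------
    band_depth
        Depth in µm of the analysis band below the apical surface; cells
        whose centroid lies within this z-distance of the apical heightfield
        are selected (default 30 µm).
    onset_threshold
        Fraction of interphase below which a scutoid onset is classified as
        occurring "after mitosis" (default 0.15; the boundary itself counts
        as mitosis-independent).
    dilation_radius
        Disk radius in pixels used to dilate each cell footprint when
        building per-surface neighbour sets (default 1).
    min_opening_area
        Minimum area in µm² for a background component of the projected
        footprint to be reported as an opening (default 0, report all).
    border_policy
        ``"exclude"`` removes image-border cells from scutoid counts;
        ``"include-flagged"`` keeps them but carries the flag.
    recompute_band_on_voronoi
        If true (default), the selection band is recomputed on each Voronoi
        construction; if false the observed frame's selection is reused.
    radii_average_order
        ``"radii-then-ratio"`` (default) averages radii of curvature per
        surface before forming apical/basal ratios; ``"ratio-then-average"``
        averages per-cell ratios instead.
    rng_seed
        Seed for any stochastic step of a run.
    """

    band_depth: float = 30.0
    onset_threshold: float = 0.15
    dilation_radius: int = 1
    min_opening_area: float = 0.0
    border_policy: str = "exclude"
    recompute_band_on_voronoi: bool = True
    radii_average_order: str = "radii-then-ratio"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.band_depth <= 0:
            raise ValueError("band_depth must be > 0")
        if not 0 < self.onset_threshold < 1:
            raise ValueError("onset_threshold must lie strictly in (0, 1)")
        if self.dilation_radius < 1:
            raise ValueError("dilation_radius must be >= 1")
        if self.border_policy not in ("exclude", "include-flagged"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if self.radii_average_order not in ("radii-then-ratio", "ratio-then-average"):
            raise ValueError(f"unknown radii_average_order {self.radii_average_order!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as a multi-page TIFF plus a JSON spacing sidecar.

    Labels are stored as 16-bit unsigned when they fit, 32-bit otherwise.
    """
    path = Path(path)
    vox = volume.voxels
    dtype = np.uint16 if vox.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, vox.astype(dtype))
    meta = {
        "spacing_um_zyx": list(volume.spacing),
        "frame_index": volume.frame_index,
        "stage_label": volume.stage_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_label_volume(
    path: str | Path,
    spacing: Sequence[float] | None = None,
) -> LabelVolume:
    """Read a multi-page TIFF stack of integer labels.

    Spacing is taken from the JSON sidecar written by
    :func:`write_label_volume`, unless overridden by ``spacing``.

    Raises
    ------
    TypeError
        If the TIFF holds non-integer pixel data.
    ValueError
        If no spacing is available from either sidecar or override.
    """
    path = Path(path)
    vox = tifffile.imread(path)
    if not np.issubdtype(vox.dtype, np.integer):
        raise TypeError(f"label TIFF must contain integer pixels, got {vox.dtype}")
    if vox.ndim == 2:
        warnings.warn(
            "single-page TIFF: volume has n_z=1, apical and basal layers coincide",
            stacklevel=2,
        )
        vox = vox[np.newaxis]
    frame_index = None
    stage_label = None
    sidecar = _sidecar_path(path)
    if spacing is None:
        if not sidecar.exists():
            raise ValueError(
                f"no spacing sidecar found at {sidecar} and no spacing override given"
            )
        meta = json.loads(sidecar.read_text())
        spacing = meta["spacing_um_zyx"]
        frame_index = meta.get("frame_index")
        stage_label = meta.get("stage_label")
    elif sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_index = meta.get("frame_index")
        stage_label = meta.get("stage_label")
    return LabelVolume(
        voxels=vox.astype(np.int64),
        spacing=tuple(spacing),
        frame_index=frame_index,
        stage_label=stage_label,
    )


#: Stable column order of the per-cell CSV.
CELL_TABLE_COLUMNS = [
    "cell_id",
    "frame_index",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "volume_um3",
    "convexity",
    "height_um",
    "basal_area_um2",
    "apical_neighbours",
    "basal_neighbours",
    "is_scutoid",
    "is_border",
    "is_selected",
]


def _join_ids(ids) -> str:
    return ";".join(str(i) for i in sorted(ids))


def write_cell_table(records: Sequence[dict], path: str | Path) -> Path:
    """Write per-cell records to CSV with a documented, stable column order.

    ``records`` is a sequence of dicts; neighbour sets are serialized as
    sorted ``;``-joined id strings. All records must share ``frame_index``
    and carry unique ``cell_id`` values.
    """
    path = Path(path)
    if records:
        frames = {r.get("frame_index") for r in records}
        if len(frames) > 1:
            raise ValueError(f"records span multiple frames: {sorted(frames, key=str)}")
        ids = [r["cell_id"] for r in records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate cell ids in records")
    rows = []
    for rec in records:
        row = dict(rec)
        for key in ("apical_neighbours", "basal_neighbours"):
            if not isinstance(row.get(key, ""), str):
                row[key] = _join_ids(row[key])
        rows.append(row)
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell CSV back into a DataFrame."""
    return pd.read_csv(path)
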