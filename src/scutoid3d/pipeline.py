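"""Per-frame and per-series orchestration of the full analysis.

``run_frame`` chains topology → morphometrics → geometry → Voronoi null
model for one labelled volume and returns a flat summary plus the
per-cell records; ``run_series`` maps it over a time-lapse, isolates
per-frame failures, adds the event-timing analysis when a track table is
available, and aggregates per developmental stage. Group comparisons are
delegated to standard rank-based routines.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dynamics, geometry, morphometrics, topology, voronoi_null
from .volume_io import LabelVolume, RunConfig

__all__ = [
    "FrameSummary",
    "run_frame",
    "run_series",
    "aggregate_by_stage",
    "compare_groups",
    "stage_from_cell_count",
]

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "frame",
    "stage",
    "n_cells",
    "n_selected",
    "n_counted",
    "scutoid_proportion",
    "density",
    "mean_volume",
    "mean_convexity",
    "mean_height",
    "sra",
    "surface_ratio",
    "opening_area_sum",
    "voronoi_proportion",
    "excess",
    "error",
]


@dataclass
class FrameSummary:
    """Figure-level scalar summary of one frame."""

    frame: int | None = None
    stage: str | None = None
    n_cells: int | None = None
    n_selected: int | None = None
    n_counted: int | None = None
    scutoid_proportion: float | None = None
    density: float | None = None
    mean_volume: float | None = None
    mean_convexity: float | None = None
    mean_height: float | None = None
    sra: float | None = None
    surface_ratio: float | None = None
    opening_area_sum: float | None = None
    voronoi_proportion: float | None = None
    excess: float | None = None
    error: str = ""

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def stage_from_cell_count(n_cells: int) -> str:
    """Nearest power-of-two stage label, e.g. 300 cells → "256-cell"."""
    if n_cells < 1:
        raise ValueError("no cells")
    exponent = int(round(np.log2(n_cells)))
    return f"{2 ** exponent}-cell"


def run_frame(
    volume: LabelVolume,
    config: RunConfig | None = None,
    with_voronoi: bool = True,
) -> tuple[FrameSummary, list[dict]]:
    """Analyse a single labelled frame.

    Returns the frame summary and one record dict per cell (the per-cell
    CSV rows). Deterministic for fixed input and config. Stage errors are
    caught and recorded in ``summary.error``; fields computed before the
    failing stage are kept.
    """
    config = config or RunConfig()
    summary = FrameSummary(frame=volume.frame_index)
    records: list[dict] = []
    errors: list[str] = []

    labels = volume.labels()
    summary.n_cells = len(labels)
    summary.stage = volume.stage_label or (
        stage_from_cell_count(len(labels)) if len(labels) else None
    )

    layers = None
    calls = None
    try:
        layers = topology.extract_layers(volume)
        selected = topology.select_band(volume, config.band_depth)
        calls = topology.detect_scutoids(layers, config, selected)
        summary.n_selected = len(calls.selected)
        summary.n_counted = len(calls.counted)
        summary.scutoid_proportion = topology.scutoid_proportion(calls)
    except Exception as exc:
        errors.append(f"topology: {exc}")

    if layers is not None and calls is not None:
        try:
            volumes = morphometrics.cell_volumes(volume)
            areas = morphometrics.basal_areas(layers, volume.spacing)
            centroids = topology.label_centroids(volume)
            heights, convexities = {}, {}
            for l in sorted(calls.counted):
                try:
                    heights[l] = morphometrics.cell_height(volume, layers, l)
                except ValueError:
                    pass
                convexities[l] = morphometrics.cell_convexity(volume, l)
            summary.density = morphometrics.cell_density(calls, areas)
            counted = sorted(calls.counted)
            summary.mean_volume = float(np.mean([volumes[l] for l in counted]))
            summary.mean_convexity = float(np.mean([convexities[l] for l in counted]))
            if heights:
                summary.mean_height = float(np.mean(list(heights.values())))
            openings = morphometrics.opening_areas(volume, config.min_opening_area)
            summary.opening_area_sum = float(sum(openings))
            for l in sorted(calls.selected):
                c = centroids[l]
                records.append(
                    {
                        "cell_id": l,
                        "frame_index": volume.frame_index,
                        "centroid_z_um": c[0],
                        "centroid_y_um": c[1],
                        "centroid_x_um": c[2],
                        "volume_um3": volumes.get(l),
                        "convexity": convexities.get(l),
                        "height_um": heights.get(l),
                        "basal_area_um2": areas.get(l),
                        "apical_neighbours": ";".join(
                            str(i) for i in sorted(calls.apical_sets.get(l, ()))
                        ),
                        "basal_neighbours": ";".join(
                            str(i) for i in sorted(calls.basal_sets.get(l, ()))
                        ),
                        "is_scutoid": calls.scutoid.get(l, False),
                        "is_border": calls.border.get(l, False),
                        "is_selected": True,
                    }
                )
        except Exception as exc:
            errors.append(f"morphometrics: {exc}")

        try:
            record = geometry.surface_ratio_anisotropy(
                volume, layers, set(calls.selected), config
            )
            summary.sra = record.sra
        except Exception as exc:
            errors.append(f"sra: {exc}")
        try:
            summary.surface_ratio = geometry.tissue_surface_ratio(
                layers, volume.spacing, set(calls.counted)
            )
        except Exception as exc:
            errors.append(f"surface_ratio: {exc}")

    if with_voronoi and calls is not None:
        try:
            cmp = voronoi_null.null_comparison(volume, config)
            summary.voronoi_proportion = cmp.voronoi_proportion
            summary.excess = cmp.excess
        except Exception as exc:
            errors.append(f"voronoi: {exc}")

    summary.error = "; ".join(errors)
    if errors:
        log.warning("frame %s: %s", volume.frame_index, summary.error)
    return summary, records


def run_series(
    volumes: list[LabelVolume],
    config: RunConfig | None = None,
    track_table: pd.DataFrame | None = None,
    with_voronoi: bool = True,
    embryo_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse an ordered time-lapse of labelled frames.

    Returns ``(summaries, events)``: one summary row per frame (failures
    isolated into the ``error`` column) and, when ``track_table`` provides
    per-cell interphase bounds, one row per scutoid onset/end event.
    """
    config = config or RunConfig()
    if not volumes:
        raise ValueError("empty series")
    spacings = {v.spacing for v in volumes}
    if len(spacings) > 1:
        raise ValueError(f"inconsistent spacing across frames: {spacings}")

    rows = []
    calls_by_frame: dict[int, topology.ScutoidCalls] = {}
    for i, vol in enumerate(volumes):
        if vol.frame_index is None:
            vol = dataclasses.replace(vol, frame_index=i)
        try:
            summary, _ = run_frame(vol, config, with_voronoi=with_voronoi)
            calls_by_frame[vol.frame_index] = topology.call_scutoids(vol, config)
        except Exception as exc:  # total per-frame failure
            summary = FrameSummary(frame=vol.frame_index, error=str(exc))
        rows.append(summary.as_row())
    summaries = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    if track_table is not None and calls_by_frame:
        events = dynamics.track_scutoid_events(
            calls_by_frame,
            track_table,
            threshold=config.onset_threshold,
            embryo_id=embryo_id,
        )
        events_df = dynamics.events_to_frame(events)
    else:
        events_df = pd.DataFrame()
    return summaries, events_df


def aggregate_by_stage(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean and s.d. of every numeric summary field, per stage."""
    numeric = summaries.select_dtypes("number").columns.drop("frame", errors="ignore")
    grouped = summaries.groupby("stage", sort=False)[list(numeric)]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()


def compare_groups(
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
    method: str = "mannwhitneyu",
) -> dict:
    """Rank-based two-sample comparison of a summary field (plumbing)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if method == "mannwhitneyu":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "kruskal":
        res = stats.kruskal(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
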