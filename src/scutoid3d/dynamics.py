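"""Time-resolved scutoid analysis relative to the cell cycle.

For each tracked cell the interphase — the window between the end of
cytokinesis and the mitotic rounding that starts the next division — is
the normalization unit for scutoid timing. Within it, the scutoid onset is
the first frame at which the cell's apical and basal neighbour sets
differ, and the scutoid end the last frame of that contiguous run. Onsets
earlier than a threshold fraction of the interphase (default 15%,
boundary exclusive) are classified as occurring "after mitosis", the rest
as mitosis-independent.

Developmental time across embryos is normalized by the span between the
first division of a reference early stage and the first division of a
reference late stage; each stage splits into a "mitotic wave" (until at
least 50% of its cells have divided) and an interphase period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import ScutoidCalls

__all__ = [
    "ScutoidEvent",
    "DevelopmentalClock",
    "track_scutoid_events",
    "normalize_event",
    "classify_onset",
    "proportion_after_mitosis",
    "developmental_clock",
    "events_to_frame",
    "nearest_centroid_tracks",
]

AFTER_MITOSIS = "after_mitosis"
INDEPENDENT = "independent"


@dataclass
class ScutoidEvent:
    """One contiguous scutoidal episode of a tracked cell."""

    cell_id: int
    interphase_start: int
    interphase_end: int
    onset: int
    end: int
    onset_norm: float
    duration_norm: float
    onset_class: str
    censored: bool = False  # still scutoidal at mitotic rounding
    anomaly: bool = False  # cell had more than one scutoidal run
    embryo_id: str | None = None


def classify_onset(onset_norm: float, threshold: float = 0.15) -> str:
    """"after mitosis" iff the normalized onset is strictly below the
    threshold; the boundary value itself counts as mitosis-independent."""
    if not 0.0 <= onset_norm <= 1.0:
        raise ValueError("onset_norm must lie in [0, 1]")
    return AFTER_MITOSIS if onset_norm < threshold else INDEPENDENT


def normalize_event(
    onset: int, end: int, interphase_start: int, interphase_end: int
) -> tuple[float, float]:
    """Normalized onset and (inclusive-frame) duration over the interphase.

    ``onset_norm = (onset − start) / (interphase length)``;
    ``duration_norm = (end − onset + 1) / (interphase length)`` — the +1
    counts frames inclusively, so a single-frame scutoid has a nonzero
    duration.
    """
    length = interphase_end - interphase_start
    if length <= 0:
        raise ValueError("interphase must have positive length")
    if not interphase_start <= onset <= end <= interphase_end:
        raise ValueError("onset/end outside the interphase bounds")
    onset_norm = (onset - interphase_start) / length
    duration_norm = (end - onset + 1) / length
    return onset_norm, duration_norm


def _scutoid_flag(calls, cell_id: int) -> bool:
    if isinstance(calls, ScutoidCalls):
        return bool(calls.scutoid.get(cell_id, False))
    return bool(calls.get(cell_id, False))


def track_scutoid_events(
    calls_by_frame: dict[int, ScutoidCalls],
    track_table: pd.DataFrame,
    threshold: float = 0.15,
    embryo_id: str | None = None,
) -> list[ScutoidEvent]:
    """Extract scutoid onset/end events from per-frame calls.

    ``track_table`` needs columns ``cell_id, interphase_start,
    interphase_end`` (frame indices, consistent with the keys of
    ``calls_by_frame``; cell ids persist across frames). For each cell the
    frames within its interphase where the scutoid flag is set are grouped
    into contiguous runs; each run becomes one event. A cell with more
    than one run is anomalous — both runs are reported with the anomaly
    flag rather than silently merged. An event reaching the end of the
    interphase is marked censored (the transition was not seen resolving).
    """
    frames = sorted(calls_by_frame)
    events: list[ScutoidEvent] = []
    for row in track_table.itertuples(index=False):
        cid = int(row.cell_id)
        start, stop = int(row.interphase_start), int(row.interphase_end)
        window = [f for f in frames if start <= f <= stop]
        flagged = [f for f in window if _scutoid_flag(calls_by_frame[f], cid)]
        if not flagged:
            continue
        runs: list[list[int]] = [[flagged[0]]]
        for f in flagged[1:]:
            # contiguous means consecutive *observed* frames
            prev = runs[-1][-1]
            if window.index(f) == window.index(prev) + 1:
                runs[-1].append(f)
            else:
                runs.append([f])
        anomaly = len(runs) > 1
        for run in runs:
            onset, end = run[0], run[-1]
            if stop > start:
                onset_norm, duration_norm = normalize_event(onset, end, start, stop)
            else:
                onset_norm, duration_norm = 0.0, 1.0
            events.append(
                ScutoidEvent(
                    cell_id=cid,
                    interphase_start=start,
                    interphase_end=stop,
                    onset=onset,
                    end=end,
                    onset_norm=onset_norm,
                    duration_norm=duration_norm,
                    onset_class=classify_onset(onset_norm, threshold),
                    censored=(end == stop),
                    anomaly=anomaly,
                    embryo_id=embryo_id,
                )
            )
    return events


def proportion_after_mitosis(
    events: list[ScutoidEvent] | np.ndarray,
    threshold: float = 0.15,
) -> tuple[float, dict[str, float]]:
    """Fraction of scutoid onsets classified as after mitosis.

    Accepts either a list of :class:`ScutoidEvent` or a raw array of
    normalized onset times. Returns the overall fraction and a per-embryo
    breakdown (empty when no embryo ids are present).
    """
    if isinstance(events, (list, tuple)) and events and isinstance(events[0], ScutoidEvent):
        onsets = np.array([e.onset_norm for e in events])
        embryos = [e.embryo_id for e in events]
    else:
        onsets = np.asarray(events, dtype=float)
        embryos = [None] * len(onsets)
    if len(onsets) == 0:
        raise ValueError("no events")
    after = onsets < threshold
    overall = float(np.mean(after))
    per_embryo: dict[str, float] = {}
    for eid in sorted({e for e in embryos if e is not None}):
        sel = [a for a, e in zip(after, embryos) if e == eid]
        per_embryo[eid] = float(np.mean(sel))
    return overall, per_embryo


@dataclass(frozen=True)
class DevelopmentalClock:
    """Normalized developmental time and per-stage mitotic-wave windows.

    Relative time 0 is the first division of the reference early stage and
    1 the first division of the reference late stage. Each stage's wave
    window runs from its first division to the earliest time at which at
    least half of its cells have divided; the remainder, until the first
    division of the next stage, is that stage's interphase period.
    """

    t0: float
    t1: float
    wave_windows: dict[str, tuple[float, float]]
    interphase_windows: dict[str, tuple[float, float]]

    def relative(self, t: float) -> float:
        return (t - self.t0) / (self.t1 - self.t0)


def developmental_clock(
    division_log: pd.DataFrame,
    stage_zero: str = "64-cell",
    stage_one: str = "512-cell",
) -> DevelopmentalClock:
    """Build the developmental clock from a division log.

    ``division_log`` needs columns ``cell_id, stage, division_time``; each
    row is one cell division, tagged with the stage the dividing cell
    belonged to. Raises if either reference stage is missing.
    """
    for col in ("cell_id", "stage", "division_time"):
        if col not in division_log.columns:
            raise ValueError(f"division log lacks column {col!r}")
    stages = list(dict.fromkeys(division_log["stage"]))
    for ref in (stage_zero, stage_one):
        if ref not in stages:
            raise ValueError(f"reference stage {ref!r} missing from the log")

    firsts = division_log.groupby("stage")["division_time"].min()
    t0 = float(firsts[stage_zero])
    t1 = float(firsts[stage_one])
    if not t0 < t1:
        raise ValueError("reference stages are not in temporal order")

    order = sorted(stages, key=lambda s: firsts[s])
    wave, inter = {}, {}
    for i, stage in enumerate(order):
        times = np.sort(division_log.loc[division_log["stage"] == stage, "division_time"].to_numpy())
        n = len(times)
        half_idx = int(np.ceil(n / 2)) - 1  # division that reaches >= 50%
        wave_end = float(times[half_idx])
        wave[stage] = (float(times[0]), wave_end)
        if i + 1 < len(order):
            inter[stage] = (wave_end, float(firsts[order[i + 1]]))
    return DevelopmentalClock(
        t0=t0, t1=t1, wave_windows=wave, interphase_windows=inter
    )


def nearest_centroid_tracks(
    volumes: list, max_distance: float = 10.0
) -> list[dict[int, int]]:
    """Greedy nearest-centroid tracking for series without persistent ids.

    Returns, per frame, a mapping from that frame's labels to persistent
    track ids. Frame 0 labels found their own tracks; in each subsequent
    frame, every label is matched to the nearest previous-frame track
    centroid (physical µm) within ``max_distance``, closest pairs first,
    one-to-one; unmatched labels open new tracks. Adequate for slowly
    moving epithelia between divisions; divisions appear as one daughter
    inheriting the track and the other opening a new one.
    """
    from .topology import label_centroids

    if not volumes:
        return []
    maps: list[dict[int, int]] = []
    prev: dict[int, np.ndarray] = {}
    next_track = 1
    for vol in volumes:
        cents = label_centroids(vol)
        if not maps:
            mapping = {l: i + 1 for i, l in enumerate(sorted(cents))}
            next_track = len(mapping) + 1
        else:
            pairs = [
                (float(np.linalg.norm(c - pc)), l, t)
                for l, c in cents.items()
                for t, pc in prev.items()
            ]
            pairs.sort()
            mapping = {}
            used_tracks: set[int] = set()
            for d, l, t in pairs:
                if d > max_distance:
                    break
                if l in mapping or t in used_tracks:
                    continue
                mapping[l] = t
                used_tracks.add(t)
            for l in sorted(set(cents) - set(mapping)):
                mapping[l] = next_track
                next_track += 1
        maps.append(mapping)
        prev = {mapping[l]: c for l, c in cents.items()}
    return maps


def events_to_frame(events: list[ScutoidEvent]) -> pd.DataFrame:
    """Serialize events to the documented CSV layout."""
    return pd.DataFrame(
        [
            {
                "embryo_id": e.embryo_id,
                "cell_id": e.cell_id,
                "interphase_start": e.interphase_start,
                "interphase_end": e.interphase_end,
                "onset_frame": e.onset,
                "end_frame": e.end,
                "onset_norm": e.onset_norm,
                "duration_norm": e.duration_norm,
                "onset_class": e.onset_class,
                "censored": e.censored,
                "anomaly": e.anomaly,
            }
            for e in events
        ]
    )
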