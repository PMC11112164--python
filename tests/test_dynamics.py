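"""Event timing: onset/duration normalization, classification, clocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scutoid3d import dynamics, phantoms
from scutoid3d.dynamics import AFTER_MITOSIS, INDEPENDENT


class TestNormalizeAndClassify:
    def test_onset_fraction_of_interphase(self):
        onset_norm, _ = dynamics.normalize_event(10, 10, 0, 100)
        assert onset_norm == 0.10

    def test_boundary_onset_is_zero(self):
        onset_norm, _ = dynamics.normalize_event(0, 5, 0, 100)
        assert onset_norm == 0.0

    def test_duration_counts_frames_inclusively(self):
        _, duration = dynamics.normalize_event(50, 100, 0, 100)
        assert duration == pytest.approx(0.51)

    def test_onset_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            dynamics.normalize_event(5, 10, 6, 20)

    @pytest.mark.parametrize(
        "onset_norm,expected",
        [(0.10, AFTER_MITOSIS), (0.50, INDEPENDENT), (0.15, INDEPENDENT)],
    )
    def test_threshold_is_strict(self, onset_norm, expected):
        # the boundary value counts as mitosis-independent: "after
        # mitosis" means strictly before the threshold fraction
        assert dynamics.classify_onset(onset_norm, 0.15) == expected

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_proportion_is_monotone_in_threshold(self, seed):
        onsets = phantoms.sample_onset_times(80, 0.5, 0.2, rng_seed=seed)
        props = [
            dynamics.proportion_after_mitosis(onsets, threshold=t)[0]
            for t in (0.05, 0.15, 0.3, 0.6, 0.9)
        ]
        assert all(a <= b for a, b in zip(props, props[1:]))


def calls_from_flags(flags_by_frame):
    return {f: dict(flags) for f, flags in flags_by_frame.items()}


class TestTrackEvents:
    track = pd.DataFrame(
        [{"cell_id": 1, "interphase_start": 0, "interphase_end": 20}]
    )

    def test_no_flags_no_event(self):
        calls = {f: {1: False} for f in range(21)}
        assert dynamics.track_scutoid_events(calls, self.track) == []

    def test_contiguous_run_becomes_one_event(self):
        calls = {f: {1: 2 <= f <= 5} for f in range(21)}
        events = dynamics.track_scutoid_events(calls, self.track)
        assert len(events) == 1
        e = events[0]
        assert (e.onset, e.end) == (2, 5)
        assert e.onset_norm == 0.10
        assert e.onset_class == AFTER_MITOSIS
        assert not e.censored and not e.anomaly

    def test_two_disjoint_runs_are_flagged_not_merged(self):
        calls = {f: {1: f in (2, 3, 10, 11)} for f in range(21)}
        events = dynamics.track_scutoid_events(calls, self.track)
        assert len(events) == 2
        assert all(e.anomaly for e in events)
        assert [(e.onset, e.end) for e in events] == [(2, 3), (10, 11)]

    def test_run_reaching_interphase_end_is_censored(self):
        calls = {f: {1: f >= 15} for f in range(21)}
        (event,) = dynamics.track_scutoid_events(calls, self.track)
        assert event.censored and event.end == 20

    def test_events_respect_interphase_windows_on_simulated_series(self):
        base = phantoms.default_phantom_spec(n_cells=30, rng_seed=6)
        spec = phantoms.synchronous_wave_spec(base, n_waves=2, frames_per_stage=2)
        from scutoid3d import topology
        from scutoid3d.volume_io import RunConfig

        vols, track = phantoms.simulate_division_series(spec)
        calls = {
            v.frame_index: topology.call_scutoids(v, RunConfig()) for v in vols
        }
        events = dynamics.track_scutoid_events(calls, track)
        assert events  # dense curved tissue: some scutoids exist
        for e in events:
            born = track.loc[track.cell_id == e.cell_id, "division_frame"].iloc[0]
            assert e.onset >= born


class TestProportionAfterMitosis:
    def test_all_early_onsets(self):
        onsets = np.full(20, 0.05)
        overall, _ = dynamics.proportion_after_mitosis(onsets)
        assert overall == 1.0

    def test_recovery_of_known_mixture_weight(self):
        onsets = phantoms.sample_onset_times(300, 0.65, 0.15, rng_seed=123)
        overall, _ = dynamics.proportion_after_mitosis(onsets, threshold=0.15)
        half_width = 1.96 * np.sqrt(0.65 * 0.35 / 300)
        assert abs(overall - 0.65) <= half_width

    def test_per_embryo_breakdown(self):
        events = [
            dynamics.ScutoidEvent(
                cell_id=i,
                interphase_start=0,
                interphase_end=10,
                onset=o,
                end=o,
                onset_norm=o / 10,
                duration_norm=0.1,
                onset_class=dynamics.classify_onset(o / 10),
                embryo_id=eid,
            )
            for i, (o, eid) in enumerate(
                [(0, "a"), (1, "a"), (9, "a"), (9, "b"), (8, "b")]
            )
        ]
        overall, per_embryo = dynamics.proportion_after_mitosis(events)
        assert overall == pytest.approx(2 / 5)
        assert per_embryo == {"a": pytest.approx(2 / 3), "b": 0.0}

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            dynamics.proportion_after_mitosis([])

    def test_normalization_invariant_to_clock_rescaling(self):
        # multiplying every frame index by a constant leaves the
        # normalized onset unchanged exactly, and the duration up to the
        # one-frame inclusive-count term
        a = dynamics.normalize_event(10, 30, 0, 100)
        b = dynamics.normalize_event(50, 150, 0, 500)
        assert a[0] == b[0]
        assert abs(a[1] - b[1]) <= 1 / 100


class TestDevelopmentalClock:
    @staticmethod
    def log():
        rows = []
        for i in range(10):  # 64-cell stage divides at minutes 100..109
            rows.append({"cell_id": i, "stage": "64-cell", "division_time": 100 + i})
        for i in range(20):
            rows.append({"cell_id": 100 + i, "stage": "128-cell", "division_time": 200 + i})
        for i in range(40):
            rows.append({"cell_id": 200 + i, "stage": "256-cell", "division_time": 300 + i})
        for i in range(80):
            rows.append({"cell_id": 300 + i, "stage": "512-cell", "division_time": 400 + i})
        return pd.DataFrame(rows)

    def test_reference_stages_define_relative_time(self):
        clock = dynamics.developmental_clock(self.log())
        assert clock.t0 == 100 and clock.t1 == 400
        assert clock.relative(250) == 0.5

    def test_wave_ends_at_half_of_divisions(self):
        clock = dynamics.developmental_clock(self.log())
        # 10 cells dividing at 100..109: the 5th division (>=50%) is at 104
        assert clock.wave_windows["64-cell"] == (100, 104)
        # interphase runs until the first division of the next stage
        assert clock.interphase_windows["64-cell"] == (104, 200)

    def test_single_cell_stage_wave_ends_at_its_division(self):
        log = pd.DataFrame(
            [
                {"cell_id": 1, "stage": "64-cell", "division_time": 10},
                {"cell_id": 2, "stage": "512-cell", "division_time": 50},
            ]
        )
        clock = dynamics.developmental_clock(log)
        assert clock.wave_windows["64-cell"] == (10, 10)

    def test_missing_reference_stage_rejected(self):
        log = self.log()
        with pytest.raises(ValueError, match="missing"):
            dynamics.developmental_clock(log[log.stage != "64-cell"])


class TestNearestCentroidTracks:
    def test_static_series_keeps_identities(self):
        vol = phantoms.make_prism_lattice(3, 3, cell_xy=8, height=10)
        maps = dynamics.nearest_centroid_tracks([vol, vol, vol])
        assert maps[0] == maps[1] == maps[2]
        assert set(maps[0]) == set(vol.labels())

    def test_relabelled_frame_is_re_identified(self):
        import numpy as np
        from scutoid3d.volume_io import LabelVolume

        vol = phantoms.make_prism_lattice(3, 3, cell_xy=8, height=10)
        perm = np.array([0, 9, 8, 7, 6, 5, 4, 3, 2, 1])  # reverse labels
        relabelled = LabelVolume(perm[vol.voxels], vol.spacing)
        maps = dynamics.nearest_centroid_tracks([vol, relabelled])
        # the same physical cell keeps its track id across the relabelling
        for label, track in maps[0].items():
            assert maps[1][int(perm[label])] == track

    def test_new_cell_opens_a_new_track(self):
        import numpy as np
        from scutoid3d.volume_io import LabelVolume

        a = phantoms.make_prism_lattice(2, 1, cell_xy=8, height=10)
        vox = a.voxels.copy()
        vox[:, :, :4] = 3  # split cell 1's left half into a new cell
        b = LabelVolume(vox, a.spacing)
        maps = dynamics.nearest_centroid_tracks([a, b], max_distance=6.0)
        assert maps[1][2] == maps[0][2]
        assert len(set(maps[1].values())) == 3
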