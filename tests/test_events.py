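import numpy as np
import pytest

from nucdyn import (
    EventConfig,
    MovementEvent,
    RecordingSet,
    SimulationConfig,
    align_events_to_onset,
    compute_kinematics,
    detect_all,
    detect_basal_persistent,
    detect_directional_segments,
    detect_oscillations,
    detect_rapid_apical,
    simulate_cohort,
    summarize_events,
)

from conftest import make_traj, single_track_recording


def _slope_track(slopes_per_interval, z0=50.0):
    """Build a track from per-interval velocities (um/min) at delta_t=10."""
    dz = 10.0 * np.asarray(slopes_per_interval, dtype=float)
    return make_traj(np.concatenate([[z0], z0 + np.cumsum(dz)]))


class TestDirectionalSegments:
    def _detect(self, slopes, persist_min=60.0):
        traj = _slope_track(slopes)
        kin = compute_kinematics(traj, window=1)  # raw velocity as smoothed
        return detect_directional_segments(kin, traj, persist_min)

    def test_six_negative_intervals_is_one_apical_event(self):
        events = self._detect([-0.2] * 6)
        assert [e.event_class for e in events] == ["directional_apical"]
        assert events[0].duration == pytest.approx(60.0)
        assert events[0].net_displacement == pytest.approx(-12.0)

    def test_five_intervals_is_below_persistence_criterion(self):
        assert self._detect([-0.2] * 5) == []

    def test_sign_change_splits_apical_then_basal(self):
        events = self._detect([-0.2] * 6 + [0.2] * 6)
        assert [e.event_class for e in events] == [
            "directional_apical", "directional_basal"
        ]
        assert events[0].end_frame == events[1].start_frame == 6

    def test_zero_velocity_breaks_runs(self):
        events = self._detect([-0.2] * 5 + [0.0] + [-0.2] * 5)
        assert events == []

    def test_interruption_tolerance_merges_runs(self):
        traj = _slope_track([-0.2] * 4 + [0.1] + [-0.2] * 4)
        kin = compute_kinematics(traj, window=1)
        assert detect_directional_segments(kin, traj, 60.0) == []
        merged = detect_directional_segments(
            kin, traj, 60.0, max_interruption=1
        )
        assert len(merged) == 1
        assert merged[0].event_class == "directional_apical"


class TestRapidApical:
    def test_embedded_run_yields_one_merged_event(self, rapid_traj):
        kin = compute_kinematics(rapid_traj)
        events = detect_rapid_apical(rapid_traj, kin)
        assert len(events) == 1
        assert events[0].net_displacement == pytest.approx(-30.0)

    def test_slow_run_below_displacement_threshold(self):
        traj = _slope_track([0.0] * 5 + [-0.2] * 6 + [0.0] * 5)
        events = detect_rapid_apical(traj, compute_kinematics(traj))
        assert events == []

    def test_threshold_is_inclusive(self):
        z = np.concatenate([np.full(6, 50.0), [47.0, 43.0, 40.0],
                            np.full(5, 40.0)])
        traj = make_traj(z)
        assert len(detect_rapid_apical(traj, compute_kinematics(traj))) == 1

    def test_just_under_threshold_is_not_an_event(self):
        z = np.concatenate([np.full(6, 50.0), [47.0, 43.0, 40.01],
                            np.full(5, 40.01)])
        traj = make_traj(z)
        assert detect_rapid_apical(traj, compute_kinematics(traj)) == []

    def test_landmarks_ordered_and_bracket_peak(self, rapid_traj):
        kin = compute_kinematics(rapid_traj)
        ev = detect_rapid_apical(rapid_traj, kin)[0]
        assert ev.onset_frame <= ev.peak_frame <= ev.cessation_frame
        # peak sits inside the constant-velocity run (frames 10..16)
        assert 9 <= ev.peak_frame <= 16

    def test_no_events_in_pure_diffusion(self):
        """False-positive rate below 1 per 10,000 recording min for a
        diffusive cohort at D = 0.05 um^2/min."""
        cfg = SimulationConfig(
            seed=20260921, n_tracks=60, diffusion_D=0.05,
            rapid_event_rate=0.0, basal_event_rate=0.0,
        )
        recording, _ = simulate_cohort(cfg)
        n_fp = 0
        for traj in recording:
            n_fp += len(detect_rapid_apical(traj, compute_kinematics(traj)))
        assert n_fp / recording.cumulative_recording_min <= 1.0 / 10_000

    def test_full_recall_on_strong_scripted_events(self):
        """Every scripted run at >= 0.5 um/min for 60 min over a weak
        diffusive background is recovered."""
        cfg = SimulationConfig(
            seed=20260921, n_tracks=50, diffusion_D=0.02,
            rapid_event_rate=0.0, basal_event_rate=0.0,
            scripted_rapid_tracks=50, rapid_speed_range=(0.5, 1.2),
            depth_init_range=(80.0, 100.0),
        )
        recording, truth = simulate_cohort(cfg)
        for traj in recording:
            events = detect_rapid_apical(traj, compute_kinematics(traj))
            (true_ev,) = [r for r in truth.for_track(traj.track_id)
                          if r.regime == "rapid_apical"]
            assert any(
                e.start_frame < true_ev.end_frame
                and e.end_frame > true_ev.start_frame
                for e in events
            )


class TestBasalPersistent:
    def test_exact_threshold_event(self):
        traj = _slope_track([0.125] * 12)
        events = detect_basal_persistent(traj)
        assert len(events) == 1
        assert events[0].net_displacement == pytest.approx(15.0)
        assert events[0].duration == pytest.approx(120.0)

    def test_below_displacement_threshold(self):
        z = np.concatenate(
            [[10.0], 10.0 + 14.0 / 12 * np.arange(1, 13), np.full(5, 24.0)]
        )
        assert detect_basal_persistent(make_traj(z)) == []

    def test_long_drift_merges_to_single_event(self):
        traj = _slope_track([0.125] * 24)
        events = detect_basal_persistent(traj)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (0, 24)
        assert events[0].duration == pytest.approx(240.0)

    def test_short_track_returns_nothing(self):
        assert detect_basal_persistent(make_traj([0.0, 20.0, 40.0])) == []


def _ev(cls, start, end, track="t"):
    return MovementEvent(cls, track, start, end,
                         -20.0 if "apical" in cls else 20.0,
                         (end - start) * 10.0, 50.0,
                         onset_frame=start if cls == "rapid_apical" else None,
                         cessation_frame=end if cls == "rapid_apical" else None)


class TestOscillations:
    def test_full_cycle(self):
        events = [_ev("rapid_apical", 0, 6), _ev("basal_persistent", 6, 24),
                  _ev("rapid_apical", 24, 30)]
        osc = detect_oscillations(events)
        assert len(osc) == 1
        assert (osc[0].start_frame, osc[0].end_frame) == (0, 30)

    def test_incomplete_cycle(self):
        events = [_ev("rapid_apical", 0, 6), _ev("basal_persistent", 6, 24)]
        assert detect_oscillations(events) == []

    def test_greedy_chaining(self):
        events = [_ev("rapid_apical", 0, 6), _ev("basal_persistent", 6, 24),
                  _ev("rapid_apical", 24, 30),
                  _ev("basal_persistent", 30, 48),
                  _ev("rapid_apical", 48, 54)]
        assert len(detect_oscillations(events)) == 2

    def test_count_bounded_by_rapid_count(self):
        cfg = SimulationConfig(
            seed=99, n_tracks=40, diffusion_D=0.03,
            rapid_event_rate=3.0, basal_event_rate=3.0,
            rapid_speed_range=(0.5, 1.0), depth_init_range=(80.0, 120.0),
        )
        recording, _ = simulate_cohort(cfg)
        for traj in recording:
            events = detect_all(single_track_recording(traj))
            n_rapid = sum(e.event_class == "rapid_apical" for e in events)
            n_osc = sum(e.event_class == "oscillation" for e in events)
            assert n_osc <= max(0, n_rapid - 1)


class TestEventWindowsDisjoint:
    def test_no_overlap_within_class_after_merging(self):
        cfg = SimulationConfig(
            seed=7, n_tracks=30, diffusion_D=0.05,
            rapid_event_rate=2.0, basal_event_rate=2.0,
            depth_init_range=(60.0, 120.0),
        )
        recording, _ = simulate_cohort(cfg)
        for traj in recording:
            events = detect_all(single_track_recording(traj))
            for cls in ("rapid_apical", "basal_persistent"):
                spans = sorted(
                    (e.start_frame, e.end_frame) for e in events
                    if e.event_class == cls
                )
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 <= s2


class TestSummarize:
    def test_normalization_formula(self):
        traj = make_traj(np.full(51, 30.0))  # 500 recording min
        rec = single_track_recording(traj)
        events = [_ev("rapid_apical", 0, 6, track=traj.track_id)]
        summary = summarize_events(events, rec)
        assert summary.normalized_counts["rapid_apical"] == pytest.approx(2.0)

    def test_no_events_all_rates_zero(self, flat_traj):
        summary = summarize_events([], single_track_recording(flat_traj))
        assert all(v == 0.0 for v in summary.normalized_counts.values())

    def test_depth_binning_left_closed(self):
        traj = make_traj(np.full(51, 30.0))
        rec = single_track_recording(traj)
        events = [
            MovementEvent("rapid_apical", traj.track_id, i, i + 3,
                          -12.0, 30.0, depth)
            for i, depth in enumerate((44.0, 47.0, 52.0))
        ]
        summary = summarize_events(events, rec, depth_bin=5.0)
        assert set(summary.start_depth_histogram) == {40.0, 45.0, 50.0}
        assert sum(summary.start_depth_histogram.values()) == pytest.approx(
            summary.normalized_counts["rapid_apical"]
        )

    def test_rates_scale_inversely_with_recording_time(self, flat_traj):
        events = [_ev("rapid_apical", 0, 6, track=flat_traj.track_id)]
        short = summarize_events(
            events, single_track_recording(flat_traj)
        )
        doubled = RecordingSet(
            (flat_traj, make_traj(flat_traj.z, track_id="other")), 10.0
        )
        long = summarize_events(events, doubled)
        assert short.normalized_counts["rapid_apical"] == pytest.approx(
            2 * long.normalized_counts["rapid_apical"]
        )

    def test_zero_recording_time_is_division_error(self):
        with pytest.raises(ZeroDivisionError):
            summarize_events(
                [], RecordingSet((), 10.0)
            )


class TestAlignToOnset:
    def test_rebased_to_origin(self, rapid_traj):
        rec = single_track_recording(rapid_traj)
        events = detect_rapid_apical(rapid_traj, compute_kinematics(rapid_traj))
        aligned = align_events_to_onset(events, rec)
        onset_col = np.flatnonzero(aligned.offsets_min == 0.0)[0]
        assert aligned.depths[0, onset_col] == 0.0

    def test_identical_events_identical_traces(self, rapid_traj):
        twin = make_traj(rapid_traj.z, track_id="twin")
        rec = RecordingSet((rapid_traj, twin), 10.0)
        events = []
        for traj in rec:
            events += detect_rapid_apical(traj, compute_kinematics(traj))
        aligned = align_events_to_onset(events, rec)
        np.testing.assert_array_equal(aligned.depths[0], aligned.depths[1])

    def test_events_without_onset_are_skipped(self, rapid_traj):
        rec = single_track_recording(rapid_traj)
        ev = MovementEvent("rapid_apical", rapid_traj.track_id, 0, 6,
                           -20.0, 60.0, 50.0)
        aligned = align_events_to_onset([ev], rec)
        assert aligned.n_skipped == 1

    def test_mean_aligned_slope_matches_scripted_speed(self):
        """Cohort of -0.5 um/min 60-min runs: the mean onset-aligned trace
        falls at the scripted speed through the event interior."""
        cfg = SimulationConfig(
            seed=20260921, n_tracks=40, diffusion_D=0.005,
            rapid_event_rate=0.0, basal_event_rate=0.0,
            scripted_rapid_tracks=40, rapid_speed_range=(0.5, 0.5),
            depth_init_range=(80.0, 100.0),
        )
        recording, _ = simulate_cohort(cfg)
        events = [
            e for traj in recording
            for e in detect_rapid_apical(traj, compute_kinematics(traj))
        ]
        aligned = align_events_to_onset(events, recording)
        mean_trace = np.nanmean(aligned.depths, axis=0)
        i10 = np.flatnonzero(aligned.offsets_min == 10.0)[0]
        i50 = np.flatnonzero(aligned.offsets_min == 50.0)[0]
        slope = (mean_trace[i50] - mean_trace[i10]) / 40.0
        assert slope == pytest.approx(-0.5, abs=0.05)
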