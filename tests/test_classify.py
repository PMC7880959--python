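import numpy as np
import pytest

from gazevents import (Chunk, ClassifierParams, GazeEvent, chunk_recording,
                       classify_pso, classify_pursuit_fixation,
                       classify_recording, compute_event_properties,
                       find_saccade_bounds)
from gazevents.metrics import collapse_labels
from gazevents.synthgaze import demo_script, generate_recording

from conftest import make_series, make_velocity


class TestChunkRecording:
    def test_two_bursts_three_chunks(self):
        v = np.zeros(10000)
        v[2000:2010] = 100.0
        v[6000:6010] = 100.0
        v[0] = np.nan
        chunks, peaks = chunk_recording(make_velocity(v), ClassifierParams())
        assert len(peaks) == 2
        assert len(chunks) == 3
        assert all(2000 <= peaks[0] < 2010 for _ in [0])
        # chunks tile the recording
        assert chunks[0].start_index == 0
        assert chunks[-1].end_index == len(v)
        for a, b in zip(chunks[:-1], chunks[1:]):
            assert a.end_index == b.start_index

    def test_flat_velocity_single_chunk(self):
        v = np.full(5000, 5.0)
        chunks, peaks = chunk_recording(make_velocity(v), ClassifierParams())
        assert peaks == []
        assert len(chunks) == 1
        assert (chunks[0].start_index, chunks[0].end_index) == (0, 5000)

    def test_frequency_cap(self):
        # 10 s at 1000 Hz with 50 candidate bursts, cap 2 Hz -> at most 20
        v = np.zeros(10000)
        for i in range(50):
            v[i * 200 + 50:i * 200 + 55] = 50.0 + i
        chunks, peaks = chunk_recording(make_velocity(v), ClassifierParams())
        assert len(peaks) == 20
        # greedy by weight: the heaviest bursts (largest i) were kept
        assert min(peaks) > 30 * 200

    def test_all_masked_single_chunk(self):
        v = np.full(1000, np.nan)
        with pytest.warns(UserWarning):
            chunks, peaks = chunk_recording(make_velocity(v),
                                            ClassifierParams())
        assert len(chunks) == 1 and peaks == []


class TestFindSaccadeBounds:
    def test_triangular_pulse(self):
        v = np.concatenate([np.zeros(10), [25, 50, 75, 100, 75, 50, 25],
                            np.zeros(10)])
        b = find_saccade_bounds(make_velocity(v), 13, 20.0)
        assert b.onset_index == 9 and b.offset_index == 17
        assert not b.clamped_onset and not b.clamped_offset

    def test_peak_at_edge_clamped(self):
        v = np.concatenate([[80.0, 100.0], 100 - np.arange(20) * 5.0])
        b = find_saccade_bounds(make_velocity(v), 1, 20.0)
        assert b.onset_index == 0 and b.clamped_onset

    def test_merged_pulses_skip_high_minimum(self):
        v = np.concatenate([np.zeros(5), [30, 100, 30, 25, 30, 90, 30],
                            np.zeros(5)])
        b = find_saccade_bounds(make_velocity(v), 6, 20.0)
        # the intermediate minimum (25) exceeds the threshold and is skipped
        assert b.offset_index == 12

    def test_stops_at_missing_data(self):
        v = np.concatenate([np.zeros(5), [np.nan], [30, 100, 30],
                            np.zeros(5)])
        b = find_saccade_bounds(make_velocity(v), 7, 20.0)
        assert b.onset_index == 6 and b.clamped_onset


def _pso_setup(tail):
    """A saccade event ending at sample 20 followed by `tail` velocities."""
    v = np.concatenate([np.zeros(5), [30, 200, 30, 5], np.zeros(11),
                        tail, np.zeros(60)])
    vel = make_velocity(v)
    series = make_series(np.zeros(len(v)))
    sacc = GazeEvent(label="SACC", onset_time=0.005, offset_time=0.020,
                     start_x=0, start_y=0, end_x=0, end_y=0, amplitude=0,
                     peak_vel=200, median_vel=30, avg_vel=50,
                     onset_index=5, offset_index=20)
    return vel, series, sacc


class TestClassifyPso:
    def test_low_velocity_pso(self):
        vel, series, sacc = _pso_setup([5, 25, 30, 25, 5.0])
        pso = classify_pso(vel, sacc, 20.0, 100.0, ClassifierParams(),
                           series)
        assert pso is not None and pso.label == "LPSO"
        assert pso.onset_index == sacc.offset_index

    def test_high_velocity_pso(self):
        vel, series, sacc = _pso_setup([5, 110, 120, 30, 5.0])
        pso = classify_pso(vel, sacc, 20.0, 100.0, ClassifierParams(),
                           series)
        assert pso is not None and pso.label == "HPSO"

    def test_intra_chunk_labels(self):
        vel, series, sacc = _pso_setup([5, 25, 30, 25, 5.0])
        sacc.label = "ISAC"
        pso = classify_pso(vel, sacc, 20.0, 100.0, ClassifierParams(),
                           series)
        assert pso.label == "ILPS"

    def test_late_recrossing_ignored(self):
        # re-crossing 50 ms after offset is outside the 0.04 s window
        v = np.concatenate([np.zeros(21), np.zeros(50), [30, 40, 30],
                            np.zeros(10)])
        vel = make_velocity(v)
        series = make_series(np.zeros(len(v)))
        sacc = GazeEvent("SACC", 0.005, 0.020, 0, 0, 0, 0, 0, 200, 30, 50,
                         onset_index=5, offset_index=20)
        assert classify_pso(vel, sacc, 20.0, 100.0, ClassifierParams(),
                            series) is None

    def test_monotone_decay_no_pso(self):
        vel, series, sacc = _pso_setup([5, 4, 3, 2, 1.0])
        assert classify_pso(vel, sacc, 20.0, 100.0, ClassifierParams(),
                            series) is None

    def test_duration_capped_at_window(self):
        vel, series, sacc = _pso_setup(np.full(60, 50.0))
        pso = classify_pso(vel, sacc, 20.0, 100.0, ClassifierParams(),
                           series)
        p = ClassifierParams()
        assert pso.duration <= p.max_pso_duration + 1e-9


class TestClassifyPursuitFixation:
    def _run(self, x_step_px, n=1000, fs=1000.0):
        x = np.arange(n) * x_step_px
        series = make_series(x, fs=fs)
        from gazevents import compute_velocity, PreprocessParams
        vel = compute_velocity(series, PreprocessParams())
        return classify_pursuit_fixation(vel, Chunk(0, n), series,
                                         ClassifierParams())

    def test_constant_drift_pursuit(self):
        # 0.5 px/sample = 5 deg/s > 2 deg/s threshold
        events = self._run(0.5)
        assert [e.label for e in events] == ["PURS"]

    def test_slow_drift_fixation(self):
        # 0.05 px/sample = 0.5 deg/s < 2 deg/s threshold
        events = self._run(0.05)
        assert [e.label for e in events] == ["FIXA"]

    def test_short_gap_no_event(self):
        events = self._run(0.05, n=30)  # 30 ms < min_fixation_duration
        assert events == []

    def test_short_segment_falls_back_unfiltered(self):
        # 8 samples at 100 Hz: above the fixation minimum but below the
        # zero-phase filter's stable length
        with pytest.warns(UserWarning, match="too short"):
            events = self._run(5.0, n=8, fs=100.0)
        assert [e.label for e in events] == ["PURS"]


class TestComputeEventProperties:
    def test_amplitude_345_triangle(self):
        x = np.array([0.0, 100, 200, 300, 300])
        y = np.array([0.0, 150, 300, 400, 400])
        series = make_series(x, y)
        vel = make_velocity([np.nan, 10, 20, 90, 1])
        ev = compute_event_properties("SACC", 0, 3, series, vel)
        assert ev.amplitude == pytest.approx(5.0)
        assert (ev.start_x, ev.start_y) == (0, 0)
        assert (ev.end_x, ev.end_y) == (300, 400)

    def test_velocity_summaries(self):
        series = make_series(np.zeros(5))
        vel = make_velocity([np.nan, 10, 20, 90, 1])
        ev = compute_event_properties("SACC", 0, 3, series, vel)
        assert ev.peak_vel == 90 and ev.median_vel == 20 and ev.avg_vel == 40

    def test_single_sample_velocity(self):
        series = make_series(np.zeros(4))
        vel = make_velocity([np.nan, 42.0, 1, 1])
        ev = compute_event_properties("ISAC", 0, 1, series, vel)
        assert ev.peak_vel == ev.median_vel == ev.avg_vel == 42.0

    def test_all_masked_dropped(self):
        series = make_series(np.full(6, np.nan))
        vel = make_velocity(np.full(6, np.nan))
        with pytest.warns(UserWarning, match="masked"):
            assert compute_event_properties("FIXA", 1, 4, series, vel) is None


class TestClassifyRecording:
    def test_deterministic(self):
        series, _ = generate_recording(demo_script(seed=4))
        sub = series.slice(0, 15000)
        e1 = classify_recording(sub)
        e2 = classify_recording(sub)
        assert [(e.label, e.onset_index, e.offset_index) for e in e1] == \
               [(e.label, e.onset_index, e.offset_index) for e in e2]

    def test_all_missing_empty(self):
        s = make_series(np.full(500, np.nan))
        with pytest.warns(UserWarning):
            assert classify_recording(s) == []

    def test_events_sorted_nonoverlapping_in_span(self):
        series, _ = generate_recording(demo_script(seed=5))
        events = classify_recording(series)
        assert len(events) > 5
        prev_end = 0
        for e in events:
            assert e.onset_index >= prev_end
            assert e.offset_index > e.onset_index
            prev_end = e.offset_index
        assert events[-1].offset_index <= series.n_samples

    def test_pursuit_threshold_monotonicity(self):
        series, _ = generate_recording(demo_script(seed=6))
        totals = []
        for thresh in (2.0, 4.0, 8.0):
            events = classify_recording(
                series, ClassifierParams(pursuit_velthresh=thresh))
            totals.append(sum(e.duration for e in events
                              if e.label == "PURS"))
        assert totals[0] >= totals[1] >= totals[2]

    def test_noise_factor_monotonicity(self):
        from gazevents import ThresholdParams
        series, _ = generate_recording(demo_script(seed=7, noise_sd=0.5))
        counts = []
        for f in (5.0, 8.0, 12.0):
            events = classify_recording(
                series, ClassifierParams(threshold=ThresholdParams(
                    noise_factor=f)))
            counts.append(sum(1 for e in events
                              if collapse_labels([e.label])[0] == "SACC"))
        assert counts[0] >= counts[1] >= counts[2]
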