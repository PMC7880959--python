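import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazevents import (ClampWarning, GazeSeries, ParameterError,
                       PreprocessParams, compute_velocity, dilate_signal_loss,
                       filter_spikes, preprocess, smooth_median,
                       smooth_savgol)

from conftest import make_series


class TestFilterSpikes:
    @pytest.mark.parametrize("x, expected", [
        ([0, 0, 10, 0, 0], [0, 0, 0, 0, 0]),          # single-sample spike
        ([0, 1, 2, 3, 4], [0, 1, 2, 3, 4]),           # monotone ramp
        ([0, 0, 10, 10, 0, 0], [0, 0, 10, 10, 0, 0]),  # two-sample excursion
    ])
    def test_replacement_rule(self, x, expected):
        out = filter_spikes(make_series(x))
        assert np.allclose(out.x, expected)

    def test_axes_independent(self):
        s = make_series([0, 0, 10, 0, 0], y=[0, 1, 2, 3, 4])
        out = filter_spikes(s)
        assert np.allclose(out.x, 0)
        assert np.allclose(out.y, s.y)

    def test_short_series_unchanged(self):
        s = make_series([0, 5])
        out = filter_spikes(s)
        assert np.allclose(out.x, s.x)

    def test_missing_markers_untouched(self):
        s = make_series([0, np.nan, 0, 10, 0])
        out = filter_spikes(s)
        assert np.isnan(out.x[1])


class TestDilateSignalLoss:
    def test_long_run_dilated(self):
        x = np.zeros(200)
        x[100:130] = np.nan  # 30 ms at 1000 Hz
        out = dilate_signal_loss(make_series(x), PreprocessParams())
        assert int(np.isnan(out.x).sum()) == 50  # 30 + 2 x 10 samples

    def test_short_run_untouched(self):
        x = np.zeros(200)
        x[100:115] = np.nan  # 15 ms < min_blink_duration (0.02 s)
        out = dilate_signal_loss(make_series(x), PreprocessParams())
        assert int(np.isnan(out.x).sum()) == 15

    def test_noop_without_missing(self):
        s = make_series(np.arange(50.0))
        out = dilate_signal_loss(s, PreprocessParams())
        assert np.array_equal(out.x, s.x)

    def test_clipping_at_bounds(self):
        x = np.zeros(40)
        x[:25] = np.nan
        out = dilate_signal_loss(make_series(x), PreprocessParams())
        assert int(np.isnan(out.x).sum()) == 35

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.booleans(), min_size=2, max_size=300))
    def test_idempotent_and_never_unmasks(self, mask):
        x = np.arange(len(mask), dtype=float)
        x[np.asarray(mask, dtype=bool)] = np.nan
        params = PreprocessParams()
        once = dilate_signal_loss(make_series(x), params)
        twice = dilate_signal_loss(once, params)
        assert np.array_equal(np.isnan(once.x), np.isnan(twice.x))
        assert np.all(np.isnan(once.x[np.asarray(mask, dtype=bool)]))


class TestSmoothMedian:
    def params(self, window_s):
        return PreprocessParams(median_filter_length=window_s)

    def test_constant_unchanged(self):
        out = smooth_median(make_series(np.full(20, 7.0)), self.params(0.005))
        assert np.allclose(out.x, 7.0)

    def test_single_outlier_removed(self):
        out = smooth_median(make_series([0, 0, 9, 0, 0]), self.params(0.003))
        assert np.allclose(out.x, 0.0)

    def test_step_preserved(self):
        out = smooth_median(make_series([0, 0, 0, 5, 5, 5]),
                            self.params(0.003))
        assert np.allclose(out.x, [0, 0, 0, 5, 5, 5])

    def test_window_longer_than_series(self):
        with pytest.raises(ParameterError):
            smooth_median(make_series(np.zeros(10)), self.params(0.05))


class TestSmoothSavgol:
    def test_constant_unchanged(self):
        out = smooth_savgol(make_series(np.full(60, 3.0)), PreprocessParams())
        assert np.allclose(out.x, 3.0)

    def test_quadratic_reproduced(self):
        t = np.arange(100, dtype=float)
        x = 0.02 * t ** 2 - 0.5 * t + 3
        out = smooth_savgol(make_series(x), PreprocessParams())
        assert np.allclose(out.x, x, atol=1e-8)

    def test_noise_variance_reduced(self, rng):
        x = rng.normal(0, 1, 2000)
        out = smooth_savgol(make_series(x), PreprocessParams())
        assert np.var(out.x) < np.var(x)

    def test_polyorder_error(self):
        with pytest.raises(ParameterError):
            smooth_savgol(make_series(np.zeros(100), fs=100.0),
                          PreprocessParams(savgol_length=0.01,
                                           savgol_polyord=5))


class TestComputeVelocity:
    def test_constant_position_zero(self):
        v = compute_velocity(make_series(np.full(50, 3.0)), PreprocessParams())
        assert np.allclose(v.v[1:], 0.0)
        assert np.isnan(v.v[0])

    def test_linear_motion(self):
        v = compute_velocity(make_series(np.arange(100.0)), PreprocessParams())
        assert np.allclose(v.v[1:], 10.0)  # 1 px/sample * 0.01 deg * 1000 Hz

    def test_clamp_with_warning(self):
        x = np.zeros(50)
        x[25:] = 200.0  # one 200 px jump = 2000 deg/s
        with pytest.warns(ClampWarning):
            v = compute_velocity(make_series(x), PreprocessParams())
        assert v.v[25] == 1000.0

    def test_masked_neighbors(self):
        x = np.arange(20.0)
        x[10] = np.nan
        v = compute_velocity(make_series(x), PreprocessParams())
        assert np.isnan(v.v[10]) and np.isnan(v.v[11])
        assert np.isfinite(v.v[9])

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 5, 200).cumsum()
        y = rng.normal(0, 5, 200).cumsum()
        p = PreprocessParams()
        v1 = compute_velocity(make_series(x, y), p)
        v2 = compute_velocity(make_series(x + 1234.5, y - 987.1), p)
        assert np.allclose(v1.v[1:], v2.v[1:], atol=1e-6)

    def test_invalid_metadata(self):
        with pytest.raises(ParameterError):
            GazeSeries(np.zeros(10), np.zeros(10), -1.0, 0.01)
        with pytest.raises(ParameterError):
            GazeSeries(np.zeros(10), np.zeros(10), 1000.0, 0.0)


class TestPipeline:
    def test_streams_match_manual_composition(self, rng):
        x = rng.normal(0, 1, 1500).cumsum() + 500
        y = rng.normal(0, 1, 1500).cumsum() + 400
        x[700:740] = np.nan
        y[700:740] = np.nan
        s = GazeSeries(x, y, 1000.0, 0.01)
        p = PreprocessParams()
        streams = preprocess(s, p)
        manual = dilate_signal_loss(filter_spikes(s), p)
        v_med = compute_velocity(smooth_median(manual, p), p)
        v_sg = compute_velocity(smooth_savgol(manual, p), p)
        assert np.array_equal(streams.chunk_velocity.v, v_med.v,
                              equal_nan=True)
        assert np.array_equal(streams.velocity.v, v_sg.v, equal_nan=True)

    def test_masked_samples_never_finite(self):
        x = np.zeros(300)
        x[100:150] = np.nan
        streams = preprocess(GazeSeries(x, x.copy(), 1000.0, 0.01))
        assert np.all(np.isnan(streams.velocity.v[100:150]))
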