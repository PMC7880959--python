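"""Preprocessing of raw gaze coordinate time series.

Turns pixel coordinate traces into angular velocity streams suitable for
event classification.  The pipeline order is fixed:

    spike removal -> signal-loss dilation -> smoothing -> velocity -> clamping

Two smoothed streams are produced from the same input: a heavily
median-filtered stream that emphasizes large-amplitude saccades (used for
coarse chunking of the recording) and a Savitzky-Golay-filtered stream on
which all event classification is performed.

Missing samples (signal loss, e.g. during blinks) are carried as NaN.
Smoothing never interpolates across missing data: windows that touch a
missing sample propagate the marker instead of fabricating gaze positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

__all__ = [
    "GazeSeries",
    "VelocitySeries",
    "PreprocessParams",
    "ParameterError",
    "ClampWarning",
    "filter_spikes",
    "dilate_signal_loss",
    "smooth_median",
    "smooth_savgol",
    "compute_velocity",
    "preprocess",
]


class ParameterError(ValueError):
    """A parameter value is invalid for the data at hand."""


class ClampWarning(UserWarning):
    """Velocities exceeded the physiological maximum and were clamped."""


@dataclass
class GazeSeries:
    """Paired X/Y gaze coordinate traces with sampling metadata.

    Parameters
    ----------
    x, y
        Per-sample screen coordinates in pixels.  Missing samples are NaN
        and must be marked identically in both axes (enforced on
        construction by masking the union).
    sampling_rate
        Sampling frequency in Hz.
    px2deg
        Visual degrees subtended by a single (square) pixel.
    loss_mask
        Boolean mask of the *original* signal-loss samples.  Kept separate
        from the NaN markers so that signal-loss dilation is idempotent:
        dilation margins are always derived from this mask, never from
        previously dilated data.  Defaults to the missing samples at
        construction time.
    """

    x: np.ndarray
    y: np.ndarray
    sampling_rate: float
    px2deg: float
    loss_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).copy()
        self.y = np.asarray(self.y, dtype=float).copy()
        if self.x.ndim != 1 or self.y.ndim != 1 or len(self.x) != len(self.y):
            raise ParameterError("x and y must be 1-D arrays of identical length")
        if len(self.x) < 2:
            raise ParameterError("a gaze series needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        if not self.px2deg > 0:
            raise ParameterError("px2deg must be positive")
        # missing samples are marked identically in x and y
        miss = ~np.isfinite(self.x) | ~np.isfinite(self.y)
        self.x[miss] = np.nan
        self.y[miss] = np.nan
        if self.loss_mask is None:
            self.loss_mask = miss
        else:
            self.loss_mask = np.asarray(self.loss_mask, dtype=bool).copy()
            if len(self.loss_mask) != len(self.x):
                raise ParameterError("loss_mask length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of currently missing (NaN) samples."""
        return ~np.isfinite(self.x) | ~np.isfinite(self.y)

    def replace_coords(self, x: np.ndarray, y: np.ndarray) -> "GazeSeries":
        return GazeSeries(x, y, self.sampling_rate, self.px2deg,
                          loss_mask=self.loss_mask)

    def slice(self, start: int, stop: int) -> "GazeSeries":
        """Sub-series over the half-open sample range [start, stop)."""
        return GazeSeries(self.x[start:stop], self.y[start:stop],
                          self.sampling_rate, self.px2deg,
                          loss_mask=self.loss_mask[start:stop])


@dataclass
class VelocitySeries:
    """Per-sample angular speed in deg/s aligned to its source GazeSeries.

    ``v[i]`` is the speed of the displacement from sample ``i-1`` to sample
    ``i`` (forward difference assigned to the later sample); the first
    sample has no predecessor and is masked.  Masked samples are NaN.
    """

    v: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)

    def __len__(self) -> int:
        return len(self.v)

    @property
    def mask(self) -> np.ndarray:
        """True where the velocity is undefined (missing data)."""
        return ~np.isfinite(self.v)

    @property
    def finite(self) -> np.ndarray:
        """The finite velocity values (masked samples dropped)."""
        return self.v[np.isfinite(self.v)]


@dataclass
class PreprocessParams:
    """Preprocessing parameters, in order of application.

    Durations are seconds, velocities deg/s.  Defaults follow the
    standard parameterization of the algorithm.
    """

    min_blink_duration: float = 0.02
    dilate_nan: float = 0.01
    median_filter_length: float = 0.05
    savgol_length: float = 0.019
    savgol_polyord: int = 2
    max_vel: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("min_blink_duration", "dilate_nan",
                     "median_filter_length", "savgol_length"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.savgol_polyord < 0:
            raise ParameterError("savgol_polyord must be >= 0")
        if not self.max_vel > 0:
            raise ParameterError("max_vel must be positive")


def _n_samples(duration: float, sampling_rate: float) -> int:
    return int(round(duration * sampling_rate))


def _odd_window(duration: float, sampling_rate: float) -> int:
    """Seconds -> odd sample count (round, then add one if even)."""
    n = _n_samples(duration, sampling_rate)
    if n % 2 == 0:
        n += 1
    return max(n, 1)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) extents of contiguous True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _despike_axis(a: np.ndarray) -> np.ndarray:
    """Single-sample spike removal on one coordinate axis.

    A sample is a spike iff it is a strict local extremum and its distance
    to each neighbor exceeds the distance between the neighbors.  It is
    replaced by the value of the nearer neighbor (previous neighbor on a
    tie).  Comparisons involving NaN are false, so missing samples and
    their neighbors are untouched.
    """
    if len(a) < 3:
        return a.copy()
    out = a.copy()
    left, mid, right = a[:-2], a[1:-1], a[2:]
    with np.errstate(invalid="ignore"):
        d_left = np.abs(mid - left)
        d_right = np.abs(mid - right)
        d_nbrs = np.abs(right - left)
        extremum = ((mid > left) & (mid > right)) | ((mid < left) & (mid < right))
        spike = extremum & (d_left > d_nbrs) & (d_right > d_nbrs)
        use_right = d_right < d_left
    idx = np.flatnonzero(spike) + 1
    out[idx] = np.where(use_right[idx - 1], a[idx + 1], a[idx - 1])
    return out


def filter_spikes(series: GazeSeries) -> GazeSeries:
    """Remove single-sample coordinate spikes, independently per axis.

    Series shorter than 3 samples are returned unchanged (no neighbors to
    compare).
    """
    if series.n_samples < 3:
        return series.replace_coords(series.x, series.y)
    return series.replace_coords(_despike_axis(series.x), _despike_axis(series.y))


def dilate_signal_loss(series: GazeSeries,
                       params: PreprocessParams) -> GazeSeries:
    """Mask margins around signal-loss windows (e.g. blink artifacts).

    Every contiguous run of originally missing samples whose duration is at
    least ``min_blink_duration`` is extended by ``dilate_nan`` seconds of
    missing markers on both sides (clipped at the series bounds).  Shorter
    runs are untouched and no sample is ever un-masked.  Dilation margins
    are derived from the original loss mask, so the operation is
    idempotent.
    """
    fs = series.sampling_rate
    min_n = _n_samples(params.min_blink_duration, fs)
    d = _n_samples(params.dilate_nan, fs)
    mask = series.missing.copy()
    n = series.n_samples
    for a, b in _bool_runs(series.loss_mask):
        if b - a >= min_n:
            mask[max(0, a - d):min(n, b + d)] = True
    x = series.x.copy()
    y = series.y.copy()
    x[mask] = np.nan
    y[mask] = np.nan
    return GazeSeries(x, y, fs, series.px2deg, loss_mask=series.loss_mask)


def _smooth_segments(series: GazeSeries, window: int, smoother) -> GazeSeries:
    """Apply ``smoother`` per contiguous finite segment, then propagate
    missing markers into the half-window flanks adjacent to gaps."""
    half = window // 2
    n = series.n_samples
    miss = series.missing
    out = {"x": series.x.copy(), "y": series.y.copy()}
    for a, b in _bool_runs(~miss):
        for key in out:
            seg = out[key][a:b]
            if len(seg) >= window:
                seg = smoother(seg)
            # windows touching missing data propagate the marker
            if a > 0:
                seg[:half] = np.nan
            if b < n:
                seg[len(seg) - half:] = np.nan
            out[key][a:b] = seg
    return series.replace_coords(out["x"], out["y"])


def smooth_median(series: GazeSeries, params: PreprocessParams) -> GazeSeries:
    """Running-median smoothing; emphasizes large-amplitude saccades."""
    window = _odd_window(params.median_filter_length, series.sampling_rate)
    if window > series.n_samples:
        raise ParameterError(
            f"median filter window ({window} samples) longer than series "
            f"({series.n_samples} samples)")
    if window == 1:
        return series.replace_coords(series.x, series.y)
    return _smooth_segments(
        series, window, lambda seg: median_filter(seg, size=window, mode="nearest"))


def smooth_savgol(series: GazeSeries, params: PreprocessParams) -> GazeSeries:
    """Savitzky-Golay least-squares polynomial smoothing."""
    window = _odd_window(params.savgol_length, series.sampling_rate)
    if params.savgol_polyord >= window:
        raise ParameterError(
            f"savgol_polyord ({params.savgol_polyord}) must be smaller than "
            f"the window length ({window} samples)")
    return _smooth_segments(
        series, window,
        lambda seg: savgol_filter(seg, window, params.savgol_polyord, mode="interp"))


def compute_velocity(series: GazeSeries,
                     params: PreprocessParams) -> VelocitySeries:
    """Per-sample angular speed in deg/s with the physiological clamp.

    Speed is the Euclidean displacement between consecutive samples scaled
    by ``px2deg * sampling_rate``.  Samples adjacent to missing data (and
    the first sample) are masked.  Values above ``max_vel`` are replaced by
    ``max_vel`` with a :class:`ClampWarning` noting potentially
    inappropriate filter settings.
    """
    if not series.px2deg > 0 or not series.sampling_rate > 0:
        raise ParameterError("px2deg and sampling_rate must be positive")
    dx = np.diff(series.x)
    dy = np.diff(series.y)
    with np.errstate(invalid="ignore"):
        v = np.hypot(dx, dy) * series.px2deg * series.sampling_rate
    v = np.concatenate([[np.nan], v])
    with np.errstate(invalid="ignore"):
        over = v > params.max_vel
    if over.any():
        warnings.warn(
            f"{int(over.sum())} velocity sample(s) exceeded max_vel="
            f"{params.max_vel} deg/s and were clamped; filter settings may "
            "be inappropriate for this recording", ClampWarning, stacklevel=2)
        v[over] = params.max_vel
    return VelocitySeries(v, series.sampling_rate)


class PreprocessedStreams(NamedTuple):
    """The two coordinate/velocity streams the classifier consumes."""

    series: GazeSeries          # Savitzky-Golay smoothed coordinates
    velocity: VelocitySeries    # velocities of the Savitzky-Golay stream
    chunk_velocity: VelocitySeries  # velocities of the median stream


def preprocess(series: GazeSeries,
               params: PreprocessParams | None = None) -> PreprocessedStreams:
    """Run the full preprocessing pipeline in its fixed order."""
    if params is None:
        params = PreprocessParams()
    series = filter_spikes(series)
    series = dilate_signal_loss(series, params)
    med = smooth_median(series, params)
    sg = smooth_savgol(series, params)
    return PreprocessedStreams(
        series=sg,
        velocity=compute_velocity(sg, params),
        chunk_velocity=compute_velocity(med, params),
    )
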