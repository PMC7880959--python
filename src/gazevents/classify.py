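"""Eye-movement event classification.

The classifier labels a gaze recording with eight event types:

========  =====================================================
label     event
========  =====================================================
FIXA      fixation
SACC      saccade that bounds an intersaccadic chunk
ISAC      saccade inside a chunk
HPSO      high-velocity post-saccadic oscillation after a SACC
IHPS      high-velocity post-saccadic oscillation after an ISAC
LPSO      low-velocity post-saccadic oscillation after a SACC
ILPS      low-velocity post-saccadic oscillation after an ISAC
PURS      smooth pursuit
========  =====================================================

Processing proceeds in stages.  A global robust threshold on a heavily
median-filtered velocity stream locates the fastest saccades, whose peaks
chunk the recording into intersaccadic intervals.  Within adaptive
contexts (a window centered on the peak for chunk-bounding saccades, the
surrounding intersaccadic interval otherwise) saccades and their
post-saccadic oscillations are classified on a Savitzky-Golay-filtered
velocity stream.  Remaining unlabeled stretches are low-pass filtered and
split into pursuit and fixation periods.  Because velocity thresholds are
re-estimated inside every context, non-stationary noise only affects
classification locally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.signal import butter, filtfilt

from .preprocess import (GazeSeries, ParameterError, PreprocessParams,
                         VelocitySeries, _bool_runs, _n_samples, preprocess)
from .threshold import (ThresholdEstimationError, ThresholdParams,
                        derive_event_thresholds, estimate_threshold)

__all__ = [
    "ClassifierParams",
    "GazeEvent",
    "Chunk",
    "SaccadeBounds",
    "chunk_recording",
    "find_saccade_bounds",
    "classify_saccades",
    "classify_pso",
    "classify_pursuit_fixation",
    "compute_event_properties",
    "classify_recording",
    "EVENT_LABELS",
]

#: The complete event label vocabulary.
EVENT_LABELS = ("FIXA", "SACC", "ISAC", "HPSO", "IHPS", "LPSO", "ILPS", "PURS")


@dataclass
class ClassifierParams:
    """Full parameter set of the classifier (durations in s, velocities in
    deg/s, frequencies in Hz), with embedded preprocessing and threshold
    parameters."""

    min_saccade_duration: float = 0.01
    max_pso_duration: float = 0.04
    min_fixation_duration: float = 0.04
    min_pursuit_duration: float = 0.04
    min_intersaccade_duration: float = 0.04
    max_initial_saccade_freq: float = 2.0
    saccade_context_window_length: float = 1.0
    lowpass_cutoff_freq: float = 4.0
    pursuit_velthresh: float = 2.0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)

    def __post_init__(self) -> None:
        for name in ("min_saccade_duration", "max_pso_duration",
                     "min_fixation_duration", "min_pursuit_duration",
                     "min_intersaccade_duration",
                     "saccade_context_window_length"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.max_initial_saccade_freq > 0:
            raise ParameterError("max_initial_saccade_freq must be positive")
        if not self.lowpass_cutoff_freq > 0:
            raise ParameterError("lowpass_cutoff_freq must be positive")
        if not self.pursuit_velthresh > 0:
            raise ParameterError("pursuit_velthresh must be positive")


@dataclass
class GazeEvent:
    """One classified eye-movement event.

    Times are seconds from recording start; the sample range
    ``[onset_index, offset_index)`` is half-open.  ``amplitude`` is the
    straight-line distance between start and end coordinates in visual
    degrees; velocity summaries are taken over the finite in-event
    velocity samples.
    """

    label: str
    onset_time: float
    offset_time: float
    start_x: float
    start_y: float
    end_x: float
    end_y: float
    amplitude: float
    peak_vel: float
    median_vel: float
    avg_vel: float
    onset_index: int = -1
    offset_index: int = -1

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass
class Chunk:
    """Half-open sample interval between major saccades."""

    start_index: int
    end_index: int
    bounded_left: bool = False
    bounded_right: bool = False

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


class SaccadeBounds(NamedTuple):
    onset_index: int
    offset_index: int
    clamped_onset: bool
    clamped_offset: bool


# ---------------------------------------------------------------------------
# chunking

def chunk_recording(chunk_velocities: VelocitySeries,
                    params: ClassifierParams
                    ) -> tuple[list[Chunk], list[int]]:
    """Chunk the recording at the peaks of its fastest saccades.

    A single robust threshold is estimated over the whole (median-filtered)
    velocity stream.  Each maximal run of consecutive above-threshold
    samples is a candidate weighted by the sum of its velocities;
    candidates are accepted in descending weight order (ties: earlier run
    wins) until accepting another one would push the average rate above
    ``max_initial_saccade_freq``.  Chunk boundaries are the accepted runs'
    peak-velocity samples.
    """
    v = chunk_velocities.v
    n = len(v)
    duration = n / chunk_velocities.sampling_rate
    whole = [Chunk(0, n, False, False)]
    try:
        est = estimate_threshold(chunk_velocities, params.threshold)
    except ThresholdEstimationError as exc:
        warnings.warn(f"chunking threshold estimation failed ({exc}); "
                      "treating the whole recording as one chunk",
                      UserWarning, stacklevel=2)
        return whole, []
    with np.errstate(invalid="ignore"):
        above = np.isfinite(v) & (v > est.pt)
    runs = _bool_runs(above)
    if not runs:
        return whole, []
    weights = np.array([v[a:b].sum() for a, b in runs])
    starts = np.array([a for a, _ in runs])
    order = np.lexsort((starts, -weights))
    max_accept = int(np.floor(params.max_initial_saccade_freq * duration + 1e-9))
    accepted = sorted(order[:max_accept])
    peaks = sorted(int(runs[i][0] + np.argmax(v[runs[i][0]:runs[i][1]]))
                   for i in accepted)
    bounds = [0] + peaks + [n]
    chunks = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b > a:
            chunks.append(Chunk(a, b, bounded_left=i > 0,
                                bounded_right=i < len(bounds) - 2))
    return chunks, peaks


# ---------------------------------------------------------------------------
# saccade boundary search

def _is_local_min(v: np.ndarray, i: int, lo: int, hi: int) -> bool:
    """Local minimum test on [lo, hi); NaN neighbors count as +inf."""
    here = v[i]
    if not np.isfinite(here):
        return False
    left = v[i - 1] if i - 1 >= lo and np.isfinite(v[i - 1]) else np.inf
    right = v[i + 1] if i + 1 < hi and np.isfinite(v[i + 1]) else np.inf
    return here <= left and here <= right


def _walk_to_minimum(v: np.ndarray, start: int, step: int, threshold: float,
                     lo: int, hi: int) -> tuple[int, bool]:
    """Walk from ``start`` in direction ``step`` to the nearest local
    velocity minimum not exceeding ``threshold``.

    Returns ``(index, clamped)``; the walk stops (clamped) at missing data
    or at the interval edge if no qualifying minimum exists.  Local minima
    *above* the threshold are skipped (merged-event rule).
    """
    i = start
    while lo <= i < hi:
        if not np.isfinite(v[i]):
            return i - step, True
        if v[i] <= threshold and _is_local_min(v, i, lo, hi):
            return i, False
        i += step
    return (lo if step < 0 else hi - 1), True


def find_saccade_bounds(velocities: VelocitySeries, peak_index: int,
                        onset_threshold: float,
                        lo: int = 0, hi: int | None = None) -> SaccadeBounds:
    """On/offset of a saccade around a velocity peak.

    Walking outward from the peak, the bounds are the nearest local
    velocity minima whose values do not exceed ``onset_threshold``,
    restricted to the context ``[lo, hi)``.  If no qualifying minimum is
    found before the context edge or missing data, the bound is clamped
    there and flagged.
    """
    v = velocities.v
    if hi is None:
        hi = len(v)
    onset, cl_on = _walk_to_minimum(v, peak_index - 1, -1, onset_threshold, lo, hi)
    offset, cl_off = _walk_to_minimum(v, peak_index + 1, +1, onset_threshold, lo, hi)
    return SaccadeBounds(onset, offset, cl_on, cl_off)


# ---------------------------------------------------------------------------
# event property computation

def compute_event_properties(label: str, onset_index: int, offset_index: int,
                             series: GazeSeries,
                             velocities: VelocitySeries) -> GazeEvent | None:
    """Fill in coordinates, amplitude and velocity summaries for an event
    spanning the half-open sample range [onset_index, offset_index).

    Start/end coordinates come from the smoothed trace at on/offset (the
    nearest finite sample inside the event if the boundary itself is
    masked).  Returns None, with a warning, if the window is all-masked.
    """
    fs = series.sampling_rate
    n = series.n_samples
    i0, i1 = onset_index, offset_index
    xs = series.x[i0:min(i1 + 1, n)]
    ys = series.y[i0:min(i1 + 1, n)]
    finite = np.isfinite(xs) & np.isfinite(ys)
    vs = velocities.v[i0 + 1:min(i1 + 1, n)]
    vs = vs[np.isfinite(vs)]
    if not finite.any() or vs.size == 0:
        warnings.warn(f"dropping {label} event at sample {i0}: all samples "
                      "masked", UserWarning, stacklevel=2)
        return None
    first = int(np.flatnonzero(finite)[0])
    last = int(np.flatnonzero(finite)[-1])
    start_x, start_y = float(xs[first]), float(ys[first])
    end_x, end_y = float(xs[last]), float(ys[last])
    amplitude = float(np.hypot(end_x - start_x, end_y - start_y)) * series.px2deg
    return GazeEvent(
        label=label,
        onset_time=i0 / fs,
        offset_time=i1 / fs,
        start_x=start_x, start_y=start_y, end_x=end_x, end_y=end_y,
        amplitude=amplitude,
        peak_vel=float(np.max(vs)),
        median_vel=float(np.median(vs)),
        avg_vel=float(np.mean(vs)),
        onset_index=i0, offset_index=i1,
    )


# ---------------------------------------------------------------------------
# saccades and PSOs

def classify_pso(velocities: VelocitySeries, saccade: GazeEvent,
                 onset_threshold: float, peak_threshold: float,
                 params: ClassifierParams, series: GazeSeries,
                 limit: int | None = None) -> GazeEvent | None:
    """Post-saccadic oscillation immediately following ``saccade``.

    If the velocity re-exceeds the onset threshold within
    ``max_pso_duration`` after the saccade offset, the oscillation from
    the saccade offset to the offset of its last supra-threshold excursion
    (nearest qualifying velocity minimum, hard-capped at the window end)
    becomes a PSO.  The label is high-velocity (HPSO/IHPS) if the peak
    threshold is exceeded within the event, low-velocity (LPSO/ILPS)
    otherwise; chunk-boundary saccades yield HPSO/LPSO, others IHPS/ILPS.
    Absence of a PSO is a normal outcome (returns None).
    """
    v = velocities.v
    fs = velocities.sampling_rate
    n = len(v)
    start = saccade.offset_index
    wend = min(n, start + _n_samples(params.max_pso_duration, fs))
    if limit is not None:
        wend = min(wend, limit)
    # truncate the search window at missing data
    window = np.arange(start + 1, wend + 1)
    window = window[window < n]
    nonfinite = ~np.isfinite(v[window]) if window.size else np.array([], bool)
    if nonfinite.any():
        wend = int(window[np.flatnonzero(nonfinite)[0]]) - 1
        window = window[window <= wend]
    if window.size == 0:
        return None
    with np.errstate(invalid="ignore"):
        above = window[v[window] > onset_threshold]
    if above.size == 0:
        return None
    last_above = int(above[-1])
    offset, _ = _walk_to_minimum(v, last_above + 1, +1, onset_threshold,
                                 start + 1, wend + 1)
    offset = min(offset, wend)
    if offset <= start:
        return None
    vs = v[start + 1:offset + 1]
    vs = vs[np.isfinite(vs)]
    if vs.size == 0:
        return None
    high = bool(np.max(vs) > peak_threshold)
    if saccade.label == "SACC":
        label = "HPSO" if high else "LPSO"
    else:
        label = "IHPS" if high else "ILPS"
    return compute_event_properties(label, start, offset, series, velocities)


def _classify_major_saccade(velocities: VelocitySeries, series: GazeSeries,
                            peak: int, params: ClassifierParams
                            ) -> tuple[GazeEvent | None, float, float]:
    """Classify one chunk-bounding saccade (label SACC) from a context
    window centered on its velocity peak.  Returns (event, onset_thr,
    peak_thr); event is None if the candidate does not qualify."""
    v = velocities.v
    fs = velocities.sampling_rate
    n = len(v)
    half = _n_samples(params.saccade_context_window_length / 2.0, fs)
    lo, hi = max(0, peak - half), min(n, peak + half)
    try:
        est = estimate_threshold(VelocitySeries(v[lo:hi], fs), params.threshold)
    except ThresholdEstimationError as exc:
        warnings.warn(f"context threshold estimation failed around sample "
                      f"{peak} ({exc}); no saccade classified there",
                      UserWarning, stacklevel=2)
        return None, np.nan, np.nan
    onset_thr, peak_thr = derive_event_thresholds(est, params.threshold)
    if not (np.isfinite(v[peak]) and v[peak] >= peak_thr):
        return None, onset_thr, peak_thr
    bounds = find_saccade_bounds(velocities, peak, onset_thr, lo, hi)
    if (bounds.offset_index - bounds.onset_index) / fs < params.min_saccade_duration:
        return None, onset_thr, peak_thr
    event = compute_event_properties("SACC", bounds.onset_index,
                                     bounds.offset_index, series, velocities)
    return event, onset_thr, peak_thr


def _relocate_peak(v: np.ndarray, peak: int, radius: int) -> int:
    """Re-locate a chunking-stream peak on the classification stream."""
    lo = max(0, peak - radius)
    hi = min(len(v), peak + radius + 1)
    seg = v[lo:hi]
    if not np.isfinite(seg).any():
        return peak
    return lo + int(np.nanargmax(seg))


def _free_intervals(n: int, occupied: list[tuple[int, int]]
                    ) -> list[tuple[int, int]]:
    """Complement of the (sorted, disjoint) occupied spans within [0, n)."""
    free = []
    cursor = 0
    for a, b in sorted(occupied):
        if a > cursor:
            free.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < n:
        free.append((cursor, n))
    return free


def _classify_intrachunk_saccades(velocities: VelocitySeries,
                                  series: GazeSeries, a: int, b: int,
                                  params: ClassifierParams,
                                  margin_left: bool, margin_right: bool
                                  ) -> list[GazeEvent]:
    """Saccades (label ISAC) plus their PSOs inside the intersaccadic
    interval [a, b), using the whole interval as threshold context."""
    v = velocities.v
    fs = velocities.sampling_rate
    min_window = (2 * params.min_intersaccade_duration
                  + params.min_saccade_duration + params.max_pso_duration)
    if (b - a) / fs < min_window:
        return []
    try:
        est = estimate_threshold(VelocitySeries(v[a:b], fs), params.threshold)
    except ThresholdEstimationError:
        return []
    onset_thr, peak_thr = derive_event_thresholds(est, params.threshold)

    idx = np.arange(a + 1, b - 1)
    if idx.size == 0:
        return []
    with np.errstate(invalid="ignore"):
        cand = idx[(v[idx] > peak_thr)
                   & ~(v[idx - 1] > v[idx]) & (v[idx] > v[idx + 1])]
    if cand.size == 0:
        return []
    order = np.lexsort((cand, -v[cand]))
    margin = _n_samples(params.min_intersaccade_duration, fs)
    occupied: list[tuple[int, int]] = []
    events: list[GazeEvent] = []
    for p in cand[order]:
        p = int(p)
        if any(s - margin <= p < e + margin for s, e in occupied):
            continue
        # saccade bounds stay within the free sub-interval around the peak
        lo, hi = a, b
        for s, e in occupied:
            if e <= p:
                lo = max(lo, e)
            if s > p:
                hi = min(hi, s)
        bounds = find_saccade_bounds(velocities, p, onset_thr, lo, hi)
        i0, i1 = bounds.onset_index, bounds.offset_index
        if (i1 - i0) / fs < params.min_saccade_duration:
            continue
        # intersaccadic proximity: keep a margin to neighboring saccades
        # and to saccade-bounded interval edges
        near_left = lo if (lo > a or margin_left) else None
        near_right = hi if (hi < b or margin_right) else None
        if near_left is not None and i0 - near_left < margin:
            continue
        if near_right is not None and near_right - i1 < margin:
            continue
        event = compute_event_properties("ISAC", i0, i1, series, velocities)
        if event is None:
            continue
        pso = classify_pso(velocities, event, onset_thr, peak_thr, params,
                           series, limit=hi)
        events.append(event)
        end = pso.offset_index if pso is not None else i1
        if pso is not None:
            events.append(pso)
        occupied.append((i0, end))
    events.sort(key=lambda e: e.onset_index)
    return events


def classify_saccades(velocities: VelocitySeries, chunk: Chunk,
                      major_peaks: list[int], params: ClassifierParams,
                      series: GazeSeries) -> list[GazeEvent]:
    """All saccadic events (saccades and their PSOs) within ``chunk``.

    Major peaks falling inside the chunk become chunk-bounding saccades
    (label SACC) classified from a context window centered on the peak;
    the intersaccadic intervals in between are then searched for further
    saccades (label ISAC) using the interval itself as threshold context.
    Intervals shorter than twice the minimum intersaccade duration plus
    the minimum saccade and maximum PSO durations are not searched.
    """
    v = velocities.v
    fs = velocities.sampling_rate
    # bridge the small peak offset between the chunking (median) and
    # classification (Savitzky-Golay) streams without jumping onto a
    # different movement
    radius = max(_n_samples(params.preprocess.savgol_length, fs), 2)
    events: list[GazeEvent] = []
    occupied: list[tuple[int, int]] = []
    thresholds: list[tuple[int, float, float]] = []

    margin = _n_samples(params.min_intersaccade_duration, fs)
    peaks = [p for p in sorted(major_peaks)
             if chunk.start_index <= p < chunk.end_index]
    for p in peaks:
        p = _relocate_peak(v, p, radius)
        event, onset_thr, peak_thr = _classify_major_saccade(
            velocities, series, p, params)
        if event is None:
            continue
        if occupied and event.onset_index < occupied[-1][1] + margin:
            continue  # proximity rule: too close to the previous saccade
        events.append(event)
        occupied.append((event.onset_index, event.offset_index))
        thresholds.append((len(events) - 1, onset_thr, peak_thr))

    # PSOs of the major saccades, capped at the next saccade's onset
    pso_events: list[GazeEvent] = []
    for k, (ei, onset_thr, peak_thr) in enumerate(thresholds):
        nxt = occupied[k + 1][0] if k + 1 < len(occupied) else chunk.end_index
        pso = classify_pso(velocities, events[ei], onset_thr, peak_thr,
                           params, series, limit=nxt)
        if pso is not None:
            pso_events.append(pso)
            occupied[k] = (occupied[k][0], pso.offset_index)
    events.extend(pso_events)

    # intersaccadic intervals between the classified major events
    span = chunk.end_index - chunk.start_index
    for (a, b) in _free_intervals(span, [(s - chunk.start_index,
                                          e - chunk.start_index)
                                         for s, e in occupied]):
        a += chunk.start_index
        b += chunk.start_index
        events.extend(_classify_intrachunk_saccades(
            velocities, series, a, b, params,
            margin_left=(a > chunk.start_index or chunk.bounded_left),
            margin_right=(b < chunk.end_index or chunk.bounded_right)))
    events.sort(key=lambda e: e.onset_index)
    return events


# ---------------------------------------------------------------------------
# pursuit / fixation

def classify_pursuit_fixation(velocities: VelocitySeries, segment: Chunk,
                              series: GazeSeries,
                              params: ClassifierParams) -> list[GazeEvent]:
    """Split an unlabeled inter-event stretch into pursuit and fixation.

    Segment velocities are low-pass filtered (zero-phase Butterworth,
    order 2, cutoff ``lowpass_cutoff_freq``); maximal runs exceeding
    ``pursuit_velthresh`` are extended to the nearest qualifying velocity
    minima and labeled PURS if at least ``min_pursuit_duration`` long.
    All residual sub-segments of at least ``min_fixation_duration`` are
    labeled FIXA; shorter residuals yield no event.  Segments too short
    for a stable filter are processed unfiltered, with a warning.
    """
    a, b = segment.start_index, segment.end_index
    fs = velocities.sampling_rate
    if (b - a) / fs < params.min_fixation_duration:
        return []
    v = velocities.v[a:b].copy()
    finite = np.isfinite(v)
    if not finite.any():
        return []
    # leading masked velocity (e.g. the very first recording sample) is
    # backfilled for the filtering decision only
    v_dec = v.copy()
    if not finite.all():
        first = int(np.flatnonzero(finite)[0])
        v_dec[:first] = v_dec[first]
        v_dec[~np.isfinite(v_dec)] = 0.0
    bb, aa = butter(2, params.lowpass_cutoff_freq,
                    btype="low", fs=fs)
    padlen = 3 * max(len(aa), len(bb))
    if len(v_dec) > padlen:
        vf = filtfilt(bb, aa, v_dec)
    else:
        warnings.warn("segment too short for the low-pass filter; deciding "
                      "pursuit on unfiltered velocities", UserWarning,
                      stacklevel=2)
        vf = v_dec
    with np.errstate(invalid="ignore"):
        above = vf > params.pursuit_velthresh
    nseg = len(vf)
    # The zero-phase filter needs ~half a cutoff period to settle from the
    # elevated velocities at saccade-bounded segment edges; pursuit must be
    # evidenced outside that settling zone, otherwise decaying saccadic
    # residue would masquerade as brief pursuit.  Accepted runs may still
    # extend to the segment edge.
    settle = int(round(0.5 / params.lowpass_cutoff_freq * fs))
    core = above.copy()
    if segment.bounded_left:
        core[:settle] = False
    if segment.bounded_right:
        core[nseg - settle:] = False
    runs = [r for r in _bool_runs(above)
            if core[r[0]:r[1]].any()]
    candidates: list[tuple[int, int]] = []
    for (ra, rb) in runs:
        peak = ra + int(np.argmax(vf[ra:rb]))
        on, _ = _walk_to_minimum(vf, peak - 1, -1, params.pursuit_velthresh,
                                 0, nseg)
        off, _ = _walk_to_minimum(vf, peak + 1, +1, params.pursuit_velthresh,
                                  0, nseg)
        on = min(on, ra)
        off = max(off, rb)
        candidates.append((on, off))
    # merge overlapping pursuit candidates
    merged: list[tuple[int, int]] = []
    for on, off in sorted(candidates):
        if merged and on <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], off))
        else:
            merged.append((on, off))
    events: list[GazeEvent] = []
    pursuits: list[tuple[int, int]] = []
    for on, off in merged:
        if (off - on) / fs >= params.min_pursuit_duration:
            ev = compute_event_properties("PURS", a + on, a + off, series,
                                          velocities)
            if ev is not None:
                events.append(ev)
                pursuits.append((on, off))
    for on, off in _free_intervals(nseg, pursuits):
        if (off - on) / fs >= params.min_fixation_duration:
            ev = compute_event_properties("FIXA", a + on, a + off, series,
                                          velocities)
            if ev is not None:
                events.append(ev)
    events.sort(key=lambda e: e.onset_index)
    return events


# ---------------------------------------------------------------------------
# full pipeline

def classify_recording(series: GazeSeries,
                       params: ClassifierParams | None = None
                       ) -> list[GazeEvent]:
    """Run the full classification pipeline on a raw gaze series.

    Returns the classified events sorted by onset; events are pairwise
    non-overlapping and the result is deterministic for fixed input and
    parameters.  An all-missing input yields an empty list with a warning.
    """
    if params is None:
        params = ClassifierParams()
    if params.lowpass_cutoff_freq >= series.sampling_rate / 2:
        raise ParameterError("lowpass_cutoff_freq must be below the Nyquist "
                             "frequency")
    streams = preprocess(series, params.preprocess)
    vel = streams.velocity
    n = len(vel)
    if not np.isfinite(vel.v).any():
        warnings.warn("no usable samples in the recording; no events "
                      "classified", UserWarning, stacklevel=2)
        return []
    _, major_peaks = chunk_recording(streams.chunk_velocity, params)
    events = classify_saccades(vel, Chunk(0, n, False, False), major_peaks,
                               params, streams.series)
    occupied = [(e.onset_index, e.offset_index) for e in events]
    finite = np.isfinite(vel.v)
    for (a, b) in _free_intervals(n, occupied):
        # segments never cross missing data; every contiguous finite
        # stretch is processed independently
        sub = finite[a:b].copy()
        if a == 0 and len(sub) > 1 and not sub[0] and sub[1] \
                and np.isfinite(series.x[0]):
            # the very first sample has no velocity by convention but a
            # valid coordinate; let the first segment start at sample 0
            sub[0] = True
        bounded_left = a > 0
        bounded_right = b < n
        for (sa, sb) in _bool_runs(sub):
            events.extend(classify_pursuit_fixation(
                vel, Chunk(a + sa, a + sb, bounded_left and sa == 0,
                           bounded_right and sb == len(sub)),
                streams.series, params))
    events.sort(key=lambda e: (e.onset_index, e.offset_index))
    return events
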