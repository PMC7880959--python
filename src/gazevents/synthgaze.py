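"""Deterministic synthetic gaze recordings with sample-level ground truth.

The generator renders an :class:`EventScript` — an ordered sequence of
oculomotor directives — into a dense coordinate time series plus aligned
per-sample truth labels, so that every stage of the classifier can be
exercised end-to-end with known answers.

Kinematic model
---------------
* Fixations are stationary points plus slow linear drift and Gaussian
  coordinate noise.
* Saccades have a positively skewed, bell-shaped velocity profile
  (``v(tau) ~ tau**2 * (1-tau)**3``, peak at 40% of the duration with a
  gentle deceleration tail, as in recorded saccades); the peak velocity
  obeys a main-sequence power law ``peak_vel = K * amplitude**M`` with
  ``K = 80``, ``M = 0.6`` by default, which fixes the saccade duration.
* Post-saccadic oscillations are modeled as a damped return from a small
  overshoot: the preceding saccade lands beyond its target and the PSO
  oscillates back along the saccade axis with a smoothly vanishing
  velocity at both ends, so saccade/PSO and PSO/fixation boundaries are
  genuine velocity minima.
* Pursuits are constant-velocity ramps.
* Blinks are signal-loss (NaN) windows flanked by brief large-amplitude
  eyelid artifacts, as produced by video-based trackers.

The model reproduces the kinematic features the classifier keys on; it
does not emulate oculomotor dynamics beyond that (no pupil/corneal-
reflection artifacts, no saccade curvature, no tracker-specific noise
spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .preprocess import GazeSeries

__all__ = [
    "Fixation", "Saccade", "PostSaccadicOscillation", "Pursuit", "Blink",
    "EventScript", "GroundTruth", "GeneratorError",
    "generate_recording", "random_script", "demo_script",
    "MAIN_SEQUENCE_K", "MAIN_SEQUENCE_M", "VELOCITY_CAP",
    "main_sequence_peak_velocity", "saccade_duration",
]

#: Main-sequence power law constants: peak_vel = K * amplitude**M
#: (deg/s for amplitude in deg).
MAIN_SEQUENCE_K = 80.0
MAIN_SEQUENCE_M = 0.6

#: Physiological cap; scripts implying faster eye movements are rejected.
VELOCITY_CAP = 1000.0


class GeneratorError(ValueError):
    """The script implies physiologically impossible kinematics."""


@dataclass
class Fixation:
    duration: float
    drift_vel: float = 0.5        # deg/s, slow ocular drift
    direction: float | None = None  # radians; None -> drawn from the RNG


@dataclass
class Saccade:
    amplitude: float              # deg, > 0
    direction: float = 0.0        # radians


@dataclass
class PostSaccadicOscillation:
    """Damped oscillation appended to the preceding saccade's offset."""

    relative_peak_fraction: float = 0.3   # PSO peak vel / saccade peak vel
    duration: float = 0.038               # s


@dataclass
class Pursuit:
    duration: float
    velocity: float = 5.0         # deg/s
    direction: float = 0.0        # radians


@dataclass
class Blink:
    duration: float               # s of signal loss


Directive = Union[Fixation, Saccade, PostSaccadicOscillation, Pursuit, Blink]


@dataclass
class EventScript:
    """Ordered oculomotor directives plus global recording properties.

    ``noise_profile`` is a piecewise-constant multiplier on ``noise_sd``:
    a tuple of ``(start_time_s, multiplier)`` pairs covering the recording
    from each start time onward.
    """

    directives: list[Directive]
    sampling_rate: float = 1000.0
    px2deg: float = 0.01
    noise_sd: float = 0.1         # px, Gaussian coordinate noise
    noise_profile: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    seed: int = 0
    start: tuple[float, float] = (960.0, 600.0)  # px

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if not self.sampling_rate > 0 or not self.px2deg > 0:
            raise GeneratorError("sampling_rate and px2deg must be positive")


@dataclass
class GroundTruth:
    """Per-sample true labels and per-event true boundaries.

    Labels use the classifier's collapsed categories (FIXA, SACC, PSO,
    PURS) plus BLINK and NONE; events are ``(label, onset_s, offset_s)``
    with half-open sample semantics matching the generated series.
    """

    labels: np.ndarray
    events: list[tuple[str, float, float]]


def main_sequence_peak_velocity(amplitude: float) -> float:
    """Main-sequence peak velocity (deg/s) for a saccade amplitude (deg)."""
    return MAIN_SEQUENCE_K * amplitude ** MAIN_SEQUENCE_M


#: Exponents of the beta-shaped saccade velocity profile
#: v(tau) ~ tau**A_SKEW * (1 - tau)**B_SKEW: a brisk acceleration, the
#: velocity peak in the first half of the saccade, and a long, gentle
#: deceleration tail — the positively skewed shape of recorded saccades.
A_SKEW, B_SKEW = 2.0, 3.0


def _beta_peak_factor() -> float:
    tau = np.linspace(0.0005, 0.9995, 2000)
    v = tau ** A_SKEW * (1.0 - tau) ** B_SKEW
    return float(v.max() / np.trapezoid(v, tau))


# peak/mean ratio of the unit velocity profile (dimensionless)
_PROFILE_PEAK_FACTOR = _beta_peak_factor()


def saccade_duration(amplitude: float) -> float:
    """Duration (s) of a main-sequence saccade with the beta velocity
    profile: T = amplitude * peak_factor / peak_velocity."""
    return (amplitude * _PROFILE_PEAK_FACTOR
            / main_sequence_peak_velocity(amplitude))


class _Track:
    """Accumulates samples, labels and truth events while rendering."""

    def __init__(self, script: EventScript):
        self.fs = script.sampling_rate
        self.px2deg = script.px2deg
        self.pos = np.array(script.start, dtype=float)
        self.x: list[np.ndarray] = []
        self.y: list[np.ndarray] = []
        self.labels: list[np.ndarray] = []
        self.events: list[tuple[str, int, int]] = []
        self.n = 0

    def emit(self, xs: np.ndarray, ys: np.ndarray, label: str) -> None:
        m = len(xs)
        if m == 0:
            return
        self.x.append(xs)
        self.y.append(ys)
        self.labels.append(np.full(m, label, dtype="U5"))
        self.events.append((label, self.n, self.n + m))
        self.n += m
        if np.isfinite(xs[-1]):
            self.pos = np.array([xs[-1], ys[-1]])


def _render_fixation(track: _Track, d: Fixation, rng: np.random.Generator,
                     label: str = "FIXA") -> None:
    """Slow ocular drift: a meandering walk whose speed fluctuates around
    ``drift_vel`` (mean-reverting heading and speed), as fixational drift
    does, rather than a perfectly straight constant-velocity ramp."""
    n = max(1, int(round(d.duration * track.fs)))
    direction = rng.uniform(0, 2 * np.pi) if d.direction is None else d.direction
    dt = 1.0 / track.fs
    heading = direction + np.cumsum(rng.normal(0.0, 0.08, n))
    speed = d.drift_vel * np.clip(
        1.0 + _smooth_noise(rng, n, int(track.fs * 0.03) + 1, 0.8),
        0.05, 3.0)
    # fixational drift is sub-pursuit by definition
    speed = np.minimum(speed, 1.9)
    step_px = speed * dt / track.px2deg
    xs = track.pos[0] + np.cumsum(np.cos(heading) * step_px)
    ys = track.pos[1] + np.cumsum(np.sin(heading) * step_px)
    track.emit(xs, ys, label)


def _smooth_noise(rng: np.random.Generator, n: int, scale: int,
                  sd: float) -> np.ndarray:
    """Band-limited unit-free noise: white noise box-smoothed over
    ``scale`` samples, rescaled to standard deviation ``sd``."""
    w = rng.normal(0.0, 1.0, n + scale)
    kernel = np.ones(scale) / scale
    s = np.convolve(w, kernel, mode="valid")[:n]
    std = s.std()
    return s * (sd / std) if std > 0 else s


def _render_saccade(track: _Track, d: Saccade,
                    pso: PostSaccadicOscillation | None,
                    bg_before: np.ndarray | None = None,
                    bg_after: np.ndarray | None = None) -> None:
    """Render one saccade; ``bg_before``/``bg_after`` are background
    velocity vectors (deg/s) of adjacent pursuit episodes.

    A saccade bracketed by pursuit is superimposed on the ongoing smooth
    tracking (the eye does not come to a full stop at a catch-up
    saccade): the background velocity blends linearly from the preceding
    to the following episode's velocity across the saccade.
    """
    if d.amplitude <= 0:
        raise GeneratorError("saccade amplitude must be > 0")
    vp = main_sequence_peak_velocity(d.amplitude)
    if vp > VELOCITY_CAP:
        raise GeneratorError(
            f"saccade of {d.amplitude} deg implies a peak velocity of "
            f"{vp:.0f} deg/s, above the physiological cap ({VELOCITY_CAP})")
    T = saccade_duration(d.amplitude)
    n = max(2, int(round(T * track.fs)))
    overshoot = _pso_overshoot(d, pso, track.fs) if pso is not None else 0.0
    amp_px = (d.amplitude + overshoot) / track.px2deg
    tau = (np.arange(n) + 0.5) / n
    vel_shape = tau ** A_SKEW * (1.0 - tau) ** B_SKEW
    profile = np.cumsum(vel_shape)
    profile *= amp_px / profile[-1]
    xs = track.pos[0] + np.cos(d.direction) * profile
    ys = track.pos[1] + np.sin(d.direction) * profile
    b0 = np.zeros(2) if bg_before is None else bg_before
    b1 = np.zeros(2) if bg_after is None else bg_after
    if b0.any() or b1.any():
        w = np.arange(1, n + 1) / n
        bg = (np.outer(1 - w, b0) + np.outer(w, b1)) \
            / track.px2deg / track.fs
        xs = xs + np.cumsum(bg[:, 0])
        ys = ys + np.cumsum(bg[:, 1])
    track.emit(xs, ys, "SACC")


def _pso_overshoot(sacc: Saccade, pso: PostSaccadicOscillation,
                   fs: float) -> float:
    """Overshoot distance (deg) that yields the requested PSO peak velocity."""
    vp_pso = pso.relative_peak_fraction * main_sequence_peak_velocity(
        sacc.amplitude)
    _, vmax_unit = _pso_profile(pso.duration, fs)
    return vp_pso / vmax_unit


def _pso_profile(duration: float, fs: float) -> tuple[np.ndarray, float]:
    """Unit-overshoot PSO displacement profile and its peak speed (deg/s
    per deg of overshoot).

    One full oscillation cycle over the duration, with a warped phase and
    a cosine-squared decay envelope:

        r(tau) = cos(2*pi * tau**2.0) * (1 - tau**2),   tau = t/T.

    The profile starts at the overshoot apex (r = 1) with vanishing
    velocity — the phase warp makes the return build up gradually,
    producing the several-millisecond low-velocity interval between
    saccade and oscillation that recorded post-saccadic oscillations
    show — and ends at the saccade target with a decisive terminal
    deceleration, so the oscillation's end is a sharp velocity minimum.
    """
    n = max(2, int(round(duration * fs)))
    tau = np.arange(1, n + 1) / n
    r = np.cos(2.0 * np.pi * tau ** 2.0) * (1.0 - tau ** 2)
    v = np.abs(np.diff(np.concatenate([[1.0], r]))) * fs
    return r, float(np.max(v))


def _render_pso(track: _Track, sacc: Saccade, d: PostSaccadicOscillation
                ) -> None:
    if not 0 < d.relative_peak_fraction:
        raise GeneratorError("relative_peak_fraction must be > 0")
    overshoot = _pso_overshoot(sacc, d, track.fs)
    r, _ = _pso_profile(d.duration, track.fs)
    # the eye sits at target + overshoot; oscillate back to the target
    target = track.pos - np.array([np.cos(sacc.direction),
                                   np.sin(sacc.direction)]) \
        * overshoot / track.px2deg
    xs = target[0] + np.cos(sacc.direction) * r * overshoot / track.px2deg
    ys = target[1] + np.sin(sacc.direction) * r * overshoot / track.px2deg
    track.emit(xs, ys, "PSO")


def _render_pursuit(track: _Track, d: Pursuit) -> None:
    if d.velocity > VELOCITY_CAP:
        raise GeneratorError("pursuit velocity above the physiological cap")
    n = max(1, int(round(d.duration * track.fs)))
    step_px = d.velocity / track.px2deg / track.fs
    t = np.arange(1, n + 1)
    xs = track.pos[0] + np.cos(d.direction) * step_px * t
    ys = track.pos[1] + np.sin(d.direction) * step_px * t
    track.emit(xs, ys, "PURS")


def _render_blink(track: _Track, d: Blink, rng: np.random.Generator) -> None:
    fs = track.fs
    n_gap = max(1, int(round(d.duration * fs)))
    n_art = max(2, int(round(0.004 * fs)))  # ~4 ms eyelid artifact
    art_px = 40.0
    down = track.pos[1] + art_px * np.linspace(1, 2, n_art) \
        * rng.uniform(0.8, 1.2, n_art)
    pre_x = np.full(n_art, track.pos[0])
    gap = np.full(n_gap, np.nan)
    up = track.pos[1] + art_px * np.linspace(2, 0, n_art) \
        * rng.uniform(0.8, 1.2, n_art)
    up[-1] = track.pos[1]
    post_x = np.full(n_art, track.pos[0])
    xs = np.concatenate([pre_x, gap, post_x])
    ys = np.concatenate([down, gap, up])
    track.emit(xs, ys, "BLINK")


def generate_recording(script: EventScript) -> tuple[GazeSeries, GroundTruth]:
    """Render a script into a gaze series plus aligned ground truth.

    Identical scripts (including the seed) produce identical output; a
    single generator seeded from the script drives all randomness.
    """
    rng = np.random.default_rng(script.seed)
    track = _Track(script)
    directives = list(script.directives)

    def pursuit_vel(d) -> np.ndarray | None:
        if isinstance(d, Pursuit):
            return d.velocity * np.array([np.cos(d.direction),
                                          np.sin(d.direction)])
        return None

    i = 0
    while i < len(directives):
        d = directives[i]
        prv = directives[i - 1] if i > 0 else None
        nxt = directives[i + 1] if i + 1 < len(directives) else None
        if isinstance(d, Fixation):
            _render_fixation(track, d, rng)
        elif isinstance(d, Saccade):
            pso = nxt if isinstance(nxt, PostSaccadicOscillation) else None
            _render_saccade(track, d, pso,
                            bg_before=pursuit_vel(prv),
                            bg_after=pursuit_vel(nxt))
            if pso is not None:
                _render_pso(track, d, pso)
                i += 1
        elif isinstance(d, PostSaccadicOscillation):
            raise GeneratorError("a PSO directive must follow a saccade")
        elif isinstance(d, Pursuit):
            _render_pursuit(track, d)
        elif isinstance(d, Blink):
            _render_blink(track, d, rng)
        else:
            raise GeneratorError(f"unknown directive {d!r}")
        i += 1
    if track.n < 2:
        raise GeneratorError("script renders fewer than 2 samples")
    x = np.concatenate(track.x)
    y = np.concatenate(track.y)
    labels = np.concatenate(track.labels)
    if script.noise_sd > 0:
        mult = np.ones(track.n)
        times = np.arange(track.n) / script.sampling_rate
        for start_t, m in sorted(script.noise_profile):
            mult[times >= start_t] = m
        x = x + rng.normal(0.0, script.noise_sd, track.n) * mult
        y = y + rng.normal(0.0, script.noise_sd, track.n) * mult
    series = GazeSeries(x, y, script.sampling_rate, script.px2deg)
    fs = script.sampling_rate
    # merge truth events of consecutive directives with the same label
    merged: list[tuple[str, int, int]] = []
    for lab, a, b in track.events:
        if merged and merged[-1][0] == lab and merged[-1][2] == a:
            merged[-1] = (lab, merged[-1][1], b)
        else:
            merged.append((lab, a, b))
    events = [(lab, a / fs, b / fs) for lab, a, b in merged]
    return series, GroundTruth(labels=labels, events=events)


# ---------------------------------------------------------------------------
# canned scripts

def random_script(seed: int, duration: float = 8.0,
                  sampling_rate: float = 500.0,
                  with_blinks: bool = True) -> EventScript:
    """A plausible random viewing script of roughly ``duration`` seconds.

    Alternates fixations and main-sequence saccades (with occasional
    PSOs), inserts occasional pursuit episodes bracketed by catch-up
    saccades, and optionally blinks.  Saccade directions are biased back
    toward the screen center so the gaze stays on-screen.
    """
    rng = np.random.default_rng(seed)
    directives: list[Directive] = []
    center = np.array([960.0, 600.0])
    pos = center.copy()
    px2deg = 0.01
    t = 0.0

    def towards_center(jitter: float = 1.2) -> float:
        offset = center - pos
        if np.hypot(*offset) < 150:
            return rng.uniform(0, 2 * np.pi)
        return float(np.arctan2(offset[1], offset[0]) + rng.normal(0, jitter))

    def add_saccade(allow_pso: bool = True) -> None:
        nonlocal t, pos
        amp = float(rng.uniform(2.0, 12.0))
        ang = towards_center()
        directives.append(Saccade(amp, ang))
        pos += amp / px2deg * np.array([np.cos(ang), np.sin(ang)])
        t_s = saccade_duration(amp)
        if allow_pso and rng.random() < 0.5:
            directives.append(PostSaccadicOscillation(
                relative_peak_fraction=float(rng.uniform(0.2, 0.4)),
                duration=float(rng.uniform(0.026, 0.036))))
            t_s += directives[-1].duration
        nonlocal_t(t_s)

    def nonlocal_t(dt: float) -> None:
        nonlocal t
        t += dt

    directives.append(Fixation(float(rng.uniform(0.5, 1.2)),
                               drift_vel=float(rng.uniform(0.2, 0.6))))
    t += directives[-1].duration
    while t < duration:
        r = rng.random()
        if r < 0.2 and t + 3 < duration:
            # pursuit episode bracketed by catch-up saccades
            add_saccade(allow_pso=False)
            ang = towards_center(0.8)
            dur = float(rng.uniform(1.0, 2.0))
            vel = float(rng.uniform(4.0, 8.0))
            directives.append(Pursuit(dur, vel, ang))
            pos += vel * dur / px2deg * np.array([np.cos(ang), np.sin(ang)])
            t += dur
            add_saccade()
        elif r < 0.3 and with_blinks and t + 1 < duration:
            directives.append(Blink(float(rng.uniform(0.05, 0.15))))
            t += directives[-1].duration + 0.008
        else:
            add_saccade()
        directives.append(Fixation(float(rng.uniform(0.6, 1.5)),
                                   drift_vel=float(rng.uniform(0.2, 0.6))))
        t += directives[-1].duration
    return EventScript(directives, sampling_rate=sampling_rate,
                       px2deg=px2deg,
                       noise_sd=float(rng.uniform(0.05, 0.25)),
                       seed=seed)


def demo_script(seed: int = 0, noise_sd: float = 0.1,
                sampling_rate: float = 1000.0) -> EventScript:
    """A deterministic 60-s validation script: 8 fixations, 10 saccades
    (6 with PSOs), and 2 pursuit episodes bracketed by saccades.

    Pursuits follow the natural catch-up pattern — a saccade to the
    moving target, smooth tracking, a return saccade — so every true
    event boundary in the script coincides with a saccade boundary.
    """
    R, L = 0.0, np.pi  # rightward / leftward
    up, down = np.pi / 2, -np.pi / 2
    # Pursuit episodes follow the natural initiation pattern: during the
    # reaction time to the appearing moving target the drift speeds up
    # toward it (low-gain pursuit initiation, still sub-threshold and
    # part of the fixation), then a catch-up saccade lands on the target
    # and full-gain pursuit continues until a return saccade.
    directives: list[Directive] = [
        Fixation(6.6, 0.55, up),
        Saccade(8.0, R), PostSaccadicOscillation(),
        Fixation(6.6, 0.55, down),
        Saccade(10.0, L), PostSaccadicOscillation(),
        Fixation(6.45, 0.45, down), Fixation(0.15, 1.5, R),
        Saccade(6.0, R),
        Pursuit(3.0, 5.0, R),
        Saccade(8.0, L), PostSaccadicOscillation(),
        Fixation(6.6, 0.55, up),
        Saccade(5.0, L), PostSaccadicOscillation(),
        Fixation(6.6, 0.45, down),
        Saccade(12.0, R), PostSaccadicOscillation(),
        Fixation(6.45, 0.55, up), Fixation(0.15, 1.5, R),
        Saccade(7.0, R),
        Pursuit(3.0, 5.0, R),
        Saccade(9.0, L), PostSaccadicOscillation(),
        Fixation(6.6, 0.45, up),
        Saccade(4.0, R),
        Fixation(6.6, 0.55, down),
    ]
    return EventScript(directives, sampling_rate=sampling_rate,
                       px2deg=0.01, noise_sd=noise_sd, seed=seed,
                       start=(760.0, 600.0))
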