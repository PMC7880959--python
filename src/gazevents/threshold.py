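"""Adaptive, robust saccade velocity threshold estimation.

The saccade threshold is found iteratively: starting from a deliberately
high initial value, the threshold is repeatedly re-placed at

    PT_n = median(V_{n-1}) + F * MAD(V_{n-1})

where ``V_{n-1}`` are the velocities strictly below the previous threshold,
``MAD`` is the raw median absolute deviation and ``F`` a noise factor.
Iteration stops once two consecutive thresholds differ by less than
1 deg/s.  Median/MAD statistics make the estimate robust to the heavy
right tail of gaze velocity distributions, unlike the classical mean/SD
update they replace.

Note that MAD is used *raw*, without the 1.4826 normality scaling; the
default noise factor of 5 is therefore only loosely comparable to the 3
standard deviations of the classical procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import VelocitySeries

__all__ = [
    "ThresholdParams",
    "ThresholdEstimate",
    "ThresholdEstimationError",
    "CONVERGENCE_VELOCITY",
    "MAX_ITERATIONS",
    "estimate_threshold",
    "derive_event_thresholds",
]

#: Convergence criterion: iteration stops when successive thresholds differ
#: by less than this many deg/s.  Fixed by the algorithm, not configurable.
CONVERGENCE_VELOCITY = 1.0

#: Hard cap on threshold iterations, as a defense against pathological
#: oscillation on degenerate inputs.
MAX_ITERATIONS = 1000


class ThresholdEstimationError(RuntimeError):
    """The adaptive threshold could not be estimated from the data."""


@dataclass
class ThresholdParams:
    """Parameters of the adaptive threshold iteration.

    velthresh_startvelocity
        Initial threshold in deg/s; should be larger than any conceivable
        minimum saccade velocity.
    noise_factor
        Scalar F placed on the MAD; increase for noisy data to reduce
        false positives.
    """

    velthresh_startvelocity: float = 300.0
    noise_factor: float = 5.0

    def __post_init__(self) -> None:
        if not self.velthresh_startvelocity > 0:
            raise ValueError("velthresh_startvelocity must be positive")
        if not self.noise_factor > 0:
            raise ValueError("noise_factor must be positive")


@dataclass
class ThresholdEstimate:
    """Converged threshold with its context statistics.

    pt
        The converged threshold in deg/s.
    med, mad
        Median and median absolute deviation of the final sub-threshold
        velocity set, from which onset and peak event thresholds derive.
    n_iter
        Number of median/MAD updates performed (>= 1).
    """

    pt: float
    med: float
    mad: float
    n_iter: int


def estimate_threshold(velocities: VelocitySeries | np.ndarray,
                       params: ThresholdParams | None = None
                       ) -> ThresholdEstimate:
    """Iterate the robust threshold update to convergence.

    Masked (non-finite) samples are excluded throughout.  The
    sub-threshold set uses a strictly-below comparison; if it becomes
    empty or stops changing between iterations, the last threshold is
    returned (this guarantees termination on degenerate data such as
    constant velocities).

    Raises
    ------
    ThresholdEstimationError
        If fewer than 2 finite samples are available, or no finite sample
        lies below the start velocity.
    """
    if params is None:
        params = ThresholdParams()
    v = velocities.finite if isinstance(velocities, VelocitySeries) \
        else np.asarray(velocities, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ThresholdEstimationError(
            "need at least 2 finite velocity samples to estimate a threshold")

    pt = float(params.velthresh_startvelocity)
    f = params.noise_factor
    prev_sub: np.ndarray | None = None
    med = mad = None
    n_iter = 0
    while n_iter < MAX_ITERATIONS:
        sub = v[v < pt]
        if sub.size == 0:
            if n_iter == 0:
                raise ThresholdEstimationError(
                    f"no finite velocities below the start velocity ({pt} deg/s)")
            break
        if prev_sub is not None and np.array_equal(sub, prev_sub):
            break
        med = float(np.median(sub))
        mad = float(np.median(np.abs(sub - med)))
        new_pt = med + f * mad
        n_iter += 1
        if abs(new_pt - pt) < CONVERGENCE_VELOCITY:
            pt = new_pt
            break
        pt = new_pt
        prev_sub = sub
    else:
        warnings.warn(
            f"threshold iteration did not converge within {MAX_ITERATIONS} "
            "iterations; returning the last estimate", UserWarning,
            stacklevel=2)
    return ThresholdEstimate(pt=pt, med=med, mad=mad, n_iter=n_iter)


def derive_event_thresholds(est: ThresholdEstimate,
                            params: ThresholdParams | None = None
                            ) -> tuple[float, float]:
    """Onset and peak velocity thresholds from converged context statistics.

    The onset threshold places the noise factor F on the MAD, the peak
    threshold twice that:

        onset = med + F * MAD        peak = med + 2F * MAD

    so ``peak - onset == F * MAD`` exactly.
    """
    if params is None:
        params = ThresholdParams()
    onset = est.med + params.noise_factor * est.mad
    peak = est.med + 2.0 * params.noise_factor * est.mad
    return onset, peak
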