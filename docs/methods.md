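# Methods

This note documents the model implemented by `gazevents`, the numerical
choices that shape its behavior, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Preprocessing

Raw pixel coordinates pass through a fixed pipeline: spike removal →
signal-loss dilation → smoothing → velocity computation → clamping.

*Spike removal.* A sample is treated as a tracker spike iff it is a
strict local extremum on an axis and its distance to each neighbor
exceeds the distance between the neighbors; it is replaced by the nearer
neighbor's value (the earlier neighbor on ties). This is a deliberately
minimal single-sample despiker, applied independently per axis, and is
isolated in one function so stricter multi-level variants can be
swapped in.

*Signal loss.* Any non-numeric input token is a missing sample (NaN).
Contiguous missing runs of at least `min_blink_duration` (default
0.02 s) are dilated by `dilate_nan` (0.01 s) on both sides to blank
eyelid artifacts around blinks. A `GazeSeries` keeps the *original*
loss mask separate from the NaN markers, so dilation is idempotent —
re-running it never grows the masks further. Smoothing never
interpolates across gaps: each contiguous finite segment is filtered on
its own, and samples whose filter window would touch missing data
propagate the marker.

*Two velocity streams.* Angular speed is the Euclidean displacement
between consecutive samples × `px2deg` × sampling rate, assigned to the
later sample (the first sample is masked). The classifier uses two
streams from the same data: a heavily median-filtered one
(`median_filter_length` = 0.05 s) in which only large-amplitude saccades
survive, used solely to chunk the recording; and a Savitzky–Golay
smoothed one (`savgol_length` = 0.019 s, order 2) on which all event
classification runs. Durations convert to windows by rounding samples
up to the next odd count (symmetric, phase-free filters). Speeds above
`max_vel` (1000 °/s) are biologically implausible; they are clamped
with a warning, since their presence usually indicates inappropriate
filter settings rather than eye movements.

## Robust adaptive threshold

The saccade threshold iterates `PT_n = median(V) + F·MAD(V)` over the
velocities strictly below the previous threshold, from
`velthresh_startvelocity` (300 °/s) until two successive values differ
by less than 1 °/s (a fixed constant of the algorithm, not a
parameter). Two degenerate-data guards make termination unconditional:
if the sub-threshold set becomes empty or stops changing, the last
threshold is returned; a hard cap of 1000 iterations warns and returns.
The MAD is used raw, without the 1.4826 normality factor — the default
noise factor F = 5 is therefore only loosely comparable to "3 standard
deviations" of the classical mean/SD update. Onset and peak thresholds
derive from the converged context statistics as `median + F·MAD` and
`median + 2F·MAD`.

The median/MAD update is the core robustness device: gaze-velocity
distributions have heavy right tails, and an iterative mean/SD update
can stabilize with moderate-velocity contamination (oscillation or
pursuit samples) inside its sub-threshold set, inflating the threshold
several-fold. The test suite demonstrates this against a literal
mean/SD oracle.

## Event classification

*Chunking.* One threshold is estimated on the median-filtered stream
over the whole recording. Each maximal run of above-threshold samples
is a candidate weighted by its velocity sum; candidates are accepted in
descending weight (earlier run wins ties) until the accepted count per
recording duration would exceed `max_initial_saccade_freq` (2 Hz). The
accepted runs' peak samples are chunk boundaries.

*Saccades.* Chunk-bounding saccades (label `SACC`) get their thresholds
from a 1-s window centered on the velocity peak; intra-chunk saccades
(`ISAC`) from the enclosing intersaccadic interval. The peak must reach
the context peak threshold; boundaries are the nearest local velocity
minima not exceeding the onset threshold, walking outward from the peak
and skipping minima that are still above it (merged-movement rule).
Events shorter than `min_saccade_duration` (0.01 s) are rejected, as is
any saccade closer than `min_intersaccade_duration` (0.04 s) to an
already-classified one — including chunk-boundary saccades, which
prevents a strong oscillation lobe that forms its own chunking run from
being classified as a second saccade. Intervals shorter than twice the
intersaccade minimum plus the saccade minimum and the PSO maximum are
not searched. The chunk-stream peak is re-located on the classification
stream within ±`savgol_length` only; a wider search radius could jump
from a spurious low-velocity candidate onto a neighboring real saccade
and mis-center its threshold context.

*Post-saccadic oscillations.* If velocity re-exceeds the onset
threshold within `max_pso_duration` (0.04 s) of a saccade offset, the
stretch from the saccade offset to the offset of the **last**
supra-threshold excursion in that window becomes a PSO (`HPSO`/`IHPS`
if the peak threshold was exceeded inside the event, `LPSO`/`ILPS`
otherwise; the I-variants follow intra-chunk saccades). Walking from
the *first* excursion would truncate a multi-lobed oscillation at its
first internal velocity zero; the event is instead closed after the
final lobe and hard-capped at the window end, so PSO duration never
exceeds `max_pso_duration`. PSOs reuse their parent saccade's context
thresholds.

*Pursuit vs. fixation.* Unlabeled stretches longer than
`min_fixation_duration` (0.04 s) are decided on Butterworth low-pass
filtered velocities (order 2, zero-phase, cutoff
`lowpass_cutoff_freq` = 4 Hz; segments shorter than the filter's stable
length are decided unfiltered, with a warning). Runs above
`pursuit_velthresh` (2 °/s) are extended to the nearest sub-threshold
velocity minima and labeled `PURS` if at least `min_pursuit_duration`
(0.04 s) long; residual stretches of at least the fixation minimum
become `FIXA`. One guard matters here: a segment that begins at a
saccade boundary starts near the onset-threshold velocity level, which
typically exceeds the pursuit threshold, and the zero-phase filter
needs roughly half a cutoff period to settle; a candidate run must
therefore have support outside that settling zone (0.5/cutoff,
i.e. 0.125 s) adjacent to saccade-bounded edges, otherwise decaying
saccadic residue would be emitted as spurious brief pursuit. Accepted
runs may still *extend* to the segment edge, so genuine pursuit
entered directly from a catch-up saccade keeps its sharp onset.
Segment boundaries never cross missing data; every contiguous finite
stretch is processed independently, and duration minima are enforced
after boundary refinement.

Event properties (onset/offset time, start/end coordinates from the
smoothed trace, amplitude = `px2deg` × straight-line distance, peak /
median / mean velocity over the finite in-event samples) are computed
per event; an all-masked window drops the event with a warning. Sample
ranges are half-open, so consecutive events share a boundary sample
index without overlapping, and a PSO's onset index equals its saccade's
offset index.

## Synthetic gaze generator

`synthgaze` renders ordered directives (fixation, saccade, PSO,
pursuit, blink) into coordinates plus aligned per-sample truth labels.
It is the package's primary test surface, so its kinematics are chosen
to reproduce the features the classifier keys on:

- **Saccades** follow a positively skewed, bell-shaped velocity profile
  `v(τ) ∝ τ²(1−τ)³` (peak at 40% of the duration, long gentle
  deceleration tail), the characteristic shape of recorded saccades; a
  symmetric profile such as a raised cosine ends with maximal
  deceleration, which is kinematically unrealistic and produces
  amplitude-dependent artifacts at the saccade/PSO junction under the
  fixed Savitzky–Golay filter. Peak velocity follows the main-sequence
  power law `v_peak = K·A^M` with K = 80 (°/s per °^M) and M = 0.6,
  which fixes the duration; scripts implying peaks above 1000 °/s are
  rejected.
- **PSOs** are a damped return from a small overshoot: the preceding
  saccade deliberately lands beyond its target and the oscillation
  (one phase-warped cycle, `cos(2πτ²)·(1−τ²)` envelope, default 38 ms,
  peak velocity a configurable fraction of the saccade's) brings the
  eye back. The phase warp gives the oscillation a gradual build-up,
  reproducing the brief low-velocity interval between saccade and
  oscillation that recorded PSOs show; the envelope ends with a
  decisive deceleration so the oscillation's end is a sharp velocity
  minimum.
- **Fixational drift** is a meandering walk whose heading diffuses and
  whose speed fluctuates (band-limited, ~30 ms correlation) around
  `drift_vel` (default 0.5 °/s), capped below the pursuit threshold.
  Perfectly straight constant-speed drift would be unrealistically
  regular — its near-zero velocity MAD produces degenerate adaptive
  thresholds.
- **Pursuit** is a constant-velocity ramp (default 5 °/s). A saccade
  adjacent to pursuit is superimposed on the ongoing pursuit velocity
  (linearly blended across the saccade): the eye does not come to a
  full stop at a catch-up saccade.
- **Blinks** are NaN windows flanked by ~4 ms large-amplitude eyelid
  artifacts, which the preprocessing dilation is designed to blank.

Global Gaussian coordinate noise (default SD 0.1 px) can vary over time
through a piecewise-constant multiplier profile, which is how
noise-robustness is exercised. A single generator seeded from the
script drives all randomness.

The bundled 60-s validation script (`demo_script`) contains 8
fixations, 10 saccades (6 with PSOs) and 2 pursuit episodes. Pursuits
follow the natural initiation pattern: during the reaction time to an
appearing moving target, drift accelerates toward it (low-gain
initiation, still below the pursuit threshold and labeled fixation),
then a catch-up saccade lands on the target and full-gain pursuit
continues until a return saccade. Besides realism, this matters for the
adaptive thresholds: it keeps every true event boundary saccade-sharp,
and it avoids handing the entry saccade a pathological threshold
context that is an exact 50/50 fixation/pursuit mixture — a genuinely
degenerate regime for any median-based estimate (the median then sits
on the cliff between the two velocity modes, and the iteration may
collapse to fixation statistics below the pursuit velocity). That
regime remains a documented limitation on real data containing
free-standing fixation-to-pursuit transitions, where pursuit onsets are
additionally smeared by the 4-Hz decision filter; boundary precision
there is limited to roughly the filter's settle time, not the
millisecond scale achieved at saccade-bounded transitions.

What passing tests show, and what they do not: the generator reproduces
kinematic shape, main-sequence scaling, noise non-stationarity and
signal loss, but not pupil/corneal-reflection PSO biases, saccade
curvature, tremor/microsaccades, or tracker-specific noise spectra.
Recovery results on synthetic data therefore validate the algorithmic
machinery, not classification accuracy on any particular eye tracker.

## Agreement metrics

Metrics operate on per-sample label sequences after collapsing
sub-labels to the four-category comparison vocabulary (`SACC`/`ISAC` →
`SACC`; all PSO labels → `PSO`). The misclassification proportion is
taken over the samples where *either* sequence assigns an included
label; samples that only one rater places in an included category count
as disagreements (the alternative — excluding them — would hide
one-sided labeling). Cohen's kappa uses chance agreement from the two
sequences' marginal frequencies and is undefined when both sequences
are constant and identical. The Jaccard matrix gives |both| / |either|
per label pair; an absent-from-both category scores 1.0 by convention,
flagged with a warning. The event-duration RMSD compares, per event
type, the vector (mean duration, SD of durations, event count) of a
candidate against the average of two raters, after scaling each
characteristic by its maximum across the three entities (exposed as
`normalization="max"`; `"none"` compares raw values); characteristics
that are zero up to rounding are left unscaled to avoid dividing by
floating-point residue.

## Parameters at a glance

| name | default | unit | role |
|---|---|---|---|
| px2deg | — | °/px | angular size of one square pixel (mandatory) |
| sampling_rate | — | Hz | recording rate (mandatory) |
| min_blink_duration | 0.02 | s | shorter loss runs are not dilated |
| dilate_nan | 0.01 | s | masking margin around signal loss |
| median_filter_length | 0.05 | s | chunking-stream smoother |
| savgol_length / polyord | 0.019 / 2 | s / — | classification-stream smoother |
| max_vel | 1000 | °/s | physiological clamp |
| velthresh_startvelocity | 300 | °/s | threshold iteration start |
| noise_factor | 5 | — | F in median + F·MAD |
| max_initial_saccade_freq | 2 | Hz | chunking greed cap |
| saccade_context_window_length | 1 | s | SACC threshold context |
| min_saccade_duration | 0.01 | s | saccade candidate minimum |
| min_intersaccade_duration | 0.04 | s | proximity rule / search gate |
| max_pso_duration | 0.04 | s | PSO search window and cap |
| lowpass_cutoff_freq | 4 | Hz | pursuit decision filter |
| pursuit_velthresh | 2 | °/s | pursuit/fixation split |
| min_pursuit_duration | 0.04 | s | pursuit candidate minimum |
| min_fixation_duration | 0.04 | s | fixation candidate minimum |

## Known limitations

- Not real-time: chunking requires the full recording.
- Blinks are masked, not classified as events.
- Classification below ~250 Hz sampling is untested; filter windows
  round to very few samples there.
- Free-standing fixation↔pursuit transitions have intrinsically fuzzy
  boundaries (see above); velocities near `pursuit_velthresh` for long
  stretches will fragment into alternating `FIXA`/`PURS`.
- Thresholds inside a context containing a near-50/50 mixture of two
  well-separated velocity regimes can collapse to the lower mode.

## Problem sizes used in validation

The test suite and acceptance checks run on synthetic recordings of
8–60 s at 500–1000 Hz (up to ~60,000 samples), 50 randomized viewing
scripts for the structural invariants, and 100 random velocity vectors
for the threshold-oracle equivalence; the full suite completes in a few
seconds on one CPU.
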