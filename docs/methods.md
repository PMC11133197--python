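# Methods

## Signals and data model

Two per-eye channels of a video eye tracker are modeled, both in
millimeters at a nominal sampling rate (default 600 Hz):

- **Eye openness (EO)** — the diameter of the largest sphere that fits
  between the upper and lower eyelids.  It is defined even when the eye is
  closed, so data loss in this channel is rare.
- **Pupil size (PS)** — pupil diameter, which becomes invalid whenever the
  eyelid occludes the pupil.  Traditional blink detection operates on the
  loss pattern of this channel.

Invalid samples are carried as NaN with a `valid=False` flag rather than
dropped, so data-loss fractions and gap geometry remain computable at every
stage.  Timestamps are stored in seconds; loaders accept s/ms/µs input.  A
loaded sample counts as valid only if the tracker's validity flag is set
*and* the value parses as a positive finite number.

## The eye-openness detector

A blink is a high-velocity eyelid closure followed by a high-velocity
re-opening: a smooth trough in the EO trace.  The detector finds troughs
and delimits them with a robust velocity criterion.

**Parameters** (defaults; durations in ms):

| setting | default | role |
|---|---|---|
| `gap_fill_ms` | 40 | max loss run repaired by linear interpolation |
| `filter_len_ms` | 25 | Savitzky–Golay window (smoothing and velocity) |
| `min_amplitude_frac` | 0.10 | min blink amplitude, fraction of fully open |
| `onset_vel_mad_factor` | 3 | onset/offset threshold `T_vel = 3·MAD(v)` |
| `min_peak_vel_mad_factor` | 2 | lower phase peak must exceed `2·MAD(v)` |
| `min_duration_ms` | 30 | min blink duration |
| `merge_ms` | 100 | merge events closer than this |

The *fully open* reference is the median of the gap-interpolated EO series:
with blinks occupying a minority of samples, the median tracks the open-eye
baseline regardless of blink depth.  Both the amplitude rule (fraction of
the median) and the velocity rules (multiples of the MAD of the velocity)
are scale-free: scaling the signal by any positive constant leaves detected
onsets and offsets unchanged.

Filter windows are converted to samples as `round(ms · fs / 1000)`, forced
odd (25 ms at 600 Hz → 15 samples).  Savitzky–Golay output samples whose
window overlaps invalid data or the series edge are themselves invalid —
validity is propagated conservatively rather than extrapolated.

MAD here is the raw `median(|x − median(x)|)`, with no Gaussian consistency
constant; the 3× and 2× factors are calibrated to that convention.  MAD is
computed once over all valid velocity samples of the whole trial.  Since
blinks occupy a small fraction of a trial, `MAD(v)` reflects the noise
floor of the velocity estimate, and `T_vel` sits well above it but far
below genuine phase velocities.  The MAD is taken over signed velocities;
deviations about the median absorb the closing/opening sign asymmetry.

### Onset/offset expansion

Velocity is signed: closing negative, opening positive.  From each closure
trough the scan walks backward to the onset and forward to the offset in
two stages: first it skips samples until it reaches the *sought* fast phase
(closing for the backward scan, `v ≤ −T_vel`; opening for the forward scan,
`v ≥ +T_vel`), then it traverses that phase and stops at the first sample
where the signed velocity falls back inside the threshold.  Two robustness
choices matter here, both adopted after measuring their failure modes on
simulated trials:

- **Direction-signed thresholds.**  Peak finding on a flat closed plateau
  can place the trough near the plateau's edge, where the smoothing-smeared
  tail of the closing phase still exceeds `T_vel` in magnitude.  An
  unsigned (`|v|`) criterion then mistakes that tail for the opening phase
  and truncates the offset at the plateau entry (~1 % of simulated blinks,
  including outright misses when the truncated phase fails the velocity
  rule).  Requiring the correct sign removes the ambiguity.
- **Sustained-phase entry on the smoothed velocity.**  The scan runs on the
  velocity of the *smoothed* signal and only accepts entry into a fast
  phase after half a filter window (8 samples at 600 Hz) of consecutive
  supra-threshold samples.  `T_vel` is calibrated on the raw velocity,
  whose noise floor is several times higher, so after smoothing a genuine
  phase clears the threshold easily while isolated noise excursions on the
  plateau (≈2σ events at the raw calibration) cannot capture the scan.
  Measured on 1 200 simulated blinks, boundary failures drop from 251 (raw
  velocity, no sustain requirement) to 0, with unchanged median onset and
  offset errors (≈3 and ≈6–8 ms).

If no fast phase is found before a series edge or invalid data, the scan
returns the trough itself; such degenerate candidates are removed by the
duration rule.  Events whose scan stopped at an edge or a data-loss
boundary are flagged `clipped`.

Reported kinematics come from the *unfiltered* (gap-interpolated) signal
and its raw Savitzky–Golay velocity: eye openness at onset/offset/minimum,
closing and opening amplitudes, and the peak speed of each phase with its
time.  Closing is the onset→minimum phase and opening the minimum→offset
phase — closing precedes opening and is typically the faster of the two.
The amplitude rule uses the larger of the two phase amplitudes, so a blink
with a post-blink baseline shift is not rejected for its smaller side.

Candidates whose expansion windows overlap are collapsed onto the deeper
trough before kinematics are read; merging events closer than 100 ms then
recomputes kinematics over the union span.

### Known failure mode

Data loss concentrated at a blink's trough that exceeds `gap_fill_ms`
leaves no closure peak to find, and the blink is missed.  This is inherent
to peak-based detection and is reproduced (and tested) rather than papered
over; bridging such gaps would require assumptions about eyelid motion
inside unobserved intervals.

## The pupil-size baseline

Three steps: interpolate loss runs shorter than 40 ms; emit each remaining
maximal invalid run as a blink event; merge events separated by less than
100 ms.  Events are half-open — onset at the first invalid sample, offset
at the first valid sample after the run — so a 36-sample run at 600 Hz is
exactly 60 ms.  Optional physiological exclusions (disabled by default)
widen the loss mask first: non-positive diameters, and diameters outside
2–7 mm with a 50 ms margin invalidated on each side of every violating
run.  Optional event-duration bounds (30 ms–3 s) can post-filter the
events.  PS events carry no kinematic fields.

## Event matching and scoring

Two streams are matched one-to-one: events may pair only if their intervals
overlap; reference events are processed greedily in onset order and take
the unpaired test event with the largest overlap (ties: earlier test
onset).  F1 = 2·TP/(2·TP+FP+FN) and is symmetric in the streams; two empty
streams score 1.  Onset/offset deltas are reference minus test, summarized
by mean and sample SD (n−1 — event counts per recording are small).

## Data-quality metrics

Data loss is the invalid fraction of all reported samples.  RMS-S2S is the
root mean square of consecutive-sample differences over pairs of valid
samples, computed whole-series — including blink intervals, where eyelid
motion legitimately inflates EO RMS-S2S well above the quiescent noise
floor.  On pure i.i.d. Gaussian noise of SD σ, RMS-S2S → σ·√2.

Velocities can be reported in deg/s via a fixed 5 deg/mm factor; over the
typical blink range the mm-to-degree mapping of the eyelid along the
corneal surface is approximately linear.

## The simulator

`simulate_recording` emulates a prompted-blink trial: 60 s at 600 Hz, one
blink per second (optionally jittered), binocular, with ground-truth event
times and amplitudes.

- **Waveform**: half-cosine descent (63 ms) from the pre-blink baseline
  (8.75 mm) to the minimum (0.73 mm), flat closed plateau (50 ms),
  half-cosine ascent (138 ms) to the post-blink baseline (8.16 mm); between
  blinks the baseline relaxes linearly back to the pre-blink level.  The
  half-cosine family is C¹, parameter-sparse, and reproduces the
  faster-closing/slower-opening peak-velocity asymmetry (peak slope
  ∝ amplitude / phase duration); it is a stand-in for measured eyelid
  trajectories, not a physiological model.
- **Noise**: additive Gaussian, per-sample SD = target RMS-S2S / √2, so the
  quality metrics recover the target precision in expectation.  Defaults
  0.200 mm (EO) and 0.004 mm (PS).
- **Occlusion**: PS samples are invalid wherever the noise-free EO trace is
  below the pupil diameter (default 4 mm) — a sphere between the eyelids
  smaller than the pupil means the pupil is partly covered.  The threshold
  is configurable; the default makes each blink's PS-detectable span a
  strict subset of its EO span, which is the mechanism behind EO blinks
  starting earlier, ending later, and lasting longer.
- **Extra degradation**: `inject_data_loss` invalidates geometrically
  distributed runs (mean 50 ms) until a target loss fraction is reached,
  never revalidating anything; it deterministically reproduces per seed.

What the simulator does *not* emulate: gaze-dependent eyelid position,
saccade-coupled eyelid movement, pupil-size drift and the pre/post-blink
pupil-size dip artifact some trackers show, head-motion-induced loss
outside blinks, and non-Gaussian tracker noise.  Tests passing on
simulated data therefore demonstrate the algorithmic properties
(recovery, thresholds, ordering, degradation response), not performance on
any particular tracker's recordings.

## Numerical choices

- Gap-fill comparisons use a nanosecond-scale slack so a gap of exactly the
  threshold duration is never filled despite timestamp rounding.
- Gaps touching the series edges are never interpolated (no flanking
  support); filters never extrapolate across them.
- Peak finding runs with invalid samples held at the fully-open level, so
  residual loss can suppress but never fabricate a closure peak.
- Sample SD (n−1) throughout; medians via numpy partial sort.
- All simulator randomness flows from one integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical output.

## Problem sizes

The validation suite and the reproduction script run on simulated trials of
36 000 samples (60 s at 600 Hz, 60 blinks): ten trials for recovery and
kinematics, twenty for the EO-vs-PS containment check, and twenty seeds ×
six loss levels for the degradation experiment — about 150 full
simulate-and-detect cycles in well under a minute on one core.
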