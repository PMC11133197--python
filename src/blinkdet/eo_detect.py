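"""Blink detection from the eye-openness (EO) signal.

The detector classifies the characteristic blink waveform — a high-velocity
eyelid closure followed by a high-velocity re-opening — in a continuous
estimate of the distance between the eyelids (mm):

1. interpolate data-loss gaps shorter than ``gap_fill_ms``;
2. low-pass the EO signal with a Savitzky-Golay filter (peak finding only);
3. find closure peaks (local minima of eye openness);
4. differentiate the *unfiltered* EO signal with a Savitzky-Golay filter;
5. expand each peak backward/forward to where the eyelid speed falls below
   ``T_vel = onset_vel_mad_factor * MAD(v)``;
6. read the kinematics (amplitudes, peak closing/opening velocity) off the
   unfiltered signal;
7. reject candidates that are too small, too short, or too slow;
8. merge events separated by less than ``merge_ms``.

Closing (onset -> minimum openness) precedes opening (minimum -> offset);
the closing phase is typically faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .preprocess import (
    VelocitySeries,
    interpolate_gaps,
    mad,
    sg_smooth,
    sg_velocity,
    window_samples,
)
from .signal_io import BlinkEvent, DetectionSettings, Recording, SampleSeries

__all__ = [
    "BlinkCandidate",
    "FullyOpenLevel",
    "fully_open_level",
    "find_closure_peaks",
    "expand_candidate",
    "extract_kinematics",
    "reject_candidates",
    "merge_events",
    "detect_eo_blinks",
    "detect_eo_blinks_series",
]


@dataclass
class BlinkCandidate:
    """A closure peak expanded to tentative onset/offset sample indices."""

    trough_idx: int
    onset_idx: int
    offset_idx: int
    t_vel: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if not self.onset_idx <= self.trough_idx <= self.offset_idx:
            raise ValueError("need onset_idx <= trough_idx <= offset_idx")
        if not self.t_vel > 0:
            raise ValueError("T_vel must be positive")


@dataclass
class FullyOpenLevel:
    """Reference eye openness (mm) at which the eyelids count as fully open."""

    level: float

    def __post_init__(self) -> None:
        if not self.level > 0:
            raise ValueError("fully-open level must be positive")


def fully_open_level(eo: SampleSeries) -> FullyOpenLevel:
    """Median of the valid samples of the (gap-interpolated, unfiltered) EO series.

    The median is robust to the minority of samples spent inside blinks, so
    it tracks the open-eye baseline.
    """
    vals = eo.valid_values()
    if vals.size == 0:
        raise ValueError("cannot compute fully-open level: no valid samples")
    return FullyOpenLevel(float(np.median(vals)))


def find_closure_peaks(
    eo_smoothed: SampleSeries,
    settings: DetectionSettings,
    fully_open: Optional[float] = None,
) -> list[int]:
    """Indices of candidate closure peaks (local minima of eye openness).

    Runs peak detection on the negated smoothed series with prominence
    ``min_amplitude_frac * fully_open`` and minimum separation
    ``min_duration_ms`` — an early pruning only; final inclusion is decided
    by the rejection rules on unfiltered-signal kinematics.  Invalid samples
    are held at the baseline during peak finding so residual data loss can
    suppress, but never fabricate, a peak.
    """
    if fully_open is None:
        fully_open = fully_open_level(eo_smoothed).level
    x = eo_smoothed.value.copy()
    invalid = ~eo_smoothed.valid
    x[invalid] = fully_open
    distance = max(1, int(round(settings.min_duration_ms * eo_smoothed.fs / 1000.0)))
    idx, _ = find_peaks(-x, prominence=settings.min_amplitude_frac * fully_open,
                        distance=distance)
    return [int(i) for i in idx if not invalid[i]]


def _scan_edge(
    v: VelocitySeries, start: int, step: int, t_vel: float, sustain: int = 1
) -> tuple[int, bool]:
    """Walk outward from a trough to the onset (step=-1) or offset (step=+1).

    The fast phase sought is direction-signed: eyelid closing (before the
    trough) is fast when ``v <= -t_vel``, opening (after it) when
    ``v >= +t_vel`` — so the smeared tail of the closing phase can never be
    mistaken for the opening phase when a trough lands at the plateau edge.
    The scan skips samples outside the sought fast phase, traverses it, and
    returns the first sample past it where the signed velocity is back below
    threshold.  If no fast phase is reached before a series edge or invalid
    velocity sample, the trough itself is returned (a degenerate candidate,
    removed later by the duration rule).  ``clipped`` is set when the scan
    stopped at an edge or at invalid data.
    """
    n = len(v)
    sign = float(step)  # closing is negative velocity, opening positive
    i = start
    # Phase A: move outward until the sought fast phase is reached, i.e.
    # until `sustain` consecutive samples are past the threshold — a single
    # noise excursion must not pass for a closing/opening phase.
    run = 0
    while 0 <= i < n and v.valid[i]:
        if sign * v.v[i] >= t_vel:
            run += 1
            if run >= sustain:
                break
        else:
            run = 0
        i += step
    else:
        if not 0 <= i < n:
            # Never reached a fast phase; clipped only if the trough is on the edge.
            return start, start in (0, n - 1)
        return start, True  # stopped at invalid velocity data
    # Phase B: traverse the fast closing/opening phase.
    while 0 <= i < n and v.valid[i] and sign * v.v[i] >= t_vel:
        i += step
    if not 0 <= i < n:
        return (0 if step < 0 else n - 1), True
    if not v.valid[i]:
        return i - step, True
    return i, i in (0, n - 1)


def expand_candidate(
    v: VelocitySeries, trough_idx: int, t_vel: float, sustain: int = 1
) -> BlinkCandidate:
    """Expand a closure peak to onset/offset via the velocity threshold.

    ``sustain`` is the number of consecutive supra-threshold samples required
    to count as a genuine closing/opening phase (1 = accept any crossing;
    the detection pipeline uses half the smoothing window).
    """
    if not t_vel > 0:
        raise ValueError("T_vel must be positive")
    if not 0 <= trough_idx < len(v):
        raise ValueError("trough_idx outside the series")
    onset, clip_on = _scan_edge(v, trough_idx, -1, t_vel, sustain)
    offset, clip_off = _scan_edge(v, trough_idx, +1, t_vel, sustain)
    return BlinkCandidate(trough_idx, onset, offset, t_vel, clip_on or clip_off)


def extract_kinematics(
    eo: SampleSeries, v: VelocitySeries, cand: BlinkCandidate
) -> BlinkEvent:
    """Read blink kinematics off the unfiltered (gap-interpolated) EO signal.

    The minimum openness is located within [onset, offset] on the unfiltered
    series (the smoothed trough may sit a sample or two away).  Peak phase
    speeds are maxima of |v| over the closing (onset -> minimum) and opening
    (minimum -> offset) phases.  A phase with no valid velocity samples
    yields null velocities and a clipped event.
    """
    on, off = cand.onset_idx, cand.offset_idx
    if not (0 <= on <= off < len(eo)):
        raise ValueError("candidate indices outside the series")
    seg = eo.value[on:off + 1]
    clipped = cand.clipped
    if np.all(np.isnan(seg)):
        trough = cand.trough_idx
        eo_min = float("nan")
        clipped = True
    else:
        trough = on + int(np.nanargmin(seg))
        eo_min = float(eo.value[trough])

    def _phase_peak(lo: int, hi: int):
        speed = np.abs(v.v[lo:hi + 1])
        speed = np.where(v.valid[lo:hi + 1], speed, np.nan)
        if np.all(np.isnan(speed)):
            return None, None
        k = int(np.nanargmax(speed))
        return float(speed[k]), float(v.t[lo + k])

    peak_close, t_close = _phase_peak(on, trough)
    peak_open, t_open = _phase_peak(trough, off)
    if peak_close is None or peak_open is None:
        clipped = True

    def _val(i: int):
        x = float(eo.value[i])
        return x if np.isfinite(x) else None

    eo_on, eo_off = _val(on), _val(off)
    eo_min_out = eo_min if np.isfinite(eo_min) else None
    return BlinkEvent(
        onset_t=float(eo.t[on]),
        offset_t=float(eo.t[off]) if off > on else float(eo.t[on]) + 0.5 / eo.fs,
        eye=eo.eye,
        source="eo",
        t_min_openness=float(eo.t[trough]),
        eo_onset=eo_on,
        eo_offset=eo_off,
        eo_min=eo_min_out,
        closing_amp=(eo_on - eo_min_out) if eo_on is not None and eo_min_out is not None else None,
        opening_amp=(eo_off - eo_min_out) if eo_off is not None and eo_min_out is not None else None,
        peak_closing_vel=peak_close,
        t_peak_closing=t_close,
        peak_opening_vel=peak_open,
        t_peak_opening=t_open,
        clipped=clipped,
    )


def reject_candidates(
    events: list[BlinkEvent],
    settings: DetectionSettings,
    fully_open: float,
    mad_v: float,
) -> list[BlinkEvent]:
    """Apply the three rejection rules; order is preserved.

    Keep an event iff its larger phase amplitude reaches
    ``min_amplitude_frac * fully_open``, its duration reaches
    ``min_duration_ms``, and its *lower* peak phase velocity reaches
    ``min_peak_vel_mad_factor * mad_v``.  Events with unmeasurable phase
    velocities are rejected.
    """
    min_amp = settings.min_amplitude_frac * fully_open
    min_dur = settings.min_duration_ms / 1000.0
    min_vel = settings.min_peak_vel_mad_factor * mad_v
    kept = []
    for ev in events:
        amps = [a for a in (ev.closing_amp, ev.opening_amp) if a is not None]
        if not amps or max(amps) < min_amp:
            continue
        if ev.duration < min_dur:
            continue
        if ev.peak_closing_vel is None or ev.peak_opening_vel is None:
            continue
        if min(ev.peak_closing_vel, ev.peak_opening_vel) < min_vel:
            continue
        kept.append(ev)
    return kept


def merge_events(
    events: list[BlinkEvent],
    merge_ms: float,
    eo: SampleSeries,
    v: VelocitySeries,
) -> list[BlinkEvent]:
    """Merge events separated by less than ``merge_ms``, to a fixed point.

    The merged event spans from the first onset to the last offset with
    kinematics recomputed over the union (its minimum-openness sample is the
    global minimum across the span).  Output gaps are all >= ``merge_ms``.
    """
    events = list(events)
    for a, b in zip(events, events[1:]):
        if b.onset_t < a.offset_t:
            raise ValueError("merge_events requires sorted, non-overlapping events")
    gap = merge_ms / 1000.0
    changed = True
    while changed:
        changed = False
        out: list[BlinkEvent] = []
        for ev in events:
            if out and ev.onset_t - out[-1].offset_t < gap:
                prev = out.pop()
                on = int(np.searchsorted(eo.t, prev.onset_t))
                off = int(np.searchsorted(eo.t, ev.offset_t))
                cand = BlinkCandidate(
                    trough_idx=min(max(on, int(np.searchsorted(eo.t, prev.t_min_openness or prev.onset_t))), off),
                    onset_idx=on, offset_idx=off,
                    t_vel=1.0,  # placeholder; kinematics do not use it
                    clipped=prev.clipped or ev.clipped,
                )
                out.append(extract_kinematics(eo, v, cand))
                changed = True
            else:
                out.append(ev)
        events = out
    return events


def _collapse_overlapping(
    cands: list[BlinkCandidate], eo_smoothed: SampleSeries
) -> list[BlinkCandidate]:
    """Collapse candidates whose expansion windows overlap onto the deeper trough.

    Noisy double minima within one closure expand to near-identical windows;
    keeping the deeper one prevents duplicate events.
    """
    cands = sorted(cands, key=lambda c: (c.onset_idx, c.trough_idx))
    out: list[BlinkCandidate] = []
    for c in cands:
        if out and c.onset_idx <= out[-1].offset_idx:
            prev = out[-1]
            depth_prev = eo_smoothed.value[prev.trough_idx]
            depth_new = eo_smoothed.value[c.trough_idx]
            keep = prev if not (depth_new < depth_prev) else c
            merged = BlinkCandidate(
                trough_idx=keep.trough_idx,
                onset_idx=min(prev.onset_idx, c.onset_idx),
                offset_idx=max(prev.offset_idx, c.offset_idx),
                t_vel=keep.t_vel,
                clipped=prev.clipped or c.clipped,
            )
            out[-1] = merged
        else:
            out.append(c)
    return out


def detect_eo_blinks_series(
    eo: SampleSeries, settings: Optional[DetectionSettings] = None
) -> list[BlinkEvent]:
    """Run the full EO blink-detection pipeline on one eye-openness series."""
    if settings is None:
        settings = DetectionSettings()
    filled = interpolate_gaps(eo, settings.gap_fill_ms)
    smoothed = sg_smooth(filled, settings.filter_len_ms)
    vel = sg_velocity(filled, settings.filter_len_ms)
    # Boundary expansion runs on the velocity of the *smoothed* signal: the
    # threshold T_vel is calibrated on the raw velocity, whose noise floor the
    # smoothing shrinks by ~sqrt(window), so a noise excursion can no longer
    # strand an onset/offset inside the closed plateau.  Kinematic peak
    # velocities are still read from the raw (unfiltered) velocity.
    vel_smooth = sg_velocity(smoothed, settings.filter_len_ms)

    open_level = fully_open_level(filled).level
    mad_v = mad(vel.v[vel.valid])
    if mad_v <= 0:
        return []
    t_vel = settings.onset_vel_mad_factor * mad_v

    troughs = find_closure_peaks(smoothed, settings, fully_open=open_level)
    sustain = max(1, window_samples(settings.filter_len_ms, eo.fs) // 2 + 1)
    cands = [expand_candidate(vel_smooth, i, t_vel, sustain) for i in troughs]
    cands = _collapse_overlapping(cands, smoothed)
    events = [extract_kinematics(filled, vel, c) for c in cands]
    events = reject_candidates(events, settings, open_level, mad_v)
    return merge_events(events, settings.merge_ms, filled, vel)


def detect_eo_blinks(
    recording: Recording, eye: str, settings: Optional[DetectionSettings] = None
) -> list[BlinkEvent]:
    """Detect blinks in the eye-openness channel of one eye of a recording."""
    return detect_eo_blinks_series(recording.get("eo", eye), settings)
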