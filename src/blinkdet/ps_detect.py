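"""The 'standard' pupil-size (PS) blink detector used as a comparison baseline.

In pupil / corneal-reflection video eye trackers the eyelid occludes the
pupil during a blink, so blinks are traditionally operationalized as runs of
invalid samples in the pupil-diameter signal: interpolate short data-loss
gaps, take each remaining loss run as a blink, and merge runs that are close
in time.  Optional physiological exclusion criteria (non-positive diameters;
diameters outside plausible bounds, with a margin around each violation)
can widen the loss mask first.

PS events carry no kinematics: the signal says nothing about the eyelids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .preprocess import find_invalid_runs, interpolate_gaps
from .signal_io import BlinkEvent, DetectionSettings, SampleSeries

__all__ = ["PsOptions", "apply_exclusions", "detect_ps_blinks"]


@dataclass
class PsOptions:
    """Options of the PS detector.

    ``exclude_nonpositive`` drops diameters <= 0; ``min_diameter_mm`` /
    ``max_diameter_mm`` (e.g. 2 and 7) drop physiologically implausible
    diameters, and ``exclusion_margin_ms`` additionally invalidates that
    margin on each side of every bound-violating run.  The optional event
    duration bounds (disabled by default) post-filter the detected events.
    """

    exclude_nonpositive: bool = False
    min_diameter_mm: Optional[float] = None
    max_diameter_mm: Optional[float] = None
    exclusion_margin_ms: float = 50.0
    min_duration_ms: Optional[float] = None
    max_duration_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.min_diameter_mm is not None and self.max_diameter_mm is not None
                and not self.min_diameter_mm < self.max_diameter_mm):
            raise ValueError("min_diameter_mm must be < max_diameter_mm")
        if self.exclusion_margin_ms < 0:
            raise ValueError("exclusion_margin_ms must be >= 0")

    @classmethod
    def from_settings(cls, settings: DetectionSettings) -> "PsOptions":
        return cls(
            exclude_nonpositive=settings.ps_exclude_nonpositive,
            min_diameter_mm=settings.ps_min_diameter_mm,
            max_diameter_mm=settings.ps_max_diameter_mm,
            exclusion_margin_ms=settings.ps_exclusion_margin_ms,
        )


def apply_exclusions(ps: SampleSeries, opts: PsOptions) -> SampleSeries:
    """Invalidate physiologically implausible pupil-diameter samples.

    Bound-violating samples are marked invalid, and so is everything within
    ``exclusion_margin_ms`` of each violating run.  Never validates an
    invalid sample, so data loss is monotone non-decreasing.
    """
    out = ps.copy()
    bad = np.zeros(len(out), dtype=bool)
    with np.errstate(invalid="ignore"):
        if opts.exclude_nonpositive:
            bad |= out.valid & (out.value <= 0)
        if opts.min_diameter_mm is not None:
            bad |= out.valid & (out.value < opts.min_diameter_mm)
        if opts.max_diameter_mm is not None:
            bad |= out.valid & (out.value > opts.max_diameter_mm)
    if not bad.any():
        return out
    margin = int(round(opts.exclusion_margin_ms * ps.fs / 1000.0))
    mask = bad.copy()
    if margin:
        padded = np.concatenate(([False], bad, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            mask[max(0, s - margin):min(len(mask), e + margin)] = True
    out.valid &= ~mask
    out.value[~out.valid] = np.nan
    return out


def detect_ps_blinks(
    ps: SampleSeries,
    settings: Optional[DetectionSettings] = None,
    opts: Optional[PsOptions] = None,
) -> list[BlinkEvent]:
    """Detect blinks as maximal runs of data loss in the pupil-size signal.

    Pipeline: optional exclusions -> interpolate gaps shorter than
    ``gap_fill_ms`` -> one event per remaining invalid run -> merge events
    separated by less than ``merge_ms`` -> optional duration bounds.

    Event intervals are half-open: onset at the first invalid sample, offset
    at the first valid sample after the run, so a run of k samples lasts
    exactly ``k / fs`` seconds.  A run reaching the series end is clipped and
    closed one nominal interval past the last sample.
    """
    if settings is None:
        settings = DetectionSettings()
    if opts is None:
        opts = PsOptions.from_settings(settings)

    cleaned = apply_exclusions(ps, opts)
    filled = interpolate_gaps(cleaned, settings.gap_fill_ms)

    n = len(filled)
    intervals = []  # (onset_t, offset_t, clipped)
    for start, end, _dur in find_invalid_runs(filled):
        onset_t = float(filled.t[start])
        if end < n:
            offset_t = float(filled.t[end])
            clipped = start == 0
        else:
            offset_t = float(filled.t[-1]) + filled.dt
            clipped = True
        intervals.append((onset_t, offset_t, clipped))

    # Merge intervals separated by less than merge_ms, to a fixed point.
    gap = settings.merge_ms / 1000.0
    merged: list[list] = []
    for onset_t, offset_t, clipped in intervals:
        if merged and onset_t - merged[-1][1] < gap:
            merged[-1][1] = offset_t
            merged[-1][2] = merged[-1][2] or clipped
        else:
            merged.append([onset_t, offset_t, clipped])

    events = [
        BlinkEvent(onset_t=o, offset_t=f, eye=ps.eye, source="ps", clipped=c)
        for o, f, c in merged
    ]
    if opts.min_duration_ms is not None:
        events = [e for e in events if e.duration >= opts.min_duration_ms / 1000.0]
    if opts.max_duration_ms is not None:
        events = [e for e in events if e.duration <= opts.max_duration_ms / 1000.0]
    return events
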