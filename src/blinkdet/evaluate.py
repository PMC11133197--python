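"""Comparison of two event streams and signal data-quality metrics.

Event streams are matched one-to-one by temporal overlap and scored with the
event-based F1 = 2*TP / (2*TP + FP + FN).  Signal quality is summarized by
the data-loss fraction (invalid samples / reported samples) and the RMS
sample-to-sample deviation (root mean square of consecutive-sample
differences, computed over pairs of valid samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signal_io import BlinkEvent, SampleSeries

__all__ = [
    "MatchResult",
    "QualityReport",
    "match_events",
    "onset_offset_deltas",
    "summarize_events",
    "quality_report",
    "mm_to_deg",
]


@dataclass
class MatchResult:
    """One-to-one pairing of a reference (a) and a test (b) event stream."""

    pairs: list = field(default_factory=list)  # (ref_event, test_event)
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_b)

    @property
    def fn(self) -> int:
        return len(self.unmatched_a)

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            return 1.0  # two empty streams agree perfectly
        return 2.0 * self.tp / denom


@dataclass
class QualityReport:
    """Data-quality summary of one sample series."""

    n_samples: int
    n_valid: int
    data_loss_frac: float
    rms_s2s: Optional[float]


def _check_stream(events: Sequence[BlinkEvent], name: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.onset_t < a.onset_t:
            raise ValueError(f"{name} events are not sorted by onset")
        if b.onset_t < a.offset_t:
            raise ValueError(f"{name} events overlap")


def _overlap(a: BlinkEvent, b: BlinkEvent) -> float:
    return min(a.offset_t, b.offset_t) - max(a.onset_t, b.onset_t)


def match_events(ref: Sequence[BlinkEvent], test: Sequence[BlinkEvent]) -> MatchResult:
    """Match two event streams one-to-one by temporal overlap.

    A reference and a test event may pair only if their intervals overlap.
    Reference events are processed greedily in onset order; each takes the
    still-unpaired test event with the largest overlap (ties broken by the
    earlier test onset).  F1 is symmetric in the two streams: swapping them
    swaps FP and FN but leaves TP, and hence F1, unchanged.
    """
    ref, test = list(ref), list(test)
    _check_stream(ref, "ref")
    _check_stream(test, "test")
    taken = [False] * len(test)
    result = MatchResult()
    for r in ref:
        best_j, best_ov = None, 0.0
        for j, t in enumerate(test):
            if taken[j]:
                continue
            if t.onset_t >= r.offset_t:
                break  # sorted: nothing later can overlap
            ov = _overlap(r, t)
            if ov > 0 and (best_j is None or ov > best_ov):
                best_j, best_ov = j, ov
        if best_j is None:
            result.unmatched_a.append(r)
        else:
            taken[best_j] = True
            result.pairs.append((r, test[best_j]))
    result.unmatched_b = [t for j, t in enumerate(test) if not taken[j]]
    return result


def onset_offset_deltas(match: MatchResult) -> dict:
    """Mean and sample SD of per-pair onset/offset differences, in seconds.

    Deltas are reference minus test, so a negative mean onset delta means the
    reference events start earlier.
    """
    if not match.pairs:
        raise ValueError("no matched pairs to summarize")
    onset = np.array([r.onset_t - t.onset_t for r, t in match.pairs])
    offset = np.array([r.offset_t - t.offset_t for r, t in match.pairs])
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else None
    return {
        "n_pairs": len(match.pairs),
        "onset_delta_mean": float(onset.mean()),
        "onset_delta_sd": sd(onset),
        "offset_delta_mean": float(offset.mean()),
        "offset_delta_sd": sd(offset),
    }


def summarize_events(events: Sequence[BlinkEvent], recording_duration_s: float) -> dict:
    """Rate and moment summary of one event stream.

    Kinematic moments are reported only over events that carry the field
    (PS events carry none) and are ``None`` otherwise.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording_duration_s must be positive")
    events = list(events)
    out: dict = {"n_events": len(events), "rate_hz": len(events) / recording_duration_s}

    def moments(values: list) -> tuple:
        vals = [v for v in values if v is not None]
        if not vals:
            return None, None
        arr = np.asarray(vals, dtype=float)
        return float(arr.mean()), (float(arr.std(ddof=1)) if len(arr) > 1 else None)

    out["duration_mean_s"], out["duration_sd_s"] = moments([e.duration for e in events])
    out["closing_amp_mean_mm"], _ = moments([e.closing_amp for e in events])
    out["opening_amp_mean_mm"], _ = moments([e.opening_amp for e in events])
    out["peak_closing_vel_mean_mm_s"], _ = moments([e.peak_closing_vel for e in events])
    out["peak_opening_vel_mean_mm_s"], _ = moments([e.peak_opening_vel for e in events])
    return out


def quality_report(series: SampleSeries) -> QualityReport:
    """Data loss and RMS sample-to-sample deviation of a series.

    Loss is the invalid fraction of all reported samples.  RMS-S2S is
    computed over consecutive-sample differences where both samples are
    valid, whole-series (blink periods included, which inflates eye-openness
    RMS-S2S relative to the quiescent noise floor — deliberately so, to
    match the data-loss operationalization).  ``None`` when no valid pair
    exists.
    """
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    n_valid = series.n_valid
    pair_ok = series.valid[:-1] & series.valid[1:]
    if pair_ok.any():
        d = np.diff(series.value)[pair_ok]
        rms = float(np.sqrt(np.mean(d * d)))
    else:
        rms = None
    return QualityReport(
        n_samples=n,
        n_valid=n_valid,
        data_loss_frac=1.0 - n_valid / n,
        rms_s2s=rms,
    )


def mm_to_deg(v_mm_per_s: float, deg_per_mm: float = 5.0) -> float:
    """Convert an eyelid speed from mm/s to deg/s.

    The eyelid rides the curved corneal surface; over the typical blink range
    (roughly +-30 degrees over about 12 mm) the mm-to-degree relationship is
    close to linear, hence a single factor (default 5 deg/mm).
    """
    if deg_per_mm <= 0:
        raise ValueError("deg_per_mm must be positive")
    return v_mm_per_s * deg_per_mm
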