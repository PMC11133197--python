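"""Shared numerics of both blink detectors.

Gap bookkeeping and linear interpolation of short data-loss runs,
Savitzky-Golay smoothing and differentiation, and the median absolute
deviation used to set velocity thresholds.

Validity is propagated conservatively through the filters: an output sample
is invalid whenever its filter window overlaps any invalid input sample or
extends past the series edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

from .signal_io import SENTINEL, SampleSeries

__all__ = [
    "VelocitySeries",
    "find_invalid_runs",
    "interpolate_gaps",
    "window_samples",
    "sg_smooth",
    "sg_velocity",
    "mad",
]


@dataclass
class VelocitySeries:
    """First derivative of an eye-openness series, in mm/s.

    Shares the timebase of its source series.  Closing is negative, opening
    positive; detection thresholds compare ``abs(v)``.
    """

    t: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.v) == len(self.valid)):
            raise ValueError("t, v, valid must have equal length")

    def __len__(self) -> int:
        return len(self.t)


def find_invalid_runs(series: SampleSeries) -> list[tuple[int, int, float]]:
    """Maximal runs of invalid samples as ``(start, end, duration_ms)``.

    Index intervals are half-open ``[start, end)``.  A run of k samples at
    nominal interval dt lasts ``k * dt`` (the span of its samples plus one
    nominal interval).
    """
    invalid = ~series.valid
    if not invalid.any():
        return []
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    runs = []
    for s, e in zip(starts, ends):
        duration_ms = (series.t[e - 1] - series.t[s]) * 1000.0 + 1000.0 / series.fs
        runs.append((int(s), int(e), float(duration_ms)))
    return runs


def interpolate_gaps(series: SampleSeries, max_gap_ms: float) -> SampleSeries:
    """Linearly fill invalid runs shorter than ``max_gap_ms``.

    Only runs with valid samples on both flanks are filled (edge-touching
    gaps have no interpolation support and stay invalid); filled samples are
    marked valid.  The input is not mutated; the operation is idempotent.
    """
    if max_gap_ms < 0:
        raise ValueError("max_gap_ms must be >= 0")
    out = series.copy()
    n = len(out)
    for start, end, duration_ms in find_invalid_runs(series):
        # strict "shorter than" with ns-scale slack so a gap of exactly the
        # threshold duration is never filled despite timestamp rounding
        if duration_ms >= max_gap_ms - 1e-6 or start == 0 or end == n:
            continue
        left, right = start - 1, end
        out.value[start:end] = np.interp(
            out.t[start:end],
            [out.t[left], out.t[right]],
            [series.value[left], series.value[right]],
        )
        out.valid[start:end] = True
    return out


def window_samples(window_ms: float, fs: float, order: int = 2) -> int:
    """Filter window length in samples: ``round(window_ms * fs / 1000)``,
    forced odd by incrementing, and at least ``order + 1`` (odd)."""
    w = int(round(window_ms * fs / 1000.0))
    if w % 2 == 0:
        w += 1
    min_w = order + 1 if (order + 1) % 2 == 1 else order + 2
    return max(w, min_w)


def _sg_apply(series: SampleSeries, window_ms: float, order: int, deriv: int) -> np.ndarray:
    w = window_samples(window_ms, series.fs, order)
    if len(series) < w:
        raise ValueError(f"series of length {len(series)} shorter than filter window {w}")
    coeffs = savgol_coeffs(w, order, deriv=deriv, delta=series.dt, use="conv")
    # np.convolve with 'conv'-ordered coefficients reproduces the interior of
    # scipy.signal.savgol_filter; NaN sentinels poison every window they touch.
    values = series.value.copy()
    values[~series.valid] = np.nan  # ensure sentinel, not just flag
    out = np.convolve(values, coeffs, mode="same")
    half = w // 2
    if half:
        out[:half] = np.nan
        out[-half:] = np.nan
    return out


def sg_smooth(series: SampleSeries, window_ms: float = 25.0, order: int = 2) -> SampleSeries:
    """Savitzky-Golay low-pass filter (local least-squares polynomial fit).

    Each valid output sample is the order-``order`` polynomial least-squares
    fit over the centered window, evaluated at the center; polynomials of
    degree <= ``order`` are reproduced exactly on window interiors.
    """
    out = _sg_apply(series, window_ms, order, deriv=0)
    valid = np.isfinite(out)
    out[~valid] = SENTINEL
    return SampleSeries(series.t, out, valid, series.fs, series.channel, series.eye)


def sg_velocity(series: SampleSeries, window_ms: float = 25.0, order: int = 2) -> VelocitySeries:
    """Savitzky-Golay first derivative, in mm/s.

    Applied to the *unfiltered* (gap-interpolated) series; the derivative of
    the local polynomial fit is evaluated at the window center and scaled by
    the sample interval to physical units.
    """
    v = _sg_apply(series, window_ms, order, deriv=1)
    valid = np.isfinite(v)
    v[~valid] = SENTINEL
    return VelocitySeries(series.t, v, valid, series.fs)


def mad(values) -> float:
    """Median absolute deviation, without any consistency scaling.

    ``median(|x - median(x)|)`` over the finite entries of ``values``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("mad of an empty (or all-invalid) vector")
    med = np.median(x)
    return float(np.median(np.abs(x - med)))
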