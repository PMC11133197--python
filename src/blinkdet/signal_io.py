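"""Shared data model and delimited-text I/O for eye-openness / pupil-size recordings.

The central containers are :class:`SampleSeries` (one channel of one eye:
timestamps, values in mm, per-sample validity), :class:`Recording` (up to four
series on a common timebase), :class:`DetectionSettings` (the blink-detection
parameters) and :class:`BlinkEvent` (one detected blink).

Invalid samples are *carried*, not dropped: they hold the sentinel value
(NaN) and ``valid=False``, so that data-loss metrics and gap geometry stay
computable downstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENTINEL",
    "EVENT_COLUMNS",
    "SampleSeries",
    "Recording",
    "DetectionSettings",
    "BlinkEvent",
    "LoadError",
    "read_recording",
    "write_events",
    "read_events",
    "read_settings",
    "write_settings",
]

#: Sentinel stored at invalid samples.
SENTINEL = float("nan")

#: Exact column order of the events TSV dialect.
EVENT_COLUMNS = [
    "eye",
    "source",
    "onset_t",
    "offset_t",
    "duration",
    "t_min_openness",
    "eo_onset",
    "eo_offset",
    "eo_min",
    "closing_amp",
    "opening_amp",
    "peak_closing_vel",
    "t_peak_closing",
    "peak_opening_vel",
    "t_peak_opening",
    "clipped",
]

_TIME_UNIT_TO_S = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


class LoadError(ValueError):
    """Raised when a recording, event table, or settings file cannot be read."""


@dataclass
class SampleSeries:
    """One channel of a recording: a uniformly sampled signal with validity flags.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    value : array of float
        Measurement in mm (eye openness or pupil diameter). Invalid samples
        hold NaN.
    valid : array of bool
        Per-sample validity flag from the tracker (plus any exclusions).
    fs : float
        Nominal sampling frequency in Hz.
    channel : {"eo", "ps"}
    eye : {"left", "right"}
    """

    t: np.ndarray
    value: np.ndarray
    valid: np.ndarray
    fs: float
    channel: str = "eo"
    eye: str = "left"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float).copy()
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if not (len(self.t) == len(self.value) == len(self.valid)):
            raise ValueError("t, value, valid must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.channel not in ("eo", "ps"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.eye not in ("left", "right"):
            raise ValueError(f"unknown eye {self.eye!r}")
        # Enforce the sentinel invariant both ways.
        self.valid &= np.isfinite(self.value)
        self.value[~self.valid] = SENTINEL

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Nominal sample interval in seconds."""
        return 1.0 / self.fs

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def valid_values(self) -> np.ndarray:
        return self.value[self.valid]

    def copy(self) -> "SampleSeries":
        return SampleSeries(
            self.t.copy(), self.value.copy(), self.valid.copy(),
            self.fs, self.channel, self.eye,
        )


@dataclass
class Recording:
    """Up to four series (eo/ps x left/right) sharing one timebase, plus metadata."""

    series: dict = field(default_factory=dict)  # (channel, eye) -> SampleSeries
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("a Recording needs at least one series")
        ts = [s.t for s in self.series.values()]
        for other in ts[1:]:
            if len(other) != len(ts[0]) or not np.array_equal(other, ts[0]):
                raise ValueError("all series in a Recording must share the same timebase")

    def get(self, channel: str, eye: str) -> SampleSeries:
        try:
            return self.series[(channel, eye)]
        except KeyError:
            raise KeyError(f"recording has no {channel!r} series for eye {eye!r}") from None

    def has(self, channel: str, eye: str) -> bool:
        return (channel, eye) in self.series

    @property
    def duration_s(self) -> float:
        any_series = next(iter(self.series.values()))
        return float(any_series.t[-1] - any_series.t[0] + any_series.dt)


@dataclass
class DetectionSettings:
    """Parameters of the eye-openness blink detector and the pupil-size baseline.

    Durations are milliseconds. ``min_amplitude_frac`` is a fraction of the
    "fully open" level (the per-series median eye openness).  The velocity
    threshold that delimits onset/offset is ``onset_vel_mad_factor *
    MAD(v)``; candidates whose lower peak-phase velocity falls below
    ``min_peak_vel_mad_factor * MAD(v)`` are rejected.
    """

    gap_fill_ms: float = 40.0
    filter_len_ms: float = 25.0
    min_amplitude_frac: float = 0.10
    onset_vel_mad_factor: float = 3.0
    min_peak_vel_mad_factor: float = 2.0
    min_duration_ms: float = 30.0
    merge_ms: float = 100.0
    ps_exclude_nonpositive: bool = False
    ps_min_diameter_mm: Optional[float] = None
    ps_max_diameter_mm: Optional[float] = None
    ps_exclusion_margin_ms: float = 50.0
    deg_per_mm: float = 5.0  # reporting convenience only

    def __post_init__(self) -> None:
        for name in ("gap_fill_ms", "filter_len_ms", "min_duration_ms",
                     "merge_ms", "ps_exclusion_margin_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.min_amplitude_frac < 1.0:
            raise ValueError("min_amplitude_frac must lie in (0, 1)")
        if not (self.onset_vel_mad_factor >= self.min_peak_vel_mad_factor > 0):
            raise ValueError(
                "need onset_vel_mad_factor >= min_peak_vel_mad_factor > 0"
            )
        if (self.ps_min_diameter_mm is not None and self.ps_max_diameter_mm is not None
                and not self.ps_min_diameter_mm < self.ps_max_diameter_mm):
            raise ValueError("ps_min_diameter_mm must be < ps_max_diameter_mm")
        if self.deg_per_mm <= 0:
            raise ValueError("deg_per_mm must be positive")


@dataclass
class BlinkEvent:
    """One detected blink.

    For EO-detected events the kinematic fields are populated; for PS events
    (pure data-loss intervals) they are ``None``.  ``clipped`` flags events
    whose onset or offset hit a series edge or a data-loss boundary.
    """

    onset_t: float
    offset_t: float
    eye: str = "left"
    source: str = "eo"
    t_min_openness: Optional[float] = None
    eo_onset: Optional[float] = None
    eo_offset: Optional[float] = None
    eo_min: Optional[float] = None
    closing_amp: Optional[float] = None
    opening_amp: Optional[float] = None
    peak_closing_vel: Optional[float] = None
    t_peak_closing: Optional[float] = None
    peak_opening_vel: Optional[float] = None
    t_peak_opening: Optional[float] = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if not self.onset_t < self.offset_t:
            raise ValueError("onset_t must precede offset_t")
        if self.source not in ("eo", "ps"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def duration(self) -> float:
        """Event duration in seconds."""
        return self.offset_t - self.onset_t

    def overlaps(self, other: "BlinkEvent") -> bool:
        return min(self.offset_t, other.offset_t) > max(self.onset_t, other.onset_t)


# ---------------------------------------------------------------------------
# Recording I/O


def _parse_column_map(column_map: dict, df: pd.DataFrame) -> tuple:
    time_col = column_map.get("time")
    if time_col is None:
        raise LoadError("column_map must name a 'time' column")
    unit = column_map.get("time_unit", "s")
    if unit not in _TIME_UNIT_TO_S:
        raise LoadError(f"unknown time unit {unit!r}; use one of {sorted(_TIME_UNIT_TO_S)}")
    entries = column_map.get("series")
    if not entries:
        raise LoadError("column_map must declare at least one series")
    for col in [time_col] + [c for e in entries for c in (e["value"], e["valid"])]:
        if col not in df.columns:
            raise LoadError(f"mapped column {col!r} not found in file")
    return time_col, _TIME_UNIT_TO_S[unit], entries


def read_recording(path, column_map: dict, fs: float) -> Recording:
    """Read a delimited-text per-sample recording.

    ``column_map`` declares which columns hold what::

        {"time": "timestamp", "time_unit": "us",      # s | ms | us
         "series": [{"channel": "eo", "eye": "left",
                     "value": "eo_left", "valid": "eo_left_valid"}, ...]}

    A sample is valid only when its validity column is truthy *and* its value
    parses as a positive finite number; everything else becomes the NaN
    sentinel with ``valid=False``.  Timestamps are converted to seconds.  If
    the median sample interval deviates from 1/fs by more than 20%, a warning
    string is recorded in ``Recording.meta["warnings"]``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    time_col, scale, entries = _parse_column_map(column_map, df)

    t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float) * scale
    if np.any(~np.isfinite(t)):
        raise LoadError("time column contains non-numeric entries")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise LoadError("timestamps are not strictly increasing")

    meta: dict = {"path": str(path), "warnings": []}
    if len(t) > 1:
        med_dt = float(np.median(np.diff(t)))
        if abs(med_dt - 1.0 / fs) > 0.2 / fs:
            meta["warnings"].append(
                f"median sample interval {med_dt:.6g} s deviates >20% from 1/fs={1.0 / fs:.6g} s"
            )

    series = {}
    for entry in entries:
        values = pd.to_numeric(df[entry["value"]], errors="coerce").to_numpy(dtype=float)
        flags = df[entry["valid"]].astype(bool).to_numpy()
        valid = flags & np.isfinite(values) & (values > 0)
        values = np.where(valid, values, SENTINEL)
        key = (entry["channel"], entry["eye"])
        series[key] = SampleSeries(t, values, valid, fs, *key)
    return Recording(series=series, meta=meta)


# ---------------------------------------------------------------------------
# Events TSV


def _event_to_row(ev: BlinkEvent) -> dict:
    row = {}
    for col in EVENT_COLUMNS:
        if col == "duration":
            row[col] = ev.duration
        else:
            row[col] = getattr(ev, col)
    return row


def write_events(events: Sequence[BlinkEvent], path) -> None:
    """Write events as a TSV (tab-separated, '.' decimal, header row).

    Column order is fixed (:data:`EVENT_COLUMNS`); ``None`` kinematic fields
    become empty cells.  Events must be sorted by onset time.
    """
    events = list(events)
    for a, b in zip(events, events[1:]):
        if b.onset_t < a.onset_t:
            raise ValueError("events must be sorted by onset_t before writing")
    df = pd.DataFrame([_event_to_row(e) for e in events], columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_events(path) -> list[BlinkEvent]:
    """Read an events TSV written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", dtype={"eye": str, "source": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"events file missing columns: {missing}")
    events = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in EVENT_COLUMNS:
            if col == "duration":
                continue
            val = row[col]
            if col in ("eye", "source"):
                kwargs[col] = str(val)
            elif col == "clipped":
                kwargs[col] = bool(val)
            else:
                kwargs[col] = None if pd.isna(val) else float(val)
        events.append(BlinkEvent(**kwargs))
    return events


# ---------------------------------------------------------------------------
# Settings JSON


def read_settings(path) -> DetectionSettings:
    """Load :class:`DetectionSettings` from JSON; unknown keys are an error."""
    with open(path) as fh:
        data = json.load(fh)
    known = {f.name for f in dataclasses.fields(DetectionSettings)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise LoadError(f"unknown settings keys: {unknown}")
    return DetectionSettings(**data)


def write_settings(settings: DetectionSettings, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(settings), fh, indent=2)
        fh.write("\n")
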