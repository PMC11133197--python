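"""Synthetic binocular eye-openness / pupil-size recordings with ground truth.

The generator emulates prompted-blink trials on a 600 Hz video eye tracker:
an eye-openness (EO) channel carrying asymmetric blink waveforms (fast
closing, brief closed plateau, slower opening) over a slowly recovering
baseline, and a pupil-size (PS) channel whose samples are lost whenever the
eyelid aperture drops below the pupil diameter (occlusion).  Additive
Gaussian noise is calibrated so that the RMS sample-to-sample deviation of a
blink-free stretch matches the target precision; extra random data loss can
be injected to emulate degraded tracking.

Blink waveforms are half-cosine phases: C1-smooth, parameter-sparse, and
with the faster-closing / slower-opening peak-velocity asymmetry seen in
real eyelid kinematics.  They are a stand-in for measured eyelid
trajectories, not a physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .signal_io import Recording, SampleSeries

__all__ = [
    "BlinkShape",
    "SimConfig",
    "TrueBlink",
    "GroundTruth",
    "blink_waveform",
    "simulate_recording",
    "inject_data_loss",
]


@dataclass
class BlinkShape:
    """Geometry of one blink waveform.

    Defaults follow typical alert spontaneous blinks: closing ~63 ms, eyes
    closed ~50 ms, opening ~138 ms; eyelid aperture ~8.75 mm before the
    blink, ~0.73 mm at minimum, and slightly lower (~8.16 mm) after, since
    the eyelids often do not return all the way.
    """

    closing_ms: float = 63.0
    opening_ms: float = 138.0
    plateau_ms: float = 50.0
    min_openness_mm: float = 0.73
    baseline_before_mm: float = 8.75
    baseline_after_mm: float = 8.16

    def __post_init__(self) -> None:
        if self.closing_ms <= 0 or self.opening_ms <= 0:
            raise ValueError("closing_ms and opening_ms must be positive")
        if self.plateau_ms < 0:
            raise ValueError("plateau_ms must be >= 0")
        if not (self.min_openness_mm < self.baseline_before_mm
                and self.min_openness_mm < self.baseline_after_mm):
            raise ValueError("both baselines must exceed min_openness_mm")
        if self.min_openness_mm < 0:
            raise ValueError("min_openness_mm must be >= 0")

    @property
    def footprint_s(self) -> float:
        return (self.closing_ms + self.plateau_ms + self.opening_ms) / 1000.0


@dataclass
class SimConfig:
    """Study conditions of a simulated trial.

    Defaults emulate a 60 s prompted-blink trial (blink every second) at
    600 Hz, with noise magnitudes set so that the recovered RMS-S2S
    precision is ~0.200 mm (EO) and ~0.004 mm (PS) — per-sample noise SD is
    the target RMS-S2S divided by sqrt(2).  The pupil becomes unmeasurable
    when the noise-free eyelid aperture falls below ``occlusion_threshold``
    (default: the pupil diameter itself).
    """

    fs: float = 600.0
    duration_s: float = 60.0
    blink_rate_hz: float = 1.0
    jitter_ms: float = 0.0
    shape: BlinkShape = field(default_factory=BlinkShape)
    shape_jitter_frac: float = 0.0
    eo_noise_rms_mm: float = 0.200
    ps_noise_rms_mm: float = 0.004
    pupil_diameter_mm: float = 4.0
    occlusion_threshold: Optional[float] = None
    extra_eo_loss_frac: float = 0.0
    extra_ps_loss_frac: float = 0.0
    loss_mean_run_ms: float = 50.0
    eyes: tuple = ("left", "right")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.blink_rate_hz < 0:
            raise ValueError("blink_rate_hz must be >= 0")
        for name in ("extra_eo_loss_frac", "extra_ps_loss_frac"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.shape_jitter_frac < 0.5:
            raise ValueError("shape_jitter_frac must lie in [0, 0.5)")

    @property
    def occlusion_level(self) -> float:
        return (self.pupil_diameter_mm if self.occlusion_threshold is None
                else self.occlusion_threshold)


@dataclass
class TrueBlink:
    """Ground-truth geometry of one simulated blink."""

    onset_t: float
    offset_t: float
    t_min_openness: float
    min_openness_mm: float
    closing_amp_mm: float
    opening_amp_mm: float

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


@dataclass
class GroundTruth:
    """Simulator-emitted true blink events, disjoint and time-ordered."""

    events: list = field(default_factory=list)
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if b.onset_t < a.offset_t:
                raise ValueError("ground-truth events must be disjoint and ordered")


def blink_waveform(shape: BlinkShape, fs: float) -> np.ndarray:
    """Sampled openness trace (mm) of one blink.

    Half-cosine descent from ``baseline_before`` over ``closing_ms``, flat
    plateau at ``min_openness``, half-cosine ascent to ``baseline_after``
    over ``opening_ms``.  The trace is C1 (phase velocities vanish at the
    joins) and its peak closing speed exceeds its peak opening speed whenever
    the closing phase is the shorter one of two comparable-amplitude phases
    (peak half-cosine slope = pi * amplitude / (2 * phase duration)).
    """
    n = max(2, int(round(shape.footprint_s * fs)) + 1)
    t = np.arange(n) / fs
    tc = shape.closing_ms / 1000.0
    tp = shape.plateau_ms / 1000.0
    to = shape.opening_ms / 1000.0
    amp_close = shape.baseline_before_mm - shape.min_openness_mm
    amp_open = shape.baseline_after_mm - shape.min_openness_mm
    out = np.empty(n)
    for i, ti in enumerate(t):
        if ti <= tc:
            out[i] = shape.min_openness_mm + amp_close * 0.5 * (1 + np.cos(np.pi * ti / tc))
        elif ti <= tc + tp:
            out[i] = shape.min_openness_mm
        elif ti <= tc + tp + to:
            phase = (ti - tc - tp) / to
            out[i] = shape.min_openness_mm + amp_open * 0.5 * (1 - np.cos(np.pi * phase))
        else:
            out[i] = shape.baseline_after_mm
    out[0] = shape.baseline_before_mm
    out[-1] = shape.baseline_after_mm
    return out


def _jittered_shape(shape: BlinkShape, frac: float, rng: np.random.Generator) -> BlinkShape:
    if frac == 0.0:
        return shape
    scale = lambda: 1.0 + frac * rng.uniform(-1.0, 1.0)
    return replace(
        shape,
        closing_ms=shape.closing_ms * scale(),
        opening_ms=shape.opening_ms * scale(),
        plateau_ms=shape.plateau_ms * scale(),
        min_openness_mm=max(0.0, shape.min_openness_mm * scale()),
    )


def simulate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate a binocular recording and its ground truth.

    Blinks are placed at ``1 / blink_rate_hz`` intervals (centered within
    each interval) with optional uniform timing jitter; both eyes share the
    noise-free trace and ground truth but receive independent noise and
    loss.  The same seed reproduces the output bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    n_blinks = int(np.floor(config.duration_s * config.blink_rate_hz)) if config.blink_rate_hz > 0 else 0
    period = 1.0 / config.blink_rate_hz if n_blinks else np.inf

    blinks = []  # (onset_t, shape, waveform)
    truth_events = []
    prev_end = 0.0
    for k in range(n_blinks):
        shape_k = _jittered_shape(config.shape, config.shape_jitter_frac, rng)
        if shape_k.footprint_s >= period:
            raise ValueError("blink footprint exceeds the inter-blink interval")
        center = (k + 0.5) * period
        onset = center - shape_k.footprint_s / 2.0
        if config.jitter_ms:
            onset += rng.uniform(-0.5, 0.5) * config.jitter_ms / 1000.0
        onset = min(max(onset, prev_end + 2.0 / config.fs),
                    config.duration_s - shape_k.footprint_s - 2.0 / config.fs)
        if onset < prev_end:
            raise ValueError("jittered blinks overlap; reduce jitter_ms or blink rate")
        wave = blink_waveform(shape_k, config.fs)
        blinks.append((onset, shape_k, wave))
        end = onset + (len(wave) - 1) / config.fs
        truth_events.append(TrueBlink(
            onset_t=onset,
            offset_t=end,
            t_min_openness=onset + (shape_k.closing_ms + 0.5 * shape_k.plateau_ms) / 1000.0,
            min_openness_mm=shape_k.min_openness_mm,
            closing_amp_mm=shape_k.baseline_before_mm - shape_k.min_openness_mm,
            opening_amp_mm=shape_k.baseline_after_mm - shape_k.min_openness_mm,
        ))
        prev_end = end

    # Baseline: flat at baseline_before, relaxing linearly back up from
    # baseline_after after each blink (slow drift, far below any velocity
    # threshold).
    anchors_t = [0.0]
    anchors_v = [config.shape.baseline_before_mm]
    for (onset, shape_k, wave), ev in zip(blinks, truth_events):
        anchors_t += [onset, ev.offset_t]
        anchors_v += [shape_k.baseline_before_mm, shape_k.baseline_after_mm]
    anchors_t.append(config.duration_s)
    anchors_v.append(config.shape.baseline_before_mm)
    eo_clean = np.interp(t, anchors_t, anchors_v)
    for onset, shape_k, wave in blinks:
        i0 = int(np.searchsorted(t, onset - 1e-12))
        i1 = min(i0 + len(wave), n)
        eo_clean[i0:i1] = np.interp(t[i0:i1] - onset,
                                    np.arange(len(wave)) / config.fs, wave)

    occluded = eo_clean < config.occlusion_level

    series = {}
    for eye in config.eyes:
        eo_noise = rng.normal(0.0, config.eo_noise_rms_mm / np.sqrt(2.0), n)
        eo = SampleSeries(t, eo_clean + eo_noise, np.ones(n, bool), config.fs, "eo", eye)
        if config.extra_eo_loss_frac > 0:
            eo = inject_data_loss(eo, config.extra_eo_loss_frac,
                                  config.loss_mean_run_ms,
                                  seed=int(rng.integers(2**31)))
        ps_noise = rng.normal(0.0, config.ps_noise_rms_mm / np.sqrt(2.0), n)
        ps_valid = ~occluded
        ps = SampleSeries(t, np.where(ps_valid, config.pupil_diameter_mm + ps_noise, np.nan),
                          ps_valid, config.fs, "ps", eye)
        if config.extra_ps_loss_frac > 0:
            ps = inject_data_loss(ps, config.extra_ps_loss_frac,
                                  config.loss_mean_run_ms,
                                  seed=int(rng.integers(2**31)))
        series[("eo", eye)] = eo
        series[("ps", eye)] = ps

    rec = Recording(series=series, meta={"simulated": True, "seed": config.seed})
    return rec, GroundTruth(events=truth_events, duration_s=config.duration_s)


def inject_data_loss(
    series: SampleSeries, frac: float, mean_run_ms: float = 50.0, seed: int = 0
) -> SampleSeries:
    """Invalidate random runs until the invalid fraction reaches ``frac``.

    Run lengths are geometric with mean ``mean_run_ms``; run starts are
    uniform.  Existing invalid samples are never revalidated, so loss is
    monotone non-decreasing; the final loss fraction lies within one run
    length above ``frac``.  Deterministic per seed.
    """
    if frac >= 1.0:
        raise ValueError("frac must be < 1")
    out = series.copy()
    if frac <= 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    mean_run = max(1.0, mean_run_ms * out.fs / 1000.0)
    p = 1.0 / mean_run
    invalid = ~out.valid
    target = frac * n
    while invalid.sum() < target:
        start = int(rng.integers(n))
        length = int(rng.geometric(p))
        invalid[start:start + length] = True
    out.valid = ~invalid
    out.value[invalid] = np.nan
    return out
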