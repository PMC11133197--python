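"""The eye-openness blink detector: peaks, expansion, kinematics, rules."""

import dataclasses

import numpy as np
import pytest

from blinkdet import (
    BlinkCandidate,
    BlinkEvent,
    BlinkShape,
    DetectionSettings,
    SimConfig,
    detect_eo_blinks,
    detect_eo_blinks_series,
    expand_candidate,
    extract_kinematics,
    find_closure_peaks,
    fully_open_level,
    interpolate_gaps,
    mad,
    merge_events,
    reject_candidates,
    sg_smooth,
    sg_velocity,
    simulate_recording,
)
from blinkdet.preprocess import VelocitySeries

from conftest import make_series

FS = 600.0


def synthetic_blink_series(shape=None, pad_s=0.5, fs=FS, noise=0.0, seed=0):
    """Baseline with one blink waveform in the middle, as a SampleSeries."""
    from blinkdet.simulate import blink_waveform

    shape = shape or BlinkShape()
    wave = blink_waveform(shape, fs)
    n_pad = int(pad_s * fs)
    vals = np.concatenate([
        np.full(n_pad, shape.baseline_before_mm),
        wave,
        np.full(n_pad, shape.baseline_after_mm),
    ])
    if noise:
        vals = vals + np.random.default_rng(seed).normal(0, noise, len(vals))
    return make_series(vals, fs=fs), n_pad, n_pad + len(wave) - 1


def scan_oracle(v, valid, start, step, t_vel, sustain=1):
    """Brute-force linear scan mirroring the onset/offset definition."""
    n = len(v)
    sign = step
    i = start
    run = 0
    while 0 <= i < n and valid[i]:
        if sign * v[i] >= t_vel:
            run += 1
            if run >= sustain:
                break
        else:
            run = 0
        i += step
    else:
        return start
    while 0 <= i < n and valid[i] and sign * v[i] >= t_vel:
        i += step
    if not 0 <= i < n:
        return 0 if step < 0 else n - 1
    if not valid[i]:
        return i - step
    return i


class TestFullyOpenLevel:
    def test_constant(self):
        assert fully_open_level(make_series([9.0] * 10)).level == 9.0

    def test_equifrequent_values(self):
        assert fully_open_level(make_series([8.0, 9.0, 10.0] * 4)).level == 9.0

    def test_robust_to_brief_blinks(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8.75, 0.15, 6000)
        vals[1000:1150] = 0.7  # a blink dip covering <10% of samples
        vals[4000:4150] = 0.7
        assert fully_open_level(make_series(vals)).level == pytest.approx(8.75, abs=0.05)

    def test_no_valid_samples_rejected(self):
        with pytest.raises(ValueError):
            fully_open_level(make_series([np.nan, np.nan]))


class TestFindClosurePeaks:
    def test_flat_series_has_no_peaks(self, settings):
        s = sg_smooth(make_series([9.0] * 200), 25)
        assert find_closure_peaks(s, settings, fully_open=9.0) == []

    def test_single_blink_found_at_minimum(self, settings):
        series, on, off = synthetic_blink_series()
        sm = sg_smooth(series, 25)
        peaks = find_closure_peaks(sm, settings, fully_open=8.75)
        assert len(peaks) == 1
        trough = peaks[0]
        assert sm.value[trough] == pytest.approx(np.nanmin(sm.value), abs=1e-9)
        assert on <= trough <= off

    def test_two_blinks_in_time_order(self, settings):
        from blinkdet.simulate import blink_waveform

        shape = BlinkShape()
        wave = blink_waveform(shape, FS)
        gap = np.full(int(0.5 * FS), shape.baseline_before_mm)
        vals = np.concatenate([gap, wave, gap, wave, gap])
        peaks = find_closure_peaks(sg_smooth(make_series(vals), 25), settings,
                                   fully_open=8.75)
        assert len(peaks) == 2
        assert peaks[0] < peaks[1]


class TestExpandCandidate:
    def test_matches_linear_scan_oracle(self):
        series, *_ = synthetic_blink_series()
        filled = interpolate_gaps(series, 40)
        vel = sg_velocity(filled, 25)
        t_vel = 5.0  # a plausible threshold for the noise-free trace
        trough = int(np.nanargmin(filled.value))
        for sustain in (1, 8):
            cand = expand_candidate(vel, trough, t_vel, sustain)
            assert cand.onset_idx == scan_oracle(vel.v, vel.valid, trough, -1, t_vel, sustain)
            assert cand.offset_idx == scan_oracle(vel.v, vel.valid, trough, +1, t_vel, sustain)
            assert cand.onset_idx <= trough <= cand.offset_idx

    def test_trough_at_series_start_is_clipped(self):
        v = VelocitySeries(np.arange(10) / FS, np.full(10, 20.0), np.ones(10, bool), FS)
        cand = expand_candidate(v, 0, t_vel=5.0)
        assert cand.onset_idx == 0
        assert cand.clipped

    def test_zero_velocity_degenerates_to_trough(self):
        v = VelocitySeries(np.arange(50) / FS, np.zeros(50), np.ones(50, bool), FS)
        cand = expand_candidate(v, 25, t_vel=5.0)
        assert cand.onset_idx == cand.offset_idx == 25

    def test_scan_stops_at_invalid_velocity(self):
        vv = np.concatenate([np.full(20, -20.0), np.zeros(20)])
        valid = np.ones(40, bool)
        valid[5] = False
        v = VelocitySeries(np.arange(40) / FS, vv, valid, FS)
        cand = expand_candidate(v, 25, t_vel=5.0)
        assert cand.clipped
        assert cand.onset_idx == 6  # last valid sample before the hole

    def test_nonpositive_threshold_rejected(self):
        v = VelocitySeries(np.arange(5) / FS, np.zeros(5), np.ones(5, bool), FS)
        with pytest.raises(ValueError):
            expand_candidate(v, 2, t_vel=0.0)


class TestExtractKinematics:
    def test_amplitude_arithmetic(self):
        series, on, off = synthetic_blink_series()
        filled = interpolate_gaps(series, 40)
        vel = sg_velocity(filled, 25)
        cand = BlinkCandidate(int(np.nanargmin(filled.value)), on, off, t_vel=5.0)
        ev = extract_kinematics(filled, vel, cand)
        assert ev.closing_amp == pytest.approx(ev.eo_onset - ev.eo_min)
        assert ev.opening_amp == pytest.approx(ev.eo_offset - ev.eo_min)
        assert ev.closing_amp == pytest.approx(8.75 - 0.73, abs=0.02)

    def test_symmetric_blink_has_equal_phase_peaks(self):
        shape = BlinkShape(closing_ms=100, opening_ms=100, plateau_ms=0,
                           baseline_after_mm=8.75)
        series, on, off = synthetic_blink_series(shape)
        filled = interpolate_gaps(series, 40)
        vel = sg_velocity(filled, 25)
        cand = BlinkCandidate(int(np.nanargmin(filled.value)), on, off, t_vel=5.0)
        ev = extract_kinematics(filled, vel, cand)
        assert ev.peak_closing_vel == pytest.approx(ev.peak_opening_vel, rel=1e-6)
        assert ev.t_peak_closing < ev.t_min_openness < ev.t_peak_opening

    def test_faster_closing_has_larger_peak_speed(self):
        shape = BlinkShape(closing_ms=63, opening_ms=138, baseline_after_mm=8.75)
        series, on, off = synthetic_blink_series(shape)
        filled = interpolate_gaps(series, 40)
        vel = sg_velocity(filled, 25)
        cand = BlinkCandidate(int(np.nanargmin(filled.value)), on, off, t_vel=5.0)
        ev = extract_kinematics(filled, vel, cand)
        assert ev.peak_closing_vel > ev.peak_opening_vel

    def test_invariants_on_detected_events(self, default_sim):
        rec, _ = default_sim
        for ev in detect_eo_blinks(rec, "left"):
            assert ev.onset_t <= ev.t_peak_closing <= ev.t_min_openness
            assert ev.t_min_openness <= ev.t_peak_opening <= ev.offset_t
            assert ev.eo_min <= min(ev.eo_onset, ev.eo_offset)
            assert ev.closing_amp >= 0 and ev.opening_amp >= 0


def _event(onset, offset, closing_amp=8.0, opening_amp=7.5,
           pcv=200.0, pov=90.0):
    mid = (onset + offset) / 2
    return BlinkEvent(
        onset_t=onset, offset_t=offset, t_min_openness=mid,
        eo_onset=8.75, eo_offset=8.2, eo_min=8.75 - closing_amp,
        closing_amp=closing_amp, opening_amp=opening_amp,
        peak_closing_vel=pcv, t_peak_closing=(onset + mid) / 2,
        peak_opening_vel=pov, t_peak_opening=(mid + offset) / 2,
    )


class TestRejectCandidates:
    MAD_V = 4.0

    def reject(self, ev, settings=None):
        settings = settings or DetectionSettings()
        return reject_candidates([ev], settings, fully_open=9.0, mad_v=self.MAD_V)

    def test_short_duration_rejected(self):
        assert self.reject(_event(1.0, 1.020)) == []  # 20 ms < 30 ms
        assert len(self.reject(_event(1.0, 1.040))) == 1

    def test_small_amplitude_rejected(self):
        ev = _event(1.0, 1.2, closing_amp=0.5, opening_amp=0.5)
        assert self.reject(ev) == []  # 0.5 < 0.1 * 9.0

    def test_low_peak_velocity_rejected(self):
        ev = _event(1.0, 1.2, pcv=5 * self.MAD_V, pov=1.5 * self.MAD_V)
        assert self.reject(ev) == []  # lower peak 1.5*MAD < 2*MAD
        ok = _event(1.0, 1.2, pcv=5 * self.MAD_V, pov=2.0 * self.MAD_V)
        assert len(self.reject(ok)) == 1

    def test_order_preserved(self):
        evs = [_event(1.0, 1.2), _event(2.0, 2.2)]
        assert reject_candidates(evs, DetectionSettings(), 9.0, self.MAD_V) == evs


class TestMergeEvents:
    def setup_method(self):
        vals = np.full(4000, 9.0)
        self.eo = make_series(vals)
        self.vel = sg_velocity(self.eo, 25)

    def merge(self, events, merge_ms=100):
        return merge_events(events, merge_ms, self.eo, self.vel)

    def test_close_pair_merges(self):
        out = self.merge([_event(1.0, 1.2), _event(1.25, 1.45)])  # 50 ms gap
        assert len(out) == 1
        assert out[0].onset_t == pytest.approx(1.0, abs=1e-3)
        assert out[0].offset_t == pytest.approx(1.45, abs=1e-3)

    def test_distant_pair_kept(self):
        out = self.merge([_event(1.0, 1.2), _event(1.35, 1.55)])  # 150 ms gap
        assert len(out) == 2

    def test_chain_merges_to_fixed_point(self):
        evs = [_event(1.0, 1.2), _event(1.28, 1.4), _event(1.49, 1.6)]  # 80, 90 ms
        out = self.merge(evs)
        assert len(out) == 1

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            self.merge([_event(1.0, 1.3), _event(1.2, 1.5)])

    def test_output_gaps_at_least_merge_interval(self, default_sim):
        rec, _ = default_sim
        events = detect_eo_blinks(rec, "left")
        gaps = [b.onset_t - a.offset_t for a, b in zip(events, events[1:])]
        assert all(g >= 0.100 for g in gaps)


class TestDetectPipeline:
    def test_noise_free_recovery(self):
        rec, truth = simulate_recording(SimConfig(seed=5, eo_noise_rms_mm=0.0,
                                                  eyes=("left",)))
        events = detect_eo_blinks(rec, "left")
        assert len(events) == len(truth.events) == 60

    def test_deterministic(self, default_sim):
        rec, _ = default_sim
        assert detect_eo_blinks(rec, "left") == detect_eo_blinks(rec, "left")

    def test_blink_free_noise_yields_no_events(self):
        rng = np.random.default_rng(11)
        vals = 8.75 + rng.normal(0, 0.2 / np.sqrt(2), 36000)
        assert detect_eo_blinks_series(make_series(vals)) == []

    def test_scale_covariance(self, default_sim):
        rec, _ = default_sim
        eo = rec.get("eo", "left")
        base = detect_eo_blinks_series(eo)
        scaled_series = make_series(eo.value * 3.7)
        scaled = detect_eo_blinks_series(scaled_series)
        assert [e.onset_t for e in base] == [e.onset_t for e in scaled]
        assert [e.offset_t for e in base] == [e.offset_t for e in scaled]

    def test_threshold_monotonicity(self, default_sim):
        rec, _ = default_sim
        eo = rec.get("eo", "left")
        base = DetectionSettings()
        n0 = len(detect_eo_blinks_series(eo, base))
        for change in ({"min_amplitude_frac": 0.3}, {"min_duration_ms": 80.0},
                       {"min_peak_vel_mad_factor": 3.0}):
            harder = dataclasses.replace(base, **change)
            assert len(detect_eo_blinks_series(eo, harder)) <= n0

    def test_gap_spanning_blink_trough_suppresses_detection(self):
        # data loss across the closure too long to repair: no peak, no blink
        series, on, off = synthetic_blink_series()
        vals = series.value.copy()
        trough = int(np.nanargmin(vals))
        vals[trough - 20:trough + 20] = np.nan  # 66 ms > 40 ms gap limit
        assert detect_eo_blinks_series(make_series(vals)) == []
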