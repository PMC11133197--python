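"""Detect blinks in a simulated eye-openness recording and summarize them.

Builds a 60 s, 600 Hz prompted-blink trial (one blink per second), runs the
eye-openness detector, and prints the recovered rate, durations, and
closing/opening kinematics.  Rate ~1 Hz and closing speeds well above
opening speeds indicate faithful recovery of the simulated eyelid motion.
"""

import numpy as np

from blinkdet import SimConfig, detect_eo_blinks, simulate_recording, summarize_events

rec, truth = simulate_recording(SimConfig(seed=1))
events = detect_eo_blinks(rec, eye="left")
summary = summarize_events(events, recording_duration_s=truth.duration_s)

print(f"true blinks:      {len(truth.events)}")
print(f"detected blinks:  {summary['n_events']}  (rate {summary['rate_hz']:.2f} Hz)")
print(f"mean duration:    {summary['duration_mean_s'] * 1000:.1f} ms")
print(f"mean closing amp: {summary['closing_amp_mean_mm']:.2f} mm")
print(f"peak closing vel: {summary['peak_closing_vel_mean_mm_s']:.0f} mm/s")
print(f"peak opening vel: {summary['peak_opening_vel_mean_mm_s']:.0f} mm/s")

first = events[0]
print(f"\nfirst blink: onset {first.onset_t:.3f} s, offset {first.offset_t:.3f} s, "
      f"min openness {first.eo_min:.2f} mm at {first.t_min_openness:.3f} s")
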