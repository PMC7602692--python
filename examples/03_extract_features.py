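"""Extract window features from one synthetic walking bout.

Simulates 60 s of flat walking, low-pass smooths it, cuts 20 s windows with
50% overlap, and prints a few features of the first window. On a noise-free
heel channel the peak count matches the cadence (one heel strike per gait
cycle per foot); with sensor noise the detector also counts many small
ripple peaks, which is why peak features are informative jointly with
magnitudes rather than as a literal step counter.
"""

from dataclasses import replace

from solewalk import (
    FULL_CONFIG,
    SubjectEffect,
    default_profiles,
    extract,
    segment_windows,
    simulate_recording,
)
from solewalk.features import detect_peaks

profile = default_profiles()["walking_flat"]
rec = simulate_recording(profile, SubjectEffect(seed=3), duration_s=60.0, seed=5)

clean = simulate_recording(replace(profile, noise_sd=0.0),
                           SubjectEffect(seed=3), duration_s=60.0, seed=5)
ps = detect_peaks(segment_windows(clean, 20)[0].channel("left", 1),
                  clean.sampling_rate)
print(f"noise-free heel channel: {ps.n} peaks in 20 s, mean interval "
      f"{ps.intervals.mean():.2f} s (gait cycle {profile.cadence_hz} Hz)")

windows = segment_windows(rec.smoothed(), 20)
print(f"{len(windows)} windows of 20 s (50% overlap) from the 60 s bout")
fv = extract(windows[0], FULL_CONFIG)
print(f"features per window: {len(fv.values)}")
for fid in (
    "general_statistics.max.L1",
    "peak_analysis.magnitude_mean.L1",
    "gait_phase.double_float_s",
    "frequency_domain.weighted_mean_freq",
    "pressure_distribution.ap_diff",
):
    print(f"  {fid:42s} {fv.values[fid]:8.3f}")
print("(no double float: walking keeps one foot on the ground; the negative "
      "anterior-posterior difference means the heel outweighs the forefoot "
      "on average)")
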