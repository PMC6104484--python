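"""Inside the pipeline: tilt estimation and wavelet denoising.

Simulates a single clean sit-to-stand, reconstructs the drift-corrected
tilt angle, and shows how the difference of Coiflet-5 approximation
reconstructions (3 vs 10 levels) isolates the transition bump.
"""

import numpy as np

from ptkit import PTSpec, SimulationConfig, simulate_session
from ptkit.posture import detect_stationary, tilt_series
from ptkit.preprocess import preprocess

cfg = SimulationConfig(
    seed=7,
    duration=30.0,
    pt_schedule=[PTSpec(12.0, "SiSt", tilt_peak=0.7, rise_height=0.25)],
    noise_accel=0.05,
    noise_gyro=0.01,
)
rec, truth = simulate_session(cfg)
pre = preprocess(rec)
mask = detect_stationary(pre)
tilt = tilt_series(pre, mask)

fs = rec.sample_rate
sl = slice(int(11 * fs), int(16 * fs))
est_peak = np.min(np.angle(np.exp(1j * tilt.theta[sl])))
true_peak = np.min(truth.theta[sl])
print(f"true peak flexion:      {np.degrees(true_peak):6.1f} deg")
print(f"estimated peak flexion: {np.degrees(est_peak):6.1f} deg")

dn = tilt.tilt_denoise
peak_idx = int(np.argmax(np.abs(dn)))
print(f"tilt_denoise extremum:  {dn[peak_idx]:+.3f} at t = {peak_idx / fs:.2f} s "
      "(mid-transition)")
rest = np.abs(dn[: int(10 * fs)]).max()
print(f"largest rest-period excursion: {rest:.4f} (far below the 0.1 threshold)")
print()
print("The denoised signal is near zero at rest and swings past 0.1 only")
print("during the transition, which is why its prominent peaks mark")
print("candidate events.")
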