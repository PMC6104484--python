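"""Detect postural transitions in a synthetic lower-back IMU session.

Builds the default 10-minute benchmark session (10 sit-to-stand,
10 stand-to-sit, 10 forward leans, sensor noise and gyro bias), runs
the full detection pipeline and prints every effective transition with
its timing and vertical displacement.
"""

from ptkit import default_benchmark, detect_full

rec, truth = default_benchmark(seed=1)
result = detect_full(rec)

print(f"session: {rec.n_samples / rec.sample_rate:.0f} s at {rec.sample_rate:.0f} Hz")
print(f"stage counts: {result.counts}")
print()
print("effective transitions (start-end [s], direction, vertical displacement):")
for ev in result.effective_events:
    print(
        f"  {ev.start_s:7.2f} - {ev.end_s:7.2f}  {ev.direction}"
        f"   dz = {ev.delta_dz:+.3f} m   duration = {ev.duration:.2f} s"
    )
print()
print(
    f"{len(result.effective_events)} effective transitions recovered; the "
    f"{result.counts['attempts']} attempts are forward leans and denoising "
    "ripple whose vertical displacement stayed below the 0.1 m threshold."
)
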