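"""Event-level validation of the detector against ground-truth annotations.

Runs simulate -> detect -> evaluate for one seed, prints the
contingency metrics and the duration agreement, then repeats with
dyskinesia-like continuous movement overlaid to show the degradation
the stationary-period logic suffers.
"""

from ptkit import detect_full, dyskinetic_benchmark, match_events, run_pipeline

result = run_pipeline(seed=1)
rep = result.report
print("clean benchmark session (20 true transitions):")
print(f"  TP={rep.tp}  FP={rep.fp}  FN={rep.fn}")
print(f"  sensitivity = {rep.sensitivity:.0f}%   PPV = {rep.ppv:.0f}%")
print(f"  direction accuracy = {rep.direction_accuracy:.0f}%")
print(f"  mean duration difference = {rep.mean_duration_diff:+.3f} s "
      f"(95% agreement {rep.diff_ci95[0]:+.3f} .. {rep.diff_ci95[1]:+.3f} s)")

rec, truth = dyskinetic_benchmark(seed=1)
dysk = match_events(detect_full(rec).effective_events, truth.annotation)
print()
print("same session overlaid with dyskinesia-like angular noise (60% coverage):")
print(f"  TP={dysk.tp}  FP={dysk.fp}  FN={dysk.fn}")
print(f"  sensitivity = {dysk.sensitivity:.0f}%   PPV = {dysk.ppv:.0f}%")
print()
print("Continuous movement hides the stationary periods that anchor the")
print("drift corrections: displacement estimates degrade, spurious effective")
print("events appear (PPV collapses) and, across seeds, true transitions are")
print("missed - the failure mode reported for dyskinetic patients.")
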