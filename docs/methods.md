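# Methods

`ptkit` detects, delimits and classifies postural transitions (PTs) —
sit-to-stand (SiSt) and stand-to-sit (StSi) movements — from a single
6DOF inertial measurement unit (3-axis accelerometer + 3-axis
gyroscope) worn on the lower back, sampled at 128 Hz. This note
describes the model, the numerical choices, what the synthetic
generator does and does not emulate, and the known limitations.

## Coordinate conventions

Canonical sensor axes: x vertical (cranial) when standing, y
medio-lateral, z anterior-posterior, right-handed. With this mounting a
forward flexion of the trunk is a *negative* rotation about the sensor
y axis. The earth frame is z-up; quaternions are scalar-first Hamilton
quaternions rotating sensor-frame vectors into the earth frame. The
initial attitude `q(0) = [1/sqrt(2), 0, -1/sqrt(2), 0]` maps sensor x
onto earth z (its predicted gravity direction in the sensor frame is
exactly `[1, 0, 0]`).

## Pipeline

1. **Preprocessing.** The accelerometer is low-pass filtered with a
   zero-phase (forward-backward) 4th-order Butterworth design, cut-off
   5 Hz, with one second of reflective padding; the effective magnitude
   response is the squared 4th-order response. The gyroscope is not
   filtered. Short-term statistics of the acceleration magnitude |a|
   and gyro magnitude |omega| use a trailing window of N = 128 samples
   (1 s); the variance is evaluated literally against the *per-lag*
   trailing mean,

       sigma^2(n) = (1/N) * sum_i (x(n-i) - mu(n-i))^2 ,

   not against a single window mean. The first N-1 samples use the
   available prefix and are flagged as warm-up. The gyroscope bias is a
   latch-and-hold estimate: whenever the short-term variance of |omega|
   drops below 1e-5 rad^2/s^2 the bias takes the instantaneous gyro
   sample, otherwise it holds; it is zero before the first latch.

2. **Stationary periods.** A sample is stationary (sp) when
   | |a| - g0 | < 0.05 m/s^2 AND sigma^2_a < 0.01 m^2/s^4 AND
   sigma^2_omega < 0.01 rad^2/s^2 (g0 = 9.81 m/s^2); warm-up samples
   are never sp; sp runs shorter than 0.25 s are dissolved. Interior
   active (ap) segments are bracketed by the last sp sample before
   (n_ls) and the first sp sample after (n_rs).

3. **Tilt.** On sp samples the tilt comes from gravity components:
   theta_sp = atan2(a_z, a_x), wrapped into [0, 2*pi). On ap segments
   the medio-lateral rate omega_y is integrated (forward rectangle
   rule, step 1/f_s) from theta_sp(n_ls), and the linear drift needed
   to land on theta_sp(n_rs) is removed, so the tilt matches both
   anchors. The anchor mismatch is taken modulo 2*pi: around upright
   rest the accelerometer tilt fluctuates across the 0/2*pi seam, and
   an unwrapped difference would masquerade as a full-turn drift.
   sin(theta) (bounded, seam-free) is then denoised.

4. **Wavelet denoising.** `tilt_denoise` is the difference between the
   approximation-only reconstructions after 3 and 10 Coiflet-5
   decomposition levels, R3[sin theta] - R10[sin theta]: a pass band of
   roughly 0.06-8 Hz at 128 Hz that preserves 2-second transition bumps
   while cancelling both measurement noise and slow baseline. The
   signal is padded by symmetric reflection to the next multiple of
   2^10 before decomposition (half of the padding on each side) and
   cropped afterwards, so a 10-level transform is defined for any
   session length.

5. **Detection and delimitation.** Candidate events are local peaks of
   `tilt_denoise` *of either polarity* with absolute height and
   topographic prominence above 0.1 (sensor mounting flips the sign of
   the sagittal bump; direction is never inferred from peak sign).
   Candidates closer than 1 s merge, keeping the larger magnitude.
   Event start/end are the nearest zero crossings of omega_y with
   negative slope (omega(k) >= 0 > omega(k+1), boundary at k) on each
   side of the peak, searched up to 5 s; if none exists the bracketing
   sp boundary is used and the event flagged. Events whose delimited
   spans overlap collapse to the strongest peak: denoising ripple can
   place a side lobe just outside the merge window but inside the same
   pair of zero crossings, and two events with one delimitation are one
   movement.

6. **Fusion and vertical displacement.** A feedback filter integrates
   q_dot = 0.5 q (x) [0, omega_est] with
   omega_est = omega_tilde + beta * (a_hat x g_est), beta = 0.5 on sp
   and 0 on ap: at rest the attitude is steered onto the measured
   gravity direction, during movement the gyro runs open-loop.
   Acceleration (normalized by g0) is rotated into the earth frame, the
   unit gravity vector [0, 0, 1] subtracted, and the remainder rescaled
   to m/s^2. Per bracketed ap segment the translational velocity is
   integrated from zero and the linear drift removed so it returns to
   zero at n_rs (a zero-velocity update at both anchors); the vertical
   velocity integrates to the displacement d_z, frozen during sp.
   Samples before the first sp carry no attitude or kinematics.

7. **Classification.** Delta d_z = d_z(end) - d_z(start) across the
   event boundaries. |Delta d_z| >= 0.1 m makes the event an
   *effective* PT (SiSt if positive, StSi if negative); smaller
   displacements are *attempts* (e.g. forward leans) and are excluded
   from final counts but kept, marked, for inspection.

8. **Evaluation.** Effective events match reference annotations
   one-to-one, greedily by ascending midpoint distance, within a
   tolerance of 2 s — the video-style reference is timed in full
   seconds and transitions last about 2 s, so sub-second matching would
   be spurious precision. Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP),
   accuracy = TP/(TP+FP+FN), direction accuracy over matched pairs.
   Duration agreement follows the limits-of-agreement convention:
   mean paired difference +/- 1.96 SD. A Welch two-sample t-test is
   available for group duration comparisons.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| cutoff_hz / order | 5 / 4 | Hz | accelerometer low-pass |
| window | 128 | samples | short-term statistics (1 s) |
| bias_var_threshold | 1e-5 | rad^2/s^2 | gyro bias latch |
| accel_dev_thresh | 0.05 | m/s^2 | sp: | |a| - g0 | bound |
| accel_var_thresh | 0.01 | m^2/s^4 | sp: accel variance bound |
| gyro_var_thresh | 0.01 | rad^2/s^2 | sp: gyro variance bound |
| min_sp_duration_s | 0.25 | s | suppress sp flickers |
| wavelet, j_lo, j_hi | coif5, 3, 10 | — | denoising band |
| height, prominence | 0.1, 0.1 | — | peak acceptance |
| merge_window_s | 1.0 | s | candidate merging |
| dz_threshold | 0.1 | m | effective vs attempt |
| max_search_s | 5.0 | s | boundary search cap |
| beta_sp / beta_ap | 0.5 / 0.0 | — | gravity feedback gain |
| tolerance_s | 2.0 | s | event matching |

All are exposed in one TOML file (`[preprocess]`, `[posture]`,
`[fusion]`, `[detect]`, `[evaluate]`, `[simulate]` sections); unknown
keys are rejected.

## Synthetic sessions

The generator models the trunk as a single rigid segment rotating about
the medio-lateral axis. A transition is a flexion-extension tilt bump
`theta_peak * sin^2(pi (t-t0)/T)` (default 0.7 rad, T = 2 s) plus a C^2
monotone vertical step (smootherstep) of +/-0.25 m; a forward lean is
the same bump with zero rise. The accelerometer measures
`(g + z_dd) * u` with u the world-up direction in the sensor frame (no
fictitious forces: the norm equals |g + z_dd| in noise-free runs); the
gyroscope measures the analytic tilt rate plus a constant bias
(default (0.01, 0.02, -0.01) rad/s) and white noise (0.01 rad/s per
axis; accelerometer noise 0.05 m/s^2 per axis). The default benchmark
is a 10-minute session of 10 SiSt + 10 StSi (alternating, so the
height track stays physical) with 10 interleaved leans. The dyskinetic
variant overlays band-limited (0.5-3 Hz) angular noise, 0.5 rad/s RMS,
tiled over 60% of the session and overlapping the transitions —
emulating continuous involuntary movement.

What the generator does **not** emulate: multi-segment kinematics,
anterior-posterior translation during transitions, gait, turning,
postural sway during rest, sensor re-mounting, or magnetometer data.
Passing the synthetic recovery checks therefore demonstrates internal
consistency of the pipeline under controlled, single-axis kinematics
with known ground truth — not free-living performance, which in the
validation study this algorithm design comes from was markedly lower
(and lower again under dyskinesia, a degradation the dyskinetic
benchmark reproduces directionally).

## Numerical choices and degenerate inputs

- Integration is the forward rectangle rule at 1/f_s throughout
  (tilt, quaternion, velocity, displacement), matching the discrete
  recursions of the method; no trapezoid upgrade.
- The quaternion is renormalized after every step; for single-axis
  constant-rate input the accumulated angle error is below 0.001% over
  10 s at 1 rad/s (measured by the acceptance script).
- Zero-crossing tie-break: a crossing is omega(k) >= 0 > omega(k+1)
  with the boundary at k, which resolves exact-zero runs to the run's
  last sample deterministically.
- Peak merging processes candidates strongest-first; ties break toward
  the earlier sample. Events with duration above 10 s are flagged
  (`long_duration`), not dropped.
- NaN runs shorter than 0.25 s in input files are linearly interpolated
  with a logged warning; longer runs are rejected.
- Recordings with no stationary period are flagged
  (`no stationary anchor`): detection still runs, but no kinematics and
  hence no effective/attempt split is available (all events are
  flagged attempts).
- Leading/trailing ap segments with one missing anchor are integrated
  from the available anchor without drift correction and flagged
  `uncorrected`.

## Known limitations

- **Constant-rate rotation looks stationary.** The stationarity rule
  thresholds the *magnitudes* and their short-term variances; a pure
  rotation at constant rate keeps |a| = g0 and both variances near
  zero and is labeled sp. Real movement is never that steady, but the
  property is intrinsic to the rule.
- **The bias latch is causal and can mislatch.** During the warm-up
  prefix the variance is computed over few samples and is near zero, so
  the bias latches onto the first quiet second of a recording (one
  noisy sample per axis). In noise-free data the trailing window also
  lets the latch fire a few samples into a movement onset, corrupting
  the bias by up to ~0.04 rad/s. With realistic sensor noise the
  rest-period magnitude variance (~1e-4 rad^2/s^2) exceeds the 1e-5
  threshold and only the warm-up latch fires. Sessions should begin
  with the wearer at rest.
- **Return-to-stationary lags by up to 2 s.** The per-lag-mean variance
  gives the statistics a two-window memory, so ap segments extend past
  the true end of movement; boundaries and displacement are anchored at
  the (correct) zero-velocity instants, but segment edges are not
  sharp.
- **Time-reversal antisymmetry holds for the kinematic chain, not the
  full causal pipeline.** Strapdown integration plus linear drift
  removal is antisymmetric under time reversal to within integration
  error; the trailing-window bias latch is not, and its error changes
  sign relative to the displacement under reversal.
- Reported accuracy uses TP/(TP+FP+FN); published group tables computed
  with an unstated denominator may differ by a few points.
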