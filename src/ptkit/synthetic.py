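"""Synthetic lower-back IMU sessions with exact ground truth.

The trunk is modeled as a single rigid segment rotating about the
medio-lateral (y) axis.  A postural transition is a flexion-extension
tilt bump together with a smooth monotone vertical displacement of the
center of mass (up for sit-to-stand, down for stand-to-sit); a forward
lean is the same tilt bump with zero displacement.  With the canonical
mounting (sensor x vertical-cranial, z anterior), forward flexion is a
*negative* rotation about the sensor's y axis, so the latent tilt angle
``theta`` (sensor convention) is the negative of the physical forward
flexion angle.

The accelerometer measures the specific force ``(g + z_dd) * u`` where
``u = (cos(theta), 0, sin(theta))`` is the world-up direction in the
sensor frame — no fictitious forces are introduced, so the accelerometer
norm equals |gravity + vertical acceleration| in noise-free runs.  The
gyroscope measures ``(0, d(theta)/dt, 0)`` plus a constant bias and white
noise.

Confounders
-----------
lean        tilt bump, zero rise (a "PT attempt").
dyskinesia  band-limited (0.5-3 Hz) angular velocity on all three gyro
            axes for its duration, emulating continuous involuntary
            movement; it may overlap scheduled episodes.
fidget      a short burst of white accelerometer noise (std = amplitude,
            m/s^2) and gyroscope noise (std = amplitude / 5, rad/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io import AnnotationSet, ImuRecording, PTAnnotation
from .posture import G0

DEFAULT_SAMPLE_RATE = 128.0
EDGE_MARGIN_S = 5.0


@dataclass(frozen=True)
class PTSpec:
    """One scheduled transition: flexion-extension bump + vertical step."""

    time: float                 # episode start, s
    direction: str              # "SiSt" or "StSi"
    tilt_peak: float = 0.7      # rad, peak forward flexion
    rise_height: float = 0.25   # m, magnitude of the vertical step
    duration: float = 2.0       # s


@dataclass(frozen=True)
class Confounder:
    time: float
    kind: str                   # "lean", "dyskinesia" or "fidget"
    amplitude: float
    duration: float


@dataclass
class SimulationConfig:
    seed: int = 0
    duration: float = 600.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pt_schedule: list[PTSpec] = field(default_factory=list)
    confounders: list[Confounder] = field(default_factory=list)
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_accel: float = 0.0    # m/s^2, white, per axis
    noise_gyro: float = 0.0     # rad/s, white, per axis

    def episodes(self) -> list[tuple[float, float]]:
        """(start, end) of every scheduled tilt episode (PTs, leans, fidgets)."""
        spans = [(p.time, p.time + p.duration) for p in self.pt_schedule]
        spans += [
            (c.time, c.time + c.duration)
            for c in self.confounders
            if c.kind != "dyskinesia"
        ]
        return sorted(spans)

    def validate(self) -> None:
        for p in self.pt_schedule:
            if p.direction not in ("SiSt", "StSi"):
                raise ValidationError(f"bad direction {p.direction!r}")
        spans = self.episodes()
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValidationError(f"overlapping episodes at {s0}/{s1} s")
        all_spans = spans + [
            (c.time, c.time + c.duration) for c in self.confounders
        ]
        for s, e in all_spans:
            if s < EDGE_MARGIN_S or e > self.duration - EDGE_MARGIN_S:
                raise ValidationError(
                    f"episode ({s}, {e}) violates the {EDGE_MARGIN_S} s margin"
                )


@dataclass
class GroundTruth:
    """Reference annotations and the latent kinematic trajectories."""

    annotation: AnnotationSet
    theta: np.ndarray       # rad, latent sensor-convention tilt (flexion negative)
    theta_rate: np.ndarray  # rad/s, analytic d(theta)/dt
    d_z: np.ndarray         # m, latent vertical displacement
    v_z: np.ndarray         # m/s, latent vertical velocity
    a_z: np.ndarray         # m/s^2, latent vertical acceleration


def _bump(t: np.ndarray, t0: float, T: float, amp: float) -> tuple[np.ndarray, np.ndarray]:
    """sin^2 flexion bump and its analytic time derivative on the grid."""
    tau = (t - t0) / T
    inside = (tau >= 0) & (tau <= 1)
    ang = np.where(inside, amp * np.sin(np.pi * tau) ** 2, 0.0)
    vel = np.where(inside, amp * (np.pi / T) * np.sin(2 * np.pi * tau), 0.0)
    return ang, vel


def _smootherstep(t: np.ndarray, t0: float, T: float, h: float):
    """C^2 monotone step of height h and its first/second derivatives."""
    tau = np.clip((t - t0) / T, 0.0, 1.0)
    s = 6 * tau**5 - 15 * tau**4 + 10 * tau**3
    ds = (30 * tau**4 - 60 * tau**3 + 30 * tau**2) / T
    d2s = (120 * tau**3 - 180 * tau**2 + 60 * tau) / T**2
    return h * s, h * ds, h * d2s


def simulate_session(config: SimulationConfig) -> tuple[ImuRecording, GroundTruth]:
    """Generate a session and its exact ground truth, reproducibly from the seed."""
    config.validate()
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)

    flexion = np.zeros(n)       # physical forward flexion angle, rad
    flexion_rate = np.zeros(n)
    z = np.zeros(n)
    vz = np.zeros(n)
    az = np.zeros(n)
    events = []

    for p in config.pt_schedule:
        ang, vel = _bump(t, p.time, p.duration, p.tilt_peak)
        flexion += ang
        flexion_rate += vel
        h = p.rise_height if p.direction == "SiSt" else -p.rise_height
        s, ds, d2s = _smootherstep(t, p.time, p.duration, h)
        z += s
        vz += ds
        az += d2s
        events.append(PTAnnotation(p.time, p.time + p.duration, p.direction))

    gyro_extra = np.zeros((n, 3))
    accel_extra = np.zeros((n, 3))
    for c in config.confounders:
        i0 = int(round(c.time * fs))
        i1 = min(int(round((c.time + c.duration) * fs)), n)
        if c.kind == "lean":
            ang, vel = _bump(t, c.time, c.duration, c.amplitude)
            flexion += ang
            flexion_rate += vel
        elif c.kind == "dyskinesia":
            white = rng.standard_normal((i1 - i0, 3))
            b, a = sps.butter(2, [0.5 / (fs / 2), 3.0 / (fs / 2)], btype="band")
            band = sps.lfilter(b, a, white, axis=0)
            rms = np.sqrt(np.mean(band**2))
            if rms > 0:
                band *= c.amplitude / rms
            gyro_extra[i0:i1] += band
        elif c.kind == "fidget":
            accel_extra[i0:i1] += c.amplitude * rng.standard_normal((i1 - i0, 3))
            gyro_extra[i0:i1] += (c.amplitude / 5.0) * rng.standard_normal(
                (i1 - i0, 3)
            )
        else:
            raise ValidationError(f"unknown confounder kind {c.kind!r}")

    # Sensor convention: forward flexion is a negative rotation about y.
    theta = -flexion
    theta_rate = -flexion_rate
    up = np.column_stack([np.cos(theta), np.zeros(n), np.sin(theta)])
    accel = (G0 + az)[:, None] * up
    gyro = np.column_stack([np.zeros(n), theta_rate, np.zeros(n)])

    accel = accel + accel_extra
    gyro = gyro + gyro_extra + np.asarray(config.gyro_bias, dtype=float)
    if config.noise_accel > 0:
        accel = accel + config.noise_accel * rng.standard_normal((n, 3))
    if config.noise_gyro > 0:
        gyro = gyro + config.noise_gyro * rng.standard_normal((n, 3))

    rec = ImuRecording(
        fs, t, accel, gyro, meta={"synthetic": True, "seed": config.seed}
    )
    truth = GroundTruth(
        annotation=AnnotationSet(events, resolution=1.0 / fs),
        theta=theta,
        theta_rate=theta_rate,
        d_z=z,
        v_z=vz,
        a_z=az,
    )
    return rec, truth


def benchmark_config(
    seed: int,
    duration: float = 600.0,
    n_triplets: int = 10,
    tilt_peak: float = 0.7,
    rise_height: float = 0.25,
    episode_duration: float = 2.0,
    gyro_bias: tuple[float, float, float] = (0.01, 0.02, -0.01),
    noise_accel: float = 0.05,
    noise_gyro: float = 0.01,
) -> SimulationConfig:
    """The default 10-minute study session: 10 SiSt + 10 StSi + 10 leans.

    Transitions alternate SiSt/StSi (so the latent height track stays
    physical) with a forward lean between each pair.
    """
    n_items = 3 * n_triplets
    usable = duration - 2 * EDGE_MARGIN_S - episode_duration
    spacing = usable / max(n_items - 1, 1)
    schedule: list[PTSpec] = []
    confounders: list[Confounder] = []
    for k in range(n_items):
        t0 = EDGE_MARGIN_S + k * spacing
        which = k % 3
        if which == 0:
            schedule.append(
                PTSpec(t0, "SiSt", tilt_peak, rise_height, episode_duration)
            )
        elif which == 1:
            confounders.append(
                Confounder(t0, "lean", tilt_peak, episode_duration)
            )
        else:
            schedule.append(
                PTSpec(t0, "StSi", tilt_peak, rise_height, episode_duration)
            )
    return SimulationConfig(
        seed=seed,
        duration=duration,
        pt_schedule=schedule,
        confounders=confounders,
        gyro_bias=gyro_bias,
        noise_accel=noise_accel,
        noise_gyro=noise_gyro,
    )


def default_benchmark(seed: int) -> tuple[ImuRecording, GroundTruth]:
    """Simulate the default benchmark session for a seed."""
    return simulate_session(benchmark_config(seed))


def dyskinetic_benchmark(
    seed: int, amplitude: float = 0.5, coverage: float = 0.6
) -> tuple[ImuRecording, GroundTruth]:
    """The default benchmark overlaid with dyskinesia-like angular noise.

    Dyskinesia bursts are tiled over the session until they cover
    ``coverage`` of its duration; they overlap transitions, emulating a
    continuously moving patient.
    """
    cfg = benchmark_config(seed)
    burst = 30.0
    n_bursts = int(math.ceil(coverage * cfg.duration / burst))
    step = (cfg.duration - 2 * EDGE_MARGIN_S - burst) / max(n_bursts - 1, 1)
    dysk = [
        Confounder(EDGE_MARGIN_S + k * step, "dyskinesia", amplitude, burst)
        for k in range(n_bursts)
    ]
    cfg.confounders = cfg.confounders + dysk
    return simulate_session(cfg)
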