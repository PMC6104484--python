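"""6DOF orientation fusion and drift-corrected vertical displacement.

Orientation is tracked as a scalar-first unit quaternion (Hamilton
convention, right-handed, earth frame z-up).  The gyroscope drives the
quaternion forward; during stationary periods the accelerometer's
gravity direction is fed back through the cross product
``delta_omega = a_hat x g_est`` with gain beta (0.5 on sp, 0 on ap),
locking the attitude to gravity whenever the sensor is at rest.

The fused attitude rotates the (gravity-normalized) acceleration into
the earth frame; subtracting the unit gravity vector [0, 0, 1] leaves
the translational acceleration, which is integrated per active segment
to a velocity (forced to zero at both stationary anchors by linear
drift removal) and then to the vertical displacement d_z.  d_z is
frozen during stationary periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError
from .posture import ActivityMask, G0
from .preprocess import PreprocessedStreams

#: Initial orientation once the first stationary period is found: maps the
#: sensor's vertical (x) axis onto the earth's z axis.
Q0 = (1.0 / math.sqrt(2.0), 0.0, -1.0 / math.sqrt(2.0), 0.0)

DEFAULT_BETA_SP = 0.5
DEFAULT_BETA_AP = 0.0


@dataclass
class QuaternionSeries:
    """Per-sample attitude and the fusion filter's internal signals."""

    q: np.ndarray           # (n, 4) unit quaternions, scalar first
    q_dot: np.ndarray       # (n, 4) quaternion rates
    g_est: np.ndarray       # (n, 3) estimated gravity direction, sensor frame
    omega_est: np.ndarray   # (n, 3) feedback-corrected angular velocity, rad/s
    omega_fb: np.ndarray    # (n, 3) feedback fixation a_hat x g_est, rad/s
    beta: np.ndarray        # (n,) feedback gain actually applied
    valid_from: int         # first sample with a defined attitude
    flags: set = field(default_factory=set)


@dataclass
class KinematicsSeries:
    """Earth-frame acceleration, velocity and vertical displacement."""

    a_earth: np.ndarray     # (n, 3), m/s^2
    a_t: np.ndarray         # translational acceleration, (n, 3), m/s^2
    v_t: np.ndarray         # drift-corrected translational velocity, (n, 3), m/s
    d_z: np.ndarray         # vertical displacement, (n,), m
    valid_from: int
    flags: set = field(default_factory=set)


def gravity_from_quaternion(q: np.ndarray) -> np.ndarray:
    """Sensor-frame gravity direction predicted by a (batch of) quaternion(s).

    ``g_est = [2(q2 q4 - q1 q3), 2(q1 q2 + q3 q4), q1^2 - q2^2 - q3^2 + q4^2]``
    """
    q = np.asarray(q, dtype=float)
    q1, q2, q3, q4 = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            2.0 * (q2 * q4 - q1 * q3),
            2.0 * (q1 * q2 + q3 * q4),
            q1 * q1 - q2 * q2 - q3 * q3 + q4 * q4,
        ],
        axis=-1,
    )


def quat_multiply(p, q):
    """Hamilton product of scalar-first quaternions (broadcasting)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    qw, qx, qy, qz = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def fuse_orientation(
    pre: PreprocessedStreams,
    mask: ActivityMask,
    beta_sp: float = DEFAULT_BETA_SP,
    beta_ap: float = DEFAULT_BETA_AP,
    q0: tuple[float, float, float, float] = Q0,
) -> QuaternionSeries:
    """Run the feedback filter from the first stationary sample onward.

    Samples before the first sp carry no attitude (the quaternion is held
    at ``q0`` there but flagged invalid via ``valid_from``).
    """
    n = pre.n_samples
    n0 = mask.first_sp_index
    flags: set = set()
    if n0 is None:
        n0 = 0
        flags.add("no stationary anchor")

    dt = 1.0 / pre.sample_rate
    acc = pre.accel
    gyro = pre.gyro_unbiased
    sp = mask.stationary

    q_arr = np.empty((n, 4))
    qd_arr = np.zeros((n, 4))
    fb_arr = np.zeros((n, 3))
    oe_arr = np.zeros((n, 3))
    beta_arr = np.zeros(n)
    q_arr[: n0 + 1] = q0

    # Scalar state for speed; ~1e5 iterations per session.
    qw, qx, qy, qz = q0
    for i in range(n0, n):
        q_arr[i] = (qw, qx, qy, qz)
        ax, ay, az = acc[i]
        na = math.sqrt(ax * ax + ay * ay + az * az)
        if na == 0.0:
            raise IntegrityError(f"zero acceleration magnitude at sample {i}")
        ax, ay, az = ax / na, ay / na, az / na
        gx = 2.0 * (qx * qz - qw * qy)
        gy = 2.0 * (qw * qx + qy * qz)
        gz = qw * qw - qx * qx - qy * qy + qz * qz
        fx = ay * gz - az * gy
        fy = az * gx - ax * gz
        fz = ax * gy - ay * gx
        beta = beta_sp if sp[i] else beta_ap
        wx = gyro[i, 0] + beta * fx
        wy = gyro[i, 1] + beta * fy
        wz = gyro[i, 2] + beta * fz
        # q_dot = 0.5 * q (x) [0, omega_est]
        dw = 0.5 * (-qx * wx - qy * wy - qz * wz)
        dx = 0.5 * (qw * wx + qy * wz - qz * wy)
        dy = 0.5 * (qw * wy - qx * wz + qz * wx)
        dz = 0.5 * (qw * wz + qx * wy - qy * wx)
        fb_arr[i] = (fx, fy, fz)
        oe_arr[i] = (wx, wy, wz)
        beta_arr[i] = beta
        qd_arr[i] = (dw, dx, dy, dz)
        if i + 1 < n:
            qw += dw * dt
            qx += dx * dt
            qy += dy * dt
            qz += dz * dt
            nq = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw, qx, qy, qz = qw / nq, qx / nq, qy / nq, qz / nq

    g_est = gravity_from_quaternion(q_arr)
    return QuaternionSeries(
        q=q_arr,
        q_dot=qd_arr,
        g_est=g_est,
        omega_est=oe_arr,
        omega_fb=fb_arr,
        beta=beta_arr,
        valid_from=n0 if "no stationary anchor" not in flags else n,
        flags=flags,
    )


def rotate_by_quaternion(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors from the sensor frame to the earth frame: q (x) [0,v] (x) q*."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # q [0,v] q* expanded: v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def to_earth_frame(
    accel: np.ndarray, qs: QuaternionSeries, g0: float = G0
) -> tuple[np.ndarray, np.ndarray]:
    """Earth-frame acceleration and the translational (gravity-free) part.

    The acceleration is normalized by g0, rotated by the attitude
    quaternion, reduced by the unit gravity vector [0, 0, 1], and scaled
    back to m/s^2.  Samples before ``valid_from`` are NaN.
    """
    a_g = np.asarray(accel, dtype=float) / g0
    a_earth = rotate_by_quaternion(qs.q, a_g)
    a_t = (a_earth - np.array([0.0, 0.0, 1.0])) * g0
    a_earth = a_earth * g0
    if qs.valid_from > 0:
        a_earth[: qs.valid_from] = np.nan
        a_t[: qs.valid_from] = np.nan
    return a_earth, a_t


def vertical_displacement(
    a_t: np.ndarray,
    mask: ActivityMask,
    sample_rate: float,
    valid_from: int = 0,
) -> KinematicsSeries:
    """Integrate translational acceleration to a drift-free vertical track.

    Per bracketed active segment the velocity (rectangle rule, seeded at
    zero) has the linear drift removed that is needed to return to zero
    at the right anchor; d_z integrates the vertical velocity and is
    frozen during stationary periods.  Unbracketed segments are
    integrated without drift removal and flagged.
    """
    n = a_t.shape[0]
    dt = 1.0 / sample_rate
    v_t = np.zeros((n, 3))
    d_z = np.zeros(n)
    flags: set = set()
    if valid_from > 0:
        d_z[:valid_from] = np.nan

    for seg in mask.ap_segments:
        if seg.last < valid_from:
            continue
        n_ls, n_rs = seg.n_ls, seg.n_rs
        if n_ls is None or n_ls < valid_from:
            flags.add("uncorrected")
            continue
        stop = n_rs if n_rs is not None else seg.last
        # v(n+1) = v(n) + a_T(n) dt over [n_ls, stop]
        seg_a = a_t[n_ls:stop]
        v = np.vstack([np.zeros(3), np.cumsum(seg_a, axis=0) * dt])
        if n_rs is not None:
            k_v = v[-1] / (n_rs - n_ls)
            v = v - np.outer(np.arange(n_rs - n_ls + 1), k_v)
        else:
            flags.add("uncorrected")
        v_t[n_ls : stop + 1] = v
        # d_z(n+1) = d_z(n) + v_z(n) dt, continuing from the segment start.
        dz_seg = d_z[n_ls] + np.concatenate(
            ([0.0], np.cumsum(v[:-1, 2]) * dt)
        )
        d_z[n_ls : stop + 1] = dz_seg
        # Freeze d_z through the following sp (and anything after, until
        # the next segment overwrites it).
        d_z[stop + 1 :] = dz_seg[-1]

    return KinematicsSeries(
        a_earth=np.full_like(a_t, np.nan),
        a_t=a_t,
        v_t=v_t,
        d_z=d_z,
        valid_from=valid_from,
        flags=flags,
    )


def kinematics(
    pre: PreprocessedStreams,
    mask: ActivityMask,
    qs: QuaternionSeries,
    g0: float = G0,
) -> KinematicsSeries:
    """Earth-frame conversion followed by displacement integration."""
    a_earth, a_t = to_earth_frame(pre.accel, qs, g0)
    ks = vertical_displacement(a_t, mask, pre.sample_rate, qs.valid_from)
    ks.a_earth = a_earth
    return ks
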