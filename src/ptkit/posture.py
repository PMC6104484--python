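"""Stationary/active labeling, sagittal tilt estimation and DWT denoising.

A sample is *stationary* (sp) when the low-passed acceleration magnitude
sits within ``accel_dev_thresh`` of standard gravity AND both short-term
variances (acceleration magnitude, gyro magnitude) are below their
thresholds; otherwise it is *active* (ap).  Stationary anchors bracket
every interior active segment and seed two drift corrections: the tilt
angle (here) and the translational velocity (fusion module).

Tilt during sp comes straight from the gravity components measured by
the accelerometer; tilt during ap integrates the bias-removed
medio-lateral angular velocity and removes the linear drift needed to
land on the accelerometer anchor at the far end.

``sin(theta)`` is denoised by keeping only the approximation branch of a
Coiflet-5 discrete wavelet decomposition: the difference between the
3-level and 10-level approximation reconstructions isolates the 0.06-8 Hz
band in which postural transitions live while cancelling both noise and
slow baseline drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import ParameterError
from .preprocess import PreprocessedStreams

G0 = 9.81  # standard gravity, m/s^2

DEFAULT_ACCEL_DEV_THRESH = 0.05   # m/s^2, | |a| - g0 |
DEFAULT_ACCEL_VAR_THRESH = 0.01   # m^2/s^4
DEFAULT_GYRO_VAR_THRESH = 0.01    # rad^2/s^2
MIN_SP_DURATION_S = 0.25          # shorter sp runs are merged into ap
DEFAULT_WAVELET = "coif5"
DEFAULT_J_LO = 3
DEFAULT_J_HI = 10


@dataclass(frozen=True)
class Segment:
    """One maximal run of identically labeled samples (inclusive indices)."""

    kind: str          # "sp" or "ap"
    first: int
    last: int
    n_ls: int | None = None  # last sample of the preceding sp (ap only)
    n_rs: int | None = None  # first sample of the following sp (ap only)

    @property
    def length(self) -> int:
        return self.last - self.first + 1


@dataclass
class ActivityMask:
    """Per-sample sp/ap labeling plus the segment structure."""

    stationary: np.ndarray          # bool per sample, True = sp
    segments: list[Segment]
    flags: set = field(default_factory=set)

    @property
    def ap_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "ap"]

    @property
    def sp_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "sp"]

    @property
    def first_sp_index(self) -> int | None:
        for s in self.segments:
            if s.kind == "sp":
                return s.first
        return None


@dataclass
class TiltSeries:
    """Tilt angle and its wavelet reconstructions."""

    theta: np.ndarray          # rad, theta_sp on sp samples, theta_ap on ap
    sin_theta: np.ndarray
    r3: np.ndarray             # approximation-only reconstruction, j_lo levels
    r10: np.ndarray            # approximation-only reconstruction, j_hi levels
    tilt_denoise: np.ndarray   # r3 - r10
    flags: set = field(default_factory=set)


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean array as (first, last, value)."""
    n = labels.shape[0]
    out = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            out.append((start, i - 1, bool(labels[start])))
            start = i
    return out


def detect_stationary(
    pre: PreprocessedStreams,
    accel_dev_thresh: float = DEFAULT_ACCEL_DEV_THRESH,
    accel_var_thresh: float = DEFAULT_ACCEL_VAR_THRESH,
    gyro_var_thresh: float = DEFAULT_GYRO_VAR_THRESH,
    g0: float = G0,
    min_sp_duration_s: float = MIN_SP_DURATION_S,
) -> ActivityMask:
    """Label each sample stationary (sp) or active (ap) and segment the session.

    Warm-up samples are always labeled ap; sp runs shorter than
    ``min_sp_duration_s`` are merged into the surrounding ap.
    """
    for thr in (accel_dev_thresh, accel_var_thresh, gyro_var_thresh):
        if thr <= 0:
            raise ParameterError("stationarity thresholds must be positive")
    sp = (
        (np.abs(pre.accel_mag - g0) < accel_dev_thresh)
        & (pre.accel_var < accel_var_thresh)
        & (pre.gyro_var < gyro_var_thresh)
        & ~pre.warmup
    )
    min_run = max(1, int(round(min_sp_duration_s * pre.sample_rate)))
    for first, last, val in _runs(sp):
        if val and (last - first + 1) < min_run:
            sp[first : last + 1] = False

    flags: set = set()
    segments: list[Segment] = []
    for first, last, val in _runs(sp):
        if val:
            segments.append(Segment("sp", first, last))
        else:
            segments.append(Segment("ap", first, last))
    # Attach bracketing anchors to ap segments.
    enriched: list[Segment] = []
    for i, seg in enumerate(segments):
        if seg.kind == "sp":
            enriched.append(seg)
            continue
        n_ls = segments[i - 1].last if i > 0 else None
        n_rs = segments[i + 1].first if i + 1 < len(segments) else None
        enriched.append(Segment("ap", seg.first, seg.last, n_ls=n_ls, n_rs=n_rs))
    if not any(s.kind == "sp" for s in enriched):
        flags.add("no stationary anchor")
    return ActivityMask(stationary=sp, segments=enriched, flags=flags)


def tilt_stationary(accel: np.ndarray, mask: ActivityMask) -> np.ndarray:
    """Tilt angle on sp samples from the measured gravity components.

    ``theta_sp = atan2(g_z, g_x)`` mapped into [0, 2*pi); values on ap
    samples are returned too (same formula) but only sp samples are
    meaningful anchors.
    """
    theta = np.arctan2(accel[:, 2], accel[:, 0])
    theta = np.where(theta < 0, theta + 2 * np.pi, theta)
    return theta


def _wrap_pi(x: float) -> float:
    """Wrap an angle difference into (-pi, pi]."""
    return float((x + np.pi) % (2 * np.pi) - np.pi)


def tilt_active(
    gyro_unbiased: np.ndarray,
    mask: ActivityMask,
    theta_sp: np.ndarray,
    sample_rate: float,
) -> tuple[np.ndarray, set]:
    """Drift-corrected tilt over active segments.

    Integrates the medio-lateral angular velocity (rectangle rule, step
    ``1/sample_rate``) from the left anchor and removes the linear drift
    that would otherwise accumulate by the right anchor, so the result
    matches the accelerometer tilt at both ends.  The anchor mismatch is
    taken modulo 2*pi so that small fluctuations of the anchor angle
    around zero (i.e. across the 0/2*pi seam) do not masquerade as a
    full-turn drift.
    """
    omega_y = gyro_unbiased[:, 1]
    dt = 1.0 / sample_rate
    theta = theta_sp.copy()
    flags: set = set()
    for seg in mask.ap_segments:
        if seg.n_ls is None and seg.n_rs is None:
            flags.add("uncorrected")
            continue
        if seg.n_ls is not None:
            n_ls = seg.n_ls
            stop = seg.n_rs if seg.n_rs is not None else seg.last
            # theta(n+1) = theta(n) + omega_y(n) * dt, seeded at the anchor.
            incr = np.concatenate(([0.0], np.cumsum(omega_y[n_ls:stop]) * dt))
            theta_drift = theta_sp[n_ls] + incr
            if seg.n_rs is not None:
                n_rs = seg.n_rs
                k = _wrap_pi(theta_drift[-1] - theta_sp[n_rs]) / (n_rs - n_ls)
                drift = k * np.arange(n_rs - n_ls + 1)
                theta[n_ls : n_rs + 1] = theta_drift - drift
            else:
                flags.add("uncorrected")
                theta[n_ls : stop + 1] = theta_drift
        else:
            # Leading segment: integrate backwards from the right anchor.
            flags.add("uncorrected")
            n_rs = seg.n_rs
            incr = np.concatenate(([0.0], np.cumsum(omega_y[seg.first:n_rs]) * dt))
            theta[seg.first : n_rs + 1] = theta_sp[n_rs] - (incr[-1] - incr)
    return theta, flags


def estimate_tilt(
    pre: PreprocessedStreams, mask: ActivityMask
) -> tuple[np.ndarray, set]:
    """Full tilt series: accelerometer tilt on sp, integrated tilt on ap."""
    theta_sp = tilt_stationary(pre.accel, mask)
    return tilt_active(pre.gyro_unbiased, mask, theta_sp, pre.sample_rate)


def _approx_reconstruction(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Reconstruction from the level-``level`` approximation only."""
    with warnings.catch_warnings():
        # Deep decompositions of short (padded) fixtures trip the
        # boundary-effects warning; the reconstruction is still exact.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level)
        coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
        rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return rec[: x.shape[0]]


def dwt_denoise(
    sin_theta: np.ndarray,
    j_lo: int = DEFAULT_J_LO,
    j_hi: int = DEFAULT_J_HI,
    wavelet: str = DEFAULT_WAVELET,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Approximation-only reconstructions R_{j_lo}, R_{j_hi} and their difference.

    The input is padded by symmetric (half-sample) reflection to the next
    multiple of ``2**j_hi`` before decomposition and cropped afterwards,
    so a 10-level decomposition is well defined for any session length.
    Returns ``(r_lo, r_hi, r_lo - r_hi)``, each the length of the input.
    """
    x = np.asarray(sin_theta, dtype=float)
    n = x.shape[0]
    filt_len = pywt.Wavelet(wavelet).dec_len
    if n < filt_len:
        raise ParameterError(f"series shorter than the {wavelet} filter ({filt_len})")
    block = 2 ** j_hi
    target = ((n + block - 1) // block) * block
    pad = target - n
    left = pad // 2
    right = pad - left
    xp = np.pad(x, (left, right), mode="symmetric") if pad else x
    r_lo = _approx_reconstruction(xp, wavelet, j_lo)[left : left + n]
    r_hi = _approx_reconstruction(xp, wavelet, j_hi)[left : left + n]
    return r_lo, r_hi, r_lo - r_hi


def tilt_series(
    pre: PreprocessedStreams,
    mask: ActivityMask,
    j_lo: int = DEFAULT_J_LO,
    j_hi: int = DEFAULT_J_HI,
    wavelet: str = DEFAULT_WAVELET,
) -> TiltSeries:
    """Tilt estimation followed by wavelet denoising."""
    theta, flags = estimate_tilt(pre, mask)
    sin_theta = np.sin(theta)
    r3, r10, denoised = dwt_denoise(sin_theta, j_lo, j_hi, wavelet)
    return TiltSeries(
        theta=theta,
        sin_theta=sin_theta,
        r3=r3,
        r10=r10,
        tilt_denoise=denoised,
        flags=flags,
    )
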