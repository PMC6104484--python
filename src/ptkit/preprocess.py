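"""Signal conditioning: low-pass filtering, short-term statistics, gyro bias.

The accelerometer is low-pass filtered with a zero-phase 4th-order
Butterworth design (5 Hz cut-off); the gyroscope is left unfiltered and
only corrected for its slowly varying bias.  Short-term mean and
variance use a trailing window of N samples (N = 128, i.e. one second
at the nominal rate), with the variance evaluated against the per-lag
trailing mean:

    mu(n)      = (1/N) * sum_{i=0}^{N-1} x(n-i)
    sigma2(n)  = (1/N) * sum_{i=0}^{N-1} (x(n-i) - mu(n-i))^2

The first N-1 samples are computed over the available prefix and
flagged as warm-up; downstream stationarity decisions ignore them.

The gyroscope bias latches to the instantaneous gyro sample whenever
the short-term variance of the gyro magnitude drops below a threshold
(1e-5 rad^2/s^2 by default) and holds its previous value otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .errors import ParameterError
from .io import ImuRecording

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_ORDER = 4
DEFAULT_WINDOW = 128
DEFAULT_BIAS_VAR_THRESHOLD = 1e-5  # rad^2/s^2


@dataclass
class PreprocessedStreams:
    """All conditioned signals and their short-term statistics."""

    sample_rate: float
    accel: np.ndarray          # filtered acceleration, m/s^2, (n, 3)
    gyro: np.ndarray           # raw angular velocity, rad/s, (n, 3)
    gyro_unbiased: np.ndarray  # bias-removed angular velocity, rad/s, (n, 3)
    gyro_bias: np.ndarray      # piecewise-constant bias estimate, rad/s, (n, 3)
    accel_mag: np.ndarray      # |a|, m/s^2, (n,)
    accel_mean: np.ndarray     # mu_a, m/s^2, (n,)
    accel_var: np.ndarray      # sigma^2_a, m^2/s^4, (n,)
    gyro_mag: np.ndarray       # |omega|, rad/s, (n,)
    gyro_mean: np.ndarray      # mu_omega, rad/s, (n,)
    gyro_var: np.ndarray       # sigma^2_omega, rad^2/s^2, (n,)
    warmup: np.ndarray         # bool, True on the first N-1 samples
    window_len: int = DEFAULT_WINDOW

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]


def lowpass_accel(
    rec: ImuRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of each accelerometer axis.

    Forward-backward filtering with one second of reflective padding, so
    the group delay is zero and the DC gain is one.
    """
    nyq = rec.sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise ParameterError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if rec.n_samples < 2 * rec.sample_rate:
        raise ParameterError("need at least 2 s of data")
    b, a = signal.butter(order, cutoff_hz / nyq, btype="low")
    padlen = min(int(rec.sample_rate), rec.n_samples - 1)
    return signal.filtfilt(b, a, rec.accel, axis=0, padtype="even", padlen=padlen)


def magnitude(stream: np.ndarray) -> np.ndarray:
    """Euclidean norm per sample of an (n, 3) series."""
    return np.linalg.norm(np.asarray(stream, dtype=float), axis=-1)


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean of the trailing window ending at each sample; prefix uses all
    available samples (warm-up)."""
    n = x.shape[0]
    out = np.empty(n)
    k = min(window, n)
    for m in range(k - 1):
        out[m] = x[: m + 1].mean()
    if n >= window:
        out[window - 1:] = sliding_window_view(x, window).mean(axis=-1)
    else:
        out[n - 1] = x.mean()
    return out


def short_term_stats(
    series: np.ndarray, window: int = DEFAULT_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean and variance of a scalar series.

    The variance is evaluated literally against the per-lag trailing
    mean (see module docstring), which differs from a fixed-mean
    windowed variance.
    """
    if window <= 1:
        raise ParameterError("window must be > 1")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    mean = _trailing_mean(x, window)
    dev2 = (x - mean) ** 2
    var = _trailing_mean(dev2, window)
    return mean, var


def track_gyro_bias(
    gyro: np.ndarray,
    gyro_var: np.ndarray,
    threshold: float = DEFAULT_BIAS_VAR_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Latch-and-hold gyroscope bias estimate and the unbiased signal.

    The bias takes the instantaneous gyro sample wherever
    ``gyro_var < threshold`` and holds its previous value elsewhere; it
    is zero before the first latch.  Returns ``(bias, gyro - bias)``.
    """
    gyro = np.asarray(gyro, dtype=float)
    n = gyro.shape[0]
    latched = np.asarray(gyro_var) < threshold
    # Index of the most recent latch at or before each sample (-1 = none).
    idx = np.where(latched, np.arange(n), -1)
    idx = np.maximum.accumulate(idx)
    bias = np.where(idx[:, None] >= 0, gyro[np.clip(idx, 0, None)], 0.0)
    return bias, gyro - bias


def preprocess(
    rec: ImuRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    window: int = DEFAULT_WINDOW,
    bias_var_threshold: float = DEFAULT_BIAS_VAR_THRESHOLD,
) -> PreprocessedStreams:
    """Run the full conditioning stage on a recording."""
    accel = lowpass_accel(rec, cutoff_hz, order)
    accel_mag = magnitude(accel)
    accel_mean, accel_var = short_term_stats(accel_mag, window)
    gyro_mag = magnitude(rec.gyro)
    gyro_mean, gyro_var = short_term_stats(gyro_mag, window)
    bias, unbiased = track_gyro_bias(rec.gyro, gyro_var, bias_var_threshold)
    warmup = np.zeros(rec.n_samples, dtype=bool)
    warmup[: window - 1] = True
    return PreprocessedStreams(
        sample_rate=rec.sample_rate,
        accel=accel,
        gyro=rec.gyro.copy(),
        gyro_unbiased=unbiased,
        gyro_bias=bias,
        accel_mag=accel_mag,
        accel_mean=accel_mean,
        accel_var=accel_var,
        gyro_mag=gyro_mag,
        gyro_mean=gyro_mean,
        gyro_var=gyro_var,
        warmup=warmup,
        window_len=window,
    )
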