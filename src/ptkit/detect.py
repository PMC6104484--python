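"""Postural-transition event detection, delimitation and classification.

Candidate events are prominent peaks (either polarity) of the denoised
tilt signal; their start and end are the nearest zero crossings of the
medio-lateral angular velocity with negative slope on each side; the
vertical displacement across the event splits *effective* transitions
(|delta d_z| >= 0.1 m) from mere *attempts* (forward leans and other
trunk movements), and its sign gives the direction: positive rise =
sit-to-stand, negative = stand-to-sit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError
from .fusion import KinematicsSeries, fuse_orientation, kinematics
from .io import ImuRecording
from .posture import ActivityMask, Segment, detect_stationary, tilt_series
from .preprocess import preprocess

log = logging.getLogger(__name__)

DEFAULT_PEAK_HEIGHT = 0.1
DEFAULT_PEAK_PROMINENCE = 0.1
DEFAULT_MERGE_WINDOW_S = 1.0
DEFAULT_DZ_THRESHOLD_M = 0.1
DEFAULT_MAX_SEARCH_S = 5.0
MAX_PLAUSIBLE_DURATION_S = 10.0

EFFECTIVE = "effective"
ATTEMPT = "attempt"


@dataclass
class PTEvent:
    """One detected postural transition."""

    peak_index: int
    start_index: int
    end_index: int
    sample_rate: float
    delta_dz: float            # m, d_z(end) - d_z(start)
    direction: str             # "SiSt", "StSi" or "unknown"
    klass: str                 # "effective" or "attempt"
    peak_value: float          # tilt_denoise at the peak
    flags: set = field(default_factory=set)

    @property
    def start_s(self) -> float:
        return self.start_index / self.sample_rate

    @property
    def end_s(self) -> float:
        return self.end_index / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.sample_rate

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class DetectionResult:
    """Events plus per-stage context, for reporting and inspection."""

    events: list[PTEvent]
    mask: ActivityMask
    tilt: object
    kin: KinematicsSeries
    counts: dict

    @property
    def effective_events(self) -> list[PTEvent]:
        return [e for e in self.events if e.klass == EFFECTIVE]


def find_pt_peaks(
    tilt_denoise: np.ndarray,
    sample_rate: float,
    height: float = DEFAULT_PEAK_HEIGHT,
    prominence: float = DEFAULT_PEAK_PROMINENCE,
    merge_window_s: float = DEFAULT_MERGE_WINDOW_S,
) -> np.ndarray:
    """Indices of prominent peaks of the denoised tilt signal, both polarities.

    A candidate is a local maximum of the signal or of its negation with
    absolute height above ``height`` and topographic prominence above
    ``prominence``.  Candidates closer than ``merge_window_s`` are merged
    keeping the larger absolute value (ties: earlier sample).
    """
    if height <= 0 or prominence <= 0:
        raise ParameterError("height and prominence must be positive")
    x = np.asarray(tilt_denoise, dtype=float)
    pos, _ = find_peaks(x, height=height, prominence=prominence)
    neg, _ = find_peaks(-x, height=height, prominence=prominence)
    cand = np.concatenate([pos, neg])
    if cand.size == 0:
        return cand.astype(int)
    # Greedy suppression: strongest first, drop anything within the window.
    order = sorted(cand, key=lambda i: (-abs(x[i]), i))
    window = merge_window_s * sample_rate
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= window for j in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def _neg_slope_crossings(omega_y: np.ndarray) -> np.ndarray:
    """Sample indices k with omega_y(k) >= 0 > omega_y(k+1).

    Exact-zero runs resolve to the run's last sample automatically, since
    only the sample immediately preceding a negative one can qualify.
    """
    w = np.asarray(omega_y, dtype=float)
    return np.flatnonzero((w[:-1] >= 0) & (w[1:] < 0))


def locate_boundaries(
    omega_y: np.ndarray,
    peak: int,
    sample_rate: float,
    max_search_s: float = DEFAULT_MAX_SEARCH_S,
    mask: ActivityMask | None = None,
) -> tuple[int, int, set]:
    """Start/end of the event around ``peak``: nearest negative-slope zero
    crossings of the medio-lateral angular velocity on each side.

    The search is capped at ``max_search_s``; when no crossing exists the
    nearest stationary-segment boundary is used instead and the event is
    flagged (``fallback_start`` / ``fallback_end``).
    """
    n = omega_y.shape[0]
    if not 0 <= peak < n:
        raise ParameterError(f"peak {peak} outside series of length {n}")
    reach = int(round(max_search_s * sample_rate))
    crossings = _neg_slope_crossings(omega_y)
    flags: set = set()

    left = crossings[(crossings < peak) & (crossings >= peak - reach)]
    if left.size:
        start = int(left[-1])
    else:
        start = _nearest_sp_boundary(mask, peak, side="left")
        flags.add("fallback_start")
    right = crossings[(crossings >= peak) & (crossings <= peak + reach)]
    if right.size:
        end = int(right[0])
    else:
        end = _nearest_sp_boundary(mask, peak, side="right")
        flags.add("fallback_end")
    if start >= peak:
        start, flags = max(peak - 1, 0), flags | {"fallback_start"}
    if end <= peak:
        end, flags = min(peak + 1, n - 1), flags | {"fallback_end"}
    return start, end, flags


def _nearest_sp_boundary(mask: ActivityMask | None, peak: int, side: str) -> int:
    if mask is not None:
        for seg in mask.ap_segments:
            if seg.first <= peak <= seg.last:
                if side == "left":
                    return seg.n_ls if seg.n_ls is not None else seg.first
                return seg.n_rs if seg.n_rs is not None else seg.last
    return max(peak - 1, 0) if side == "left" else peak + 1


def classify_events(
    peaks: np.ndarray,
    tilt_denoise: np.ndarray,
    omega_y: np.ndarray,
    d_z: np.ndarray,
    sample_rate: float,
    dz_threshold: float = DEFAULT_DZ_THRESHOLD_M,
    max_search_s: float = DEFAULT_MAX_SEARCH_S,
    mask: ActivityMask | None = None,
) -> list[PTEvent]:
    """Delimit each peak and classify it by vertical displacement.

    An event is *effective* iff |d_z(end) - d_z(start)| >= ``dz_threshold``
    and its direction follows the displacement sign; otherwise it is an
    *attempt* with direction "unknown" kept for inspection.

    Candidates whose delimited spans overlap describe the same movement
    (denoising ripple can put a secondary peak inside, or next to, the
    same pair of zero crossings); of each overlapping group only the
    event with the largest absolute peak value is kept.
    """
    if dz_threshold <= 0:
        raise ParameterError("dz_threshold must be positive")
    n = d_z.shape[0]
    events: list[PTEvent] = []
    for peak in np.asarray(peaks, dtype=int):
        start, end, flags = locate_boundaries(
            omega_y, int(peak), sample_rate, max_search_s, mask
        )
        end = min(end, n - 1)
        dz0, dz1 = d_z[start], d_z[end]
        if math.isnan(dz0) or math.isnan(dz1):
            delta = math.nan
            flags.add("no_kinematics")
        else:
            delta = float(dz1 - dz0)
        if math.isfinite(delta) and abs(delta) >= dz_threshold:
            klass = EFFECTIVE
            direction = "SiSt" if delta > 0 else "StSi"
        else:
            klass = ATTEMPT
            direction = "unknown"
        duration = (end - start) / sample_rate
        if duration > MAX_PLAUSIBLE_DURATION_S:
            flags.add("long_duration")
        events.append(
            PTEvent(
                peak_index=int(peak),
                start_index=int(start),
                end_index=int(end),
                sample_rate=sample_rate,
                delta_dz=delta,
                direction=direction,
                klass=klass,
                peak_value=float(tilt_denoise[peak]),
                flags=flags,
            )
        )
    # One event per delimited span: overlapping spans collapse to the
    # strongest peak (ties: earlier peak).
    events.sort(key=lambda e: (e.start_index, e.end_index, e.peak_index))
    merged: list[PTEvent] = []
    group_end = -1
    for ev in events:
        if merged and ev.start_index < group_end:
            if (-abs(ev.peak_value), ev.peak_index) < (
                -abs(merged[-1].peak_value), merged[-1].peak_index
            ):
                merged[-1] = ev
        else:
            merged.append(ev)
            group_end = -1
        group_end = max(group_end, ev.end_index)
    return merged


def detect_full(rec: ImuRecording, config=None) -> DetectionResult:
    """Run the complete pipeline on a recording and keep stage context."""
    from .config import PipelineConfig

    cfg = config if config is not None else PipelineConfig()
    cfg.validate()
    pre = preprocess(
        rec,
        cutoff_hz=cfg.preprocess.cutoff_hz,
        order=cfg.preprocess.order,
        window=cfg.preprocess.window,
        bias_var_threshold=cfg.preprocess.bias_var_threshold,
    )
    mask = detect_stationary(
        pre,
        accel_dev_thresh=cfg.posture.accel_dev_thresh,
        accel_var_thresh=cfg.posture.accel_var_thresh,
        gyro_var_thresh=cfg.posture.gyro_var_thresh,
        g0=cfg.posture.g0,
        min_sp_duration_s=cfg.posture.min_sp_duration_s,
    )
    tilt = tilt_series(
        pre, mask, j_lo=cfg.posture.j_lo, j_hi=cfg.posture.j_hi,
        wavelet=cfg.posture.wavelet,
    )
    qs = fuse_orientation(
        pre, mask, beta_sp=cfg.fusion.beta_sp, beta_ap=cfg.fusion.beta_ap,
        q0=tuple(cfg.fusion.q0),
    )
    kin = kinematics(pre, mask, qs, g0=cfg.posture.g0)
    peaks = find_pt_peaks(
        tilt.tilt_denoise,
        rec.sample_rate,
        height=cfg.detect.height,
        prominence=cfg.detect.prominence,
        merge_window_s=cfg.detect.merge_window_s,
    )
    events = classify_events(
        peaks,
        tilt.tilt_denoise,
        pre.gyro_unbiased[:, 1],
        kin.d_z,
        rec.sample_rate,
        dz_threshold=cfg.detect.dz_threshold,
        max_search_s=cfg.detect.max_search_s,
        mask=mask,
    )
    counts = {
        "sp_segments": len(mask.sp_segments),
        "ap_segments": len(mask.ap_segments),
        "candidate_peaks": int(len(peaks)),
        "attempts": sum(1 for e in events if e.klass == ATTEMPT),
        "effective_events": sum(1 for e in events if e.klass == EFFECTIVE),
    }
    log.info("detection counts: %s", counts)
    return DetectionResult(events=events, mask=mask, tilt=tilt, kin=kin, counts=counts)


def detect(rec: ImuRecording, config=None) -> list[PTEvent]:
    """Classified events for a recording (effective and attempts)."""
    return detect_full(rec, config).events
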