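"""Event-level validation against a reference annotation.

Detected effective transitions are matched one-to-one to reference
events by ascending midpoint distance (greedy) within a tolerance;
matched pairs are true positives, unmatched detections false positives,
unmatched references false negatives.  The contingency metrics are the
event-level sensitivity TP/(TP+FN), positive predictive value
TP/(TP+FP) and accuracy TP/(TP+FP+FN); duration agreement follows the
limits-of-agreement convention (mean paired difference +/- 1.96 SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import InsufficientDataError, ValidationError
from .io import AnnotationSet, PTAnnotation

DEFAULT_MATCH_TOLERANCE_S = 2.0


@dataclass
class MatchedPair:
    event: object            # detected PTEvent
    annotation: PTAnnotation
    offset: float            # event midpoint - annotation midpoint, s


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float              # %, nan when undefined
    ppv: float                      # %
    accuracy: float                 # %
    direction_accuracy: float       # % over matched pairs
    matches: list[MatchedPair] = field(default_factory=list)
    duration_mean_alg: float = math.nan
    duration_sd_alg: float = math.nan
    duration_mean_ref: float = math.nan
    mean_duration_diff: float = math.nan
    diff_sd: float = math.nan
    diff_ci95: tuple[float, float] = (math.nan, math.nan)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "ppv_pct": self.ppv,
            "accuracy_pct": self.accuracy,
            "direction_accuracy_pct": self.direction_accuracy,
            "duration_mean_alg_s": self.duration_mean_alg,
            "duration_sd_alg_s": self.duration_sd_alg,
            "duration_mean_ref_s": self.duration_mean_ref,
            "mean_duration_diff_s": self.mean_duration_diff,
            "diff_ci95_s": list(self.diff_ci95),
            "n_matches": len(self.matches),
        }


def contingency_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity %, PPV %, accuracy %) from event-level counts.

    Undefined ratios (zero denominator) come back as NaN.  Full precision
    is returned; round for display.
    """
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else math.nan
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else math.nan
    acc = 100.0 * tp / (tp + fp + fn) if (tp + fp + fn) > 0 else math.nan
    return sens, ppv, acc


def match_events(
    detected: list,
    reference: AnnotationSet,
    tolerance: float = DEFAULT_MATCH_TOLERANCE_S,
) -> EvaluationReport:
    """Greedy one-to-one matching of effective events to reference events.

    Only effective events should be passed in (attempts are excluded from
    the final result by convention).  Pairs are admitted in order of
    ascending absolute midpoint difference, each side used at most once.
    """
    dets = list(detected)
    refs = list(reference.events)
    pairs = []
    for i, ev in enumerate(dets):
        for j, ann in enumerate(refs):
            off = ev.midpoint_s - ann.midpoint
            if abs(off) <= tolerance:
                pairs.append((abs(off), i, j, off))
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    matches: list[MatchedPair] = []
    for _, i, j, off in pairs:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        matches.append(MatchedPair(dets[i], refs[j], off))
    tp = len(matches)
    fp = len(dets) - tp
    fn = len(refs) - tp
    sens, ppv, acc = contingency_metrics(tp, fp, fn)
    if tp:
        agree = sum(1 for m in matches if m.event.direction == m.annotation.direction)
        dir_acc = 100.0 * agree / tp
    else:
        dir_acc = math.nan
    report = EvaluationReport(
        tp=tp, fp=fp, fn=fn,
        sensitivity=sens, ppv=ppv, accuracy=acc,
        direction_accuracy=dir_acc, matches=matches,
    )
    if tp >= 2:
        duration_agreement(report)
    return report


def duration_agreement(report: EvaluationReport) -> EvaluationReport:
    """Fill in duration statistics (limits of agreement) for matched pairs."""
    if len(report.matches) < 2:
        raise InsufficientDataError("need at least 2 matched pairs")
    alg = np.array([m.event.duration for m in report.matches])
    ref = np.array([m.annotation.duration for m in report.matches])
    diffs = alg - ref
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    report.duration_mean_alg = float(alg.mean())
    report.duration_sd_alg = float(alg.std(ddof=1))
    report.duration_mean_ref = float(ref.mean())
    report.mean_duration_diff = mean
    report.diff_sd = sd
    report.diff_ci95 = (mean - 1.96 * sd, mean + 1.96 * sd)
    return report


def welch_ttest(durations_a, durations_b) -> tuple[float, float]:
    """Two-sample Welch t statistic and p-value for group duration comparison."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 durations per group")
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pool_reports(reports: list[EvaluationReport]) -> tuple[int, int, int]:
    """Summed (tp, fp, fn) over grouped reports."""
    return (
        sum(r.tp for r in reports),
        sum(r.fp for r in reports),
        sum(r.fn for r in reports),
    )
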