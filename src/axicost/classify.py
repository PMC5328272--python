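"""Threshold classification of nomogram scores against the observed NSN status.

The nomogram score is read as a binary test: predicted positive iff the score
exceeds the threshold (ties go to the low-risk side), with ground truth being
non-sentinel node (NSN) positivity on completion axillary dissection.  Beyond
the usual sensitivity/specificity, the whole-cohort false-negative and
false-positive rates FN/N and FP/N are first-class here because they are the
quantities a clinic deciding on a threshold actually trades off — the share
of all patients whose dissection would be wrongly omitted or wrongly kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cohort import Cohort, RiskGroup, SNType, stratify

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "classify",
    "metrics",
    "sweep",
    "DEFAULT_THRESHOLD_GRID",
]

DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TN/FN/TP/FP totals with a per-SN-type breakdown.

    Truth = NSN positivity; prediction = score > threshold.  TN and FN are the
    below-threshold (low-risk) patients, TP and FP the above-threshold ones.
    """

    threshold: float
    tn: int
    fn: int
    tp: int
    fp: int
    per_type: Mapping[SNType, tuple[int, int, int, int]]  # (tn, fn, tp, fp)

    def __post_init__(self) -> None:
        if min(self.tn, self.fn, self.tp, self.fp) < 0:
            raise ValueError("confusion cells must be non-negative")
        sums = [sum(cells[i] for cells in self.per_type.values()) for i in range(4)]
        if sums != [self.tn, self.fn, self.tp, self.fp]:
            raise ValueError("per-type breakdown does not sum to the totals")

    @property
    def n(self) -> int:
        return self.tn + self.fn + self.tp + self.fp


@dataclass(frozen=True)
class MetricSet:
    """The validation metrics; ratios with a zero denominator are None.

    ``fn_rate_total`` and ``fp_rate_total`` are FN/N and FP/N — proportions of
    the whole cohort, not of the diseased/healthy subsets.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    fn_rate_total: float
    fp_rate_total: float

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "fn_rate_total": self.fn_rate_total,
            "fp_rate_total": self.fp_rate_total,
        }


def classify(cohort: Cohort, threshold: float) -> ConfusionMatrix:
    """Tally the confusion matrix of ``score > threshold`` against NSN status."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    per_type = {t: [0, 0, 0, 0] for t in SNType}  # tn, fn, tp, fp
    for p in cohort:
        predicted_pos = p.mskcc_score > threshold
        if predicted_pos:
            idx = 2 if p.nsn_positive else 3
        else:
            idx = 1 if p.nsn_positive else 0
        per_type[p.sn_type][idx] += 1
    totals = [sum(per_type[t][i] for t in SNType) for i in range(4)]
    return ConfusionMatrix(
        threshold=threshold,
        tn=totals[0],
        fn=totals[1],
        tp=totals[2],
        fp=totals[3],
        per_type={t: tuple(cells) for t, cells in per_type.items()},
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, predictive values, accuracy and the
    whole-cohort FN/FP rates for one confusion matrix."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / n,
        fn_rate_total=cm.fn / n,
        fp_rate_total=cm.fp / n,
    )


def metrics_exact(cm: ConfusionMatrix) -> dict[str, Fraction]:
    """Rational-arithmetic counterpart of :func:`metrics` for exact checks."""
    n = cm.n
    out: dict[str, Fraction] = {
        "accuracy": Fraction(cm.tp + cm.tn, n),
        "fn_rate_total": Fraction(cm.fn, n),
        "fp_rate_total": Fraction(cm.fp, n),
    }
    if cm.tp + cm.fn:
        out["sensitivity"] = Fraction(cm.tp, cm.tp + cm.fn)
    if cm.tn + cm.fp:
        out["specificity"] = Fraction(cm.tn, cm.tn + cm.fp)
    return out


def sweep(cohort: Cohort, thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID) -> pd.DataFrame:
    """Confusion cells, metrics and per-type LOW/HIGH counts over a threshold grid.

    One row per threshold; the default grid is 0.1, 0.2, ..., 0.9.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    rows = []
    for t in thresholds:
        cm = classify(cohort, t)
        ms = metrics(cm)
        sc = stratify(cohort, t)
        row: dict[str, object] = {
            "threshold": t,
            "tn": cm.tn,
            "fn": cm.fn,
            "tp": cm.tp,
            "fp": cm.fp,
        }
        for sn_type in SNType:
            row[f"low_{sn_type.value}"] = sc.group_type(RiskGroup.LOW, sn_type)
            row[f"high_{sn_type.value}"] = sc.group_type(RiskGroup.HIGH, sn_type)
        row.update(ms.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
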