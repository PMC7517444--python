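"""Confusion-matrix scoring of hourly detections against ground truth.

Every hour in the label set is scored: a labeled-abnormal hour flagged by
the detector is a true positive, an unflagged one a false negative, and
symmetrically for labeled-normal hours.  The five ratios (sensitivity,
specificity, false positive rate, false negative rate, accuracy) are
reported as percentages; a ratio with a zero denominator is returned as
NaN (undefined) rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .detection import DetectionResult
from .event_io import ABNORMAL, LabelSet

__all__ = ["ConfusionMatrix", "score", "metrics", "metrics_table"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Hourly-event counts; TP+FP+TN+FN equals the number of scored hours."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def score(result: DetectionResult, labels: LabelSet, measure: str) -> ConfusionMatrix:
    """Count TP/FP/TN/FN over every labeled hour for one measure."""
    if measure not in result.anomalous_hours:
        raise ValueError(f"measure {measure!r} not in detection result")
    flagged = result.anomalous_hours[measure]
    tp = fp = tn = fn = 0
    for key, label in labels.hour_labels.items():
        is_abnormal = label == ABNORMAL
        is_flagged = key in flagged
        if is_abnormal and is_flagged:
            tp += 1
        elif is_abnormal:
            fn += 1
        elif is_flagged:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den else math.nan


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, FPR, FNR and accuracy, in percent.

    Undefined ratios (zero denominator) are NaN.
    """
    return {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "fpr": _ratio(cm.fp, cm.fp + cm.tn),
        "fnr": _ratio(cm.fn, cm.fn + cm.tp),
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
    }


def metrics_table(
    result: DetectionResult, labels: LabelSet, measures: Iterable[str] | None = None
) -> pd.DataFrame:
    """One row per measure with the five metrics (percent, 1-decimal shape
    when printed); columns: sensitivity, specificity, fpr, fnr, accuracy."""
    measures = list(measures) if measures is not None else sorted(
        result.anomalous_hours
    )
    rows = {m: metrics(score(result, labels, m)) for m in measures}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "measure"
    return table
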