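"""Confusion-matrix construction and fall-detection metrics.

Overall accuracy is the diagonal fraction of the 8x8 actual-by-predicted
matrix.  Fall sensitivity and specificity use the standard binary
fall-vs-ADL collapse:

    sensitivity = TP / (TP + FN)   (fall windows predicted as falls)
    specificity = TN / (TN + FP)   (ADL windows not predicted as falls)

Note on the published reference matrix: the offline-test confusion
matrix bundled here as :data:`REFERENCE_OFFLINE_CONFUSION` yields
99.17% accuracy, but its binary fall sensitivity/specificity are
99.58%/100.00% — the 94.09%/99.94% quoted alongside it in the original
evaluation are not derivable from the matrix under any standard binary
collapse, and the formula behind those two figures was never stated.
This package reports the standard definitions and flags the mismatch
rather than reverse-engineering an undocumented one.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_imu import ActivityLabel, FALL_LABEL


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows = actual class, columns = predicted class,
    ordered by the fixed ActivityLabel encoding."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            m = m.astype(int)
            if np.any(m < 0):
                raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "counts", m)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path | io.TextIOBase | None = None) -> str:
        names = [a.name for a in ActivityLabel][: self.k]
        if len(names) < self.k:
            names = [f"class_{i}" for i in range(self.k)]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        text = df.to_csv()
        if path is not None and not isinstance(path, io.TextIOBase):
            Path(path).write_text(text)
        return text


def confusion(y_true, y_pred, k: int = len(ActivityLabel)) -> ConfusionMatrix:
    """Count matrix entry (i, j) = samples with actual i predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}")
    if y_true.size and not ((0 <= y_true).all() and (y_true < k).all()
                            and (0 <= y_pred).all() and (y_pred < k).all()):
        raise ValueError(f"labels must lie in [0, {k})")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 x trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall in percent; NaN for classes with no samples."""
    row_sums = cm.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * np.diag(cm.counts) / np.where(row_sums, row_sums, np.nan)


def fall_binary_metrics(cm: ConfusionMatrix,
                        fall_index: int = int(FALL_LABEL)
                        ) -> tuple[float, float]:
    """(sensitivity %, specificity %) of the binary fall-vs-ADL collapse.

    A zero denominator (no fall rows, or no ADL rows) makes the affected
    metric NaN rather than raising.
    """
    if not 0 <= fall_index < cm.k:
        raise ValueError(f"fall_index {fall_index} out of range for k={cm.k}")
    m = cm.counts
    tp = int(m[fall_index, fall_index])
    fn = int(m[fall_index].sum()) - tp
    fp = int(m[:, fall_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale summary of a classification run; values carry full
    precision internally and round to 2 dp only for display."""

    accuracy: float
    fall_sensitivity: float
    fall_specificity: float
    per_class_recall: tuple[float, ...]

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix,
                       fall_index: int = int(FALL_LABEL)) -> "MetricsReport":
        sens, spec = fall_binary_metrics(cm, fall_index)
        return cls(accuracy=accuracy(cm), fall_sensitivity=sens,
                   fall_specificity=spec,
                   per_class_recall=tuple(per_class_recall(cm)))

    def to_json(self) -> str:
        return json.dumps({
            "accuracy_pct": self.accuracy,
            "fall_sensitivity_pct": self.fall_sensitivity,
            "fall_specificity_pct": self.fall_specificity,
            "per_class_recall_pct": list(self.per_class_recall),
        })

    def to_text(self) -> str:
        lines = [f"accuracy:          {self.accuracy:.2f}%",
                 f"fall sensitivity:  {self.fall_sensitivity:.2f}%",
                 f"fall specificity:  {self.fall_specificity:.2f}%"]
        names = [a.name for a in ActivityLabel]
        for name, r in zip(names, self.per_class_recall):
            lines.append(f"  recall {name:<16s} {r:6.2f}%")
        return "\n".join(lines)


# Offline-test confusion matrix published for the reference FD-DNN
# evaluation (8 activities x 240 test windows each); rows/columns follow
# the ActivityLabel order walking..falling.  Used as a worked example and
# as the arithmetic check that its accuracy equals 99.17%.
REFERENCE_OFFLINE_CONFUSION = ConfusionMatrix(np.array([
    #  wal  jog  jum  ups  dwn  stu  sit  fal
    [240,   0,   0,   0,   0,   0,   0,   0],   # walking
    [  0, 239,   0,   1,   0,   0,   0,   0],   # jogging
    [  0,   0, 240,   0,   0,   0,   0,   0],   # jumping
    [  0,   0,   0, 238,   2,   0,   0,   0],   # going upstairs
    [  0,   0,   0,   2, 238,   0,   0,   0],   # going downstairs
    [  0,   0,   0,   0,   0, 234,   6,   0],   # standing up
    [  0,   0,   0,   0,   0,   4, 236,   0],   # sitting down
    [  0,   0,   0,   0,   0,   0,   1, 239],   # falling
]))
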