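"""Classification metrics for the three-way motion classifier.

The classifier assigns each flow-color frame one of three movement classes
(insertion, withdrawal, stop).  Its cross-validated predictions are summarised
in a 3x3 confusion matrix whose rows index the *predicted* (output) class and
whose columns index the *true* (target) class.  From that matrix this module
derives per-class recall, precision and F1 together with the overall accuracy,
and it evaluates cecum estimates against ground truth with the +/- t/2 hit
rule used to score the locator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical class order used everywhere in the package.
CLASS_NAMES = ("insertion", "withdrawal", "stop")


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 confusion matrix; rows = predicted class, columns = true class.

    Class order is ``(insertion, withdrawal, stop)`` on both axes.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_sums(self) -> np.ndarray:
        """Total predictions per output class."""
        return self.counts.sum(axis=1)

    @property
    def column_sums(self) -> np.ndarray:
        """Total true samples per target class."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls, predicted: Sequence[int], true: Sequence[int]
    ) -> "ConfusionMatrix3":
        """Build the matrix from integer class indices (0, 1, 2)."""
        predicted = np.asarray(predicted, dtype=np.int64)
        true = np.asarray(true, dtype=np.int64)
        if predicted.shape != true.shape:
            raise ValueError("predicted and true label arrays differ in length")
        counts = np.zeros((3, 3), dtype=np.int64)
        np.add.at(counts, (predicted, true), 1)
        return cls(counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix3":
        """Read a matrix written by :meth:`to_csv` (header row and column)."""
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(dtype=np.int64))

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.counts, index=CLASS_NAMES, columns=CLASS_NAMES)
        frame.to_csv(path)

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class recall/precision/F1 plus overall accuracy.

    Each per-class dict is keyed by class name in canonical order.
    """

    recall: dict[str, float]
    precision: dict[str, float]
    f1: dict[str, float]
    overall_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        """Metrics as a tidy table, one row per class."""
        return pd.DataFrame(
            {
                "recall": self.recall,
                "precision": self.precision,
                "f1": self.f1,
            }
        ).loc[list(CLASS_NAMES)]

    def round(self, ndigits: int = 3) -> "ClassMetrics":
        rnd = lambda d: {k: round(v, ndigits) for k, v in d.items()}
        return ClassMetrics(
            recall=rnd(self.recall),
            precision=rnd(self.precision),
            f1=rnd(self.f1),
            overall_accuracy=round(self.overall_accuracy, ndigits),
        )


def compute_metrics(cm: ConfusionMatrix3) -> ClassMetrics:
    """Derive recall, precision, F1 and overall accuracy from a confusion matrix.

    recall_c = diag_c / column_sum_c, precision_c = diag_c / row_sum_c and
    f1_c is their harmonic mean; overall accuracy is trace / total.  A class
    absent from the truth (zero column sum) has recall 0 by convention, and a
    class never predicted (zero row sum) has precision 0; a warning is issued
    because small runs commonly hit this.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty (total count is zero)")
    diag = np.diag(cm.counts).astype(float)
    col = cm.column_sums.astype(float)
    row = cm.row_sums.astype(float)
    if (col == 0).any() or (row == 0).any():
        warnings.warn(
            "confusion matrix has an empty class; its recall/precision is 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        precision = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = recall + precision
        f1 = np.where(denom > 0, 2 * recall * precision / np.where(denom > 0, denom, 1), 0.0)
    return ClassMetrics(
        recall=dict(zip(CLASS_NAMES, recall)),
        precision=dict(zip(CLASS_NAMES, precision)),
        f1=dict(zip(CLASS_NAMES, f1)),
        overall_accuracy=float(diag.sum() / cm.total),
    )


def load_reference_confusion() -> ConfusionMatrix3:
    """Load the packaged reference confusion matrix of the published
    three-way classifier (5-fold cross-validation counts, 328,927 frames)."""
    with resources.as_file(
        resources.files("scopemotion.data").joinpath("table1_confusion.csv")
    ) as path:
        return ConfusionMatrix3.from_csv(path)


def cecum_hit(estimated_time: float, truth_time: float, t: float) -> bool:
    """A cecum estimate is a hit when it lies within +/- t/2 of the truth."""
    if t <= 0:
        raise ValueError("t must be positive")
    return abs(float(estimated_time) - float(truth_time)) <= t / 2.0


def accuracy_vs_t(
    signals_with_truth: Sequence[tuple["DirectionSignal", float]],
    t_values: Sequence[float],
) -> dict[float, float]:
    """Hit rate of the cecum locator across a battery of signals, per window t.

    For each ``t`` the locator is run with that window on every signal and the
    fraction of estimates within +/- t/2 of the known cecum time is returned.
    Signals in which the locator finds no turning point count as misses.
    """
    from .locator import locate_cecum

    if not signals_with_truth or not t_values:
        raise ValueError("signals and t_values must be non-empty")
    result: dict[float, float] = {}
    for t in t_values:
        hits = 0
        for signal, truth in signals_with_truth:
            estimate = locate_cecum(signal, t)
            if estimate.time is not None and cecum_hit(estimate.time, truth, t):
                hits += 1
        result[float(t)] = hits / len(signals_with_truth)
    return result
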