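"""Confusion counting and the four detection scores.

Red tide is the positive class. Over the valid pixels of the test data:

    Accuracy  = (TP + TN) / (TP + TN + FP + FN) * 100%
    Precision = TP / (TP + FP) * 100%
    Recall    = TP / (TP + FN) * 100%
    F1-score  = 2 * Precision * Recall / (Precision + Recall)   (0..1)

Percentages are reported to 2 decimal places and F1 as a fraction to 2
decimal places, the conventional table precision. Scores are pooled
(micro) over all valid pixels, not averaged per patch. Precision, recall
and F1 are defined as 0 when their denominators vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import CLASS_RED_TIDE, LabelMap

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "metric_delta",
    "comparison_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 pixel counts with red tide as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """accuracy/precision/recall in percent, F1 as a fraction in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        return MetricsReport(
            round(self.accuracy, ndigits), round(self.precision, ndigits),
            round(self.recall, ndigits), round(self.f1, ndigits),
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def confusion(pred: LabelMap, truth: LabelMap) -> ConfusionCounts:
    """Count the 2x2 table over pixels valid in the truth map."""
    if pred.labels.shape != truth.labels.shape:
        raise ValueError("prediction and truth shapes differ")
    v = truth.valid
    if not v.any():
        raise ValueError("no valid pixels to evaluate")
    p = pred.labels[v] == CLASS_RED_TIDE
    t = truth.labels[v] == CLASS_RED_TIDE
    return ConfusionCounts(
        tp=int((p & t).sum()), tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()), fn=int((~p & t).sum()),
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """F1 (fraction) from precision/recall given in percent."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall) / 100.0


def metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total == 0:
        raise ValueError("metrics need at least one counted pixel")
    accuracy = (c.tp + c.tn) / c.total * 100.0
    precision = c.tp / (c.tp + c.fp) * 100.0 if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) * 100.0 if c.tp + c.fn else 0.0
    return MetricsReport(accuracy, precision, recall, f1_from_pr(precision, recall))


def metric_delta(a: MetricsReport, b: MetricsReport) -> dict[str, float]:
    """Per-metric differences b - a, rounded to 2 decimal places."""
    return {
        "accuracy": round(b.accuracy - a.accuracy, 2),
        "precision": round(b.precision - a.precision, 2),
        "recall": round(b.recall - a.recall, 2),
        "f1": round(b.f1 - a.f1, 2),
    }


def comparison_table(
    reports: dict[str, MetricsReport], sort_by_f1: bool = False
) -> pd.DataFrame:
    """One row of rounded scores per model, suitable for CSV/JSON output."""
    df = pd.DataFrame(
        [
            {"model": name, **report.rounded().to_dict()}
            for name, report in reports.items()
        ]
    )
    if sort_by_f1:
        df = df.sort_values("f1", ascending=False, kind="stable").reset_index(drop=True)
    return df


def confusion_on_patches(model, dataset, split: str | None = "test") -> ConfusionCounts:
    """Pooled confusion counts of a patch model over a dataset split.

    `model` needs a ``predict_patches((N, C, P, P)) -> (N, P, P)`` method;
    counts pool every valid pixel of the selected split (micro).
    """
    if split is not None:
        dataset = dataset.subset(split)
    if len(dataset) == 0:
        raise ValueError("no patches to evaluate")
    x = dataset.features.transpose(0, 3, 1, 2).astype(np.float32)
    pred = model.predict_patches(x).astype(bool)
    truth = dataset.labels.astype(bool)
    v = dataset.valid
    return ConfusionCounts(
        tp=int((pred & truth & v).sum()), tn=int((~pred & ~truth & v).sum()),
        fp=int((pred & ~truth & v).sum()), fn=int((~pred & truth & v).sum()),
    )


def evaluate_predictions(
    named_predictions: dict[str, LabelMap], truth: LabelMap, sort_by_f1: bool = False
) -> pd.DataFrame:
    """Confusion + metrics per named prediction against one truth map."""
    return comparison_table(
        {name: metrics(confusion(pred, truth)) for name, pred in named_predictions.items()},
        sort_by_f1=sort_by_f1,
    )
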