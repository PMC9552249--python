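"""Segmentation and classification metrics, and competition-rank model selection.

Segmentation metrics are averaged *per image and per class* rather than
per batch: histology datasets contain many patches with no eosinophils
at all, and batch-pooled counts would let a few dense patches dominate.
The mean of a metric m over a dataset is

    m = (1 / (I*C)) * sum_i sum_c m(TP_ic, FP_ic, FN_ic, TN_ic)

with I images and C classes.  Terms with a zero denominator (e.g. an
empty-truth patch under recall) follow a configurable convention; the
default scores 1 when the corresponding prediction is also empty and 0
otherwise, so a model is rewarded for correctly predicting "nothing".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .masks import CLASSES, LabelMaskStack

MetricKind = Literal["iou", "precision", "recall", "specificity"]
ZeroDivision = Literal["score", "skip"]

#: The eight per-image selection metrics used during model training:
#: mIoU, mRecall, mPrecision, and five precision/recall mixes.
SELECTION_METRICS: tuple[tuple[str, float | None], ...] = (
    ("miou", None),
    ("mrecall", 0.0),
    ("mprecision", 1.0),
    ("m(0.3P+0.7R)", 0.3),
    ("m(0.4P+0.6R)", 0.4),
    ("m(0.5P+0.5R)", 0.5),
    ("m(0.6P+0.4R)", 0.6),
    ("m(0.7P+0.3R)", 0.7),
)


@dataclass
class ConfusionCounts:
    """Pixel confusion counts, shape (I, C) for I images and C classes."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        arrs = [np.atleast_2d(np.asarray(a, dtype=np.int64)) for a in (self.tp, self.fp, self.fn, self.tn)]
        self.tp, self.fp, self.fn, self.tn = arrs
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError("tp/fp/fn/tn must share a shape")
        if any((a < 0).any() for a in arrs):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_images(self) -> int:
        return self.tp.shape[0]

    @staticmethod
    def concatenate(parts: Sequence["ConfusionCounts"]) -> "ConfusionCounts":
        return ConfusionCounts(
            tp=np.concatenate([p.tp for p in parts]),
            fp=np.concatenate([p.fp for p in parts]),
            fn=np.concatenate([p.fn for p in parts]),
            tn=np.concatenate([p.tn for p in parts]),
            classes=parts[0].classes,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (image, class)."""
        rows = []
        for i in range(self.n_images):
            for j, cls in enumerate(self.classes):
                rows.append(
                    {"image": i, "class": cls,
                     "tp": self.tp[i, j], "fp": self.fp[i, j],
                     "fn": self.fn[i, j], "tn": self.tn[i, j]}
                )
        return pd.DataFrame(rows)


def confusion_counts(pred: LabelMaskStack, truth: LabelMaskStack) -> ConfusionCounts:
    """Pixelwise per-class TP/FP/FN/TN for one image."""
    if pred.extent != truth.extent:
        raise ValueError(f"extent mismatch: {pred.extent} vs {truth.extent}")
    tp, fp, fn, tn = [], [], [], []
    for cls in CLASSES:
        p, g = pred.masks[cls], truth.masks[cls]
        tp.append(int(np.count_nonzero(p & g)))
        fp.append(int(np.count_nonzero(p & ~g)))
        fn.append(int(np.count_nonzero(~p & g)))
        tn.append(int(np.count_nonzero(~p & ~g)))
    return ConfusionCounts(tp=[tp], fp=[fp], fn=[fn], tn=[tn])


def _term(kind: MetricKind, tp: int, fp: int, fn: int, tn: int,
          zero_division: ZeroDivision) -> float | None:
    if kind == "iou":
        num, den, other_empty = tp, tp + fp + fn, True
    elif kind == "precision":
        num, den, other_empty = tp, tp + fp, fn == 0  # pred empty: perfect iff truth empty
    elif kind == "recall":
        num, den, other_empty = tp, tp + fn, fp == 0  # truth empty: perfect iff pred empty
    elif kind == "specificity":
        num, den, other_empty = tn, tn + fp, fn == 0
    else:
        raise ValueError(f"unknown metric kind {kind!r}")
    if den == 0:
        if zero_division == "skip":
            return None
        return 1.0 if other_empty else 0.0
    return num / den


def mean_metric(counts: ConfusionCounts, kind: MetricKind,
                zero_division: ZeroDivision = "score") -> float:
    """Mean of a per-(image, class) metric over all images and classes."""
    terms = [
        _term(kind, counts.tp[i, j], counts.fp[i, j], counts.fn[i, j], counts.tn[i, j],
              zero_division)
        for i in range(counts.tp.shape[0])
        for j in range(counts.tp.shape[1])
    ]
    terms = [t for t in terms if t is not None]
    if not terms:
        raise ValueError("no defined metric terms (all skipped)")
    return float(np.mean(terms))


def weighted_pr(counts: ConfusionCounts, alpha: float,
                zero_division: ZeroDivision = "score") -> float:
    """alpha * mPrecision + (1 - alpha) * mRecall."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * mean_metric(counts, "precision", zero_division) + (
        1.0 - alpha
    ) * mean_metric(counts, "recall", zero_division)


def selection_metric(counts: ConfusionCounts, name: str) -> float:
    """Evaluate one of the eight named model-selection metrics."""
    for key, alpha in SELECTION_METRICS:
        if key == name:
            if alpha is None:
                return mean_metric(counts, "iou")
            return weighted_pr(counts, alpha)
    raise ValueError(f"unknown selection metric {name!r}")


def classification_metrics(pred_labels: Sequence[bool], true_labels: Sequence[bool]) -> dict[str, float]:
    """Binary active/not-active classification scores, as percentages.

    Returns Accuracy, F1 (harmonic mean of precision and recall of the
    active class), Miss-rate (FNR), Fall-out (FPR), Specificity (TNR)
    and Sensitivity (TPR).
    """
    pred = np.asarray(pred_labels, dtype=bool)
    true = np.asarray(true_labels, dtype=bool)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("label vectors must be non-empty and equal length")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    n_pos, n_neg = tp + fn, tn + fp
    tpr = tp / n_pos if n_pos else 1.0
    tnr = tn / n_neg if n_neg else 1.0
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if n_pos == 0 else 0.0)
    f1 = (2 * precision * tpr / (precision + tpr)) if (precision + tpr) > 0 else 0.0
    return {
        "accuracy": 100.0 * (tp + tn) / pred.size,
        "f1": 100.0 * f1,
        "fnr": 100.0 * (1.0 - tpr),
        "fpr": 100.0 * (1.0 - tnr),
        "tnr": 100.0 * tnr,
        "tpr": 100.0 * tpr,
    }


# ---------------------------------------------------------------------------
# Competition ranking of candidate models
# ---------------------------------------------------------------------------

#: Metric -> whether higher values are better.  count_error is ranked
#: and reported but excluded from the mean rank.
RANKED_METRICS: dict[str, bool] = {
    "count_error": False,
    "accuracy": True,
    "f1": True,
    "fnr": False,
    "fpr": False,
    "tnr": True,
    "tpr": True,
}
CLASSIFICATION_RANK_METRICS = ("accuracy", "f1", "fnr", "fpr", "tnr", "tpr")


def competition_rank(values: Sequence[float], higher_is_better: bool) -> np.ndarray:
    """Standard competition ("1224") ranking: ties share the best rank,
    and the next distinct value skips by the tie count."""
    v = np.asarray(values, dtype=float)
    if higher_is_better:
        better = v[:, None] < v[None, :]
    else:
        better = v[:, None] > v[None, :]
    return better.sum(axis=1) + 1


def rank_models(table: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate models across quantification and classification metrics.

    ``table`` is indexed by model name with the columns of
    :data:`RANKED_METRICS`.  Adds ``rank_<metric>`` columns, the mean
    rank over the six classification metrics (rounded to 2 decimals),
    and the final competition rank of the mean rank.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 models to rank")
    missing = [m for m in RANKED_METRICS if m not in table.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    out = table.copy()
    for metric, higher in RANKED_METRICS.items():
        out[f"rank_{metric}"] = competition_rank(table[metric].to_numpy(), higher)
    mean_rank = out[[f"rank_{m}" for m in CLASSIFICATION_RANK_METRICS]].mean(axis=1)
    out["mean_rank"] = mean_rank.round(2)
    out["final_rank"] = competition_rank(out["mean_rank"].to_numpy(), higher_is_better=False)
    return out
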