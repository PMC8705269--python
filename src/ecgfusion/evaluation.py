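"""Metrics and cross-validation aggregation.

Per-class one-vs-rest confusion counts yield accuracy, precision, recall and
F1 (macro-averaged across classes in the multi-class case, zero-denominator
conventions resolve to 0); AUC is the area under the ROC curve, macro
one-vs-rest on softmax scores for more than two classes.  The five
cross-validation splits are summarized as min-max range, mean and population
standard deviation, rendered as "min-max | mean | std" table rows.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclasses.dataclass
class ConfusionCounts:
    """One-vs-rest counts per class; arrays of length n_classes."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_examples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def confusion(predictions: Sequence[int], labels: Sequence[int],
              n_classes: int) -> ConfusionCounts:
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    cm = confusion_matrix(labels, predictions, labels=np.arange(n_classes))
    tp = np.diag(cm).astype(int)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, macro precision/recall/F1 from confusion counts."""
    accuracy = counts.tp.sum() / counts.n_examples
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return {
        "accuracy": float(accuracy),
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }


def roc_auc(scores: np.ndarray, labels: Sequence[int]) -> float:
    """Area under the ROC curve from class scores.

    Binary: the positive-class score column is swept over thresholds.
    Multi-class: unweighted (macro) mean of one-vs-rest AUCs.  Labels from a
    single class make the curve undefined and raise ``ValueError``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC undefined for single-class labels")
    if scores.ndim == 1 or scores.shape[1] == 2:
        pos = scores if scores.ndim == 1 else scores[:, 1]
        return float(roc_auc_score(labels, pos))
    return float(roc_auc_score(labels, scores, multi_class="ovr", average="macro"))


def evaluate_predictions(scores: np.ndarray, labels: Sequence[int],
                         n_classes: int) -> dict[str, float]:
    """All metrics for one run from raw class scores."""
    predictions = np.argmax(scores, axis=1)
    out = metrics(confusion(predictions, labels, n_classes))
    from .nn import softmax

    out["auc"] = roc_auc(softmax(np.asarray(scores, dtype=float)), labels)
    return out


@dataclasses.dataclass
class EvalReport:
    """Per-split metric values with range/mean/std aggregates."""

    per_split: dict[str, list[float]]
    aggregate: dict[str, dict[str, float]]

    def row(self, metric: str, percent: bool = True) -> str:
        agg = self.aggregate[metric]
        scale = 100.0 if percent else 1.0
        return (f"{agg['max'] * scale:.1f}-{agg['min'] * scale:.1f}"
                f"|{agg['mean'] * scale:.1f}|{agg['std'] * scale:.1f}")


def aggregate_cv(per_split_reports: Sequence[Mapping[str, float]]) -> EvalReport:
    """Aggregate per-split metric dicts into range, mean and population std."""
    if not per_split_reports:
        raise ValueError("no reports to aggregate")
    if len(per_split_reports) < 2:
        warnings.warn("fewer than 2 splits: standard deviation reported as 0")
    names = list(per_split_reports[0])
    per_split = {m: [float(r[m]) for r in per_split_reports] for m in names}
    aggregate = {}
    for m, vals in per_split.items():
        arr = np.asarray(vals)
        aggregate[m] = {
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "std": float(arr.std()) if len(arr) > 1 else 0.0,
        }
    return EvalReport(per_split, aggregate)


def format_results_table(rows: Mapping[str, EvalReport],
                         metrics_shown: Sequence[str] = ("accuracy", "f1", "auc")) -> str:
    """Render model-combination rows sorted by descending maximum accuracy."""
    order = sorted(rows, key=lambda k: rows[k].aggregate["accuracy"]["max"],
                   reverse=True)
    header = "Name\t" + "\t".join(
        f"{m.capitalize()}\t{m.capitalize()} Avg|Std" for m in metrics_shown)
    lines = [header]
    for name in order:
        rep = rows[name]
        cells = []
        for m in metrics_shown:
            agg = rep.aggregate[m]
            cells.append(f"{agg['max'] * 100:.1f}-{agg['min'] * 100:.1f}")
            cells.append(f"{agg['mean'] * 100:.1f}|{agg['std'] * 100:.1f}")
        lines.append(name + "\t" + "\t".join(cells))
    return "\n".join(lines)
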