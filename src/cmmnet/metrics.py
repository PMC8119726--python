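"""Segmentation metrics: contingency counts, scalar indices, ROC/PR curves.

All scalar indices derive from the pixel contingency table (TP, FP, TN, FN)
and are reported as percentages:

    SEN = TP/(TP+FN)            SPE = TN/(TN+FP)
    ACC = (TP+TN)/total         DSC = 2TP/(2TP+FP+FN)
    JAC = TP/(TP+FP+FN)         MCC = (TP*TN-FP*FN)/sqrt(prod of marginals)

Degenerate denominators yield 0 with a warning.  An optional region-of-
interest mask (e.g. the fundus field of view) restricts which pixels are
counted.  Curve metrics delegate to scikit-learn.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "ContingencyCounts",
    "contingency",
    "scalar_metrics",
    "roc_pr_curves",
    "aggregate",
    "write_metrics_csv",
    "write_summary_json",
]

METRIC_NAMES = ("SEN", "SPE", "ACC", "DSC", "JAC", "MCC")


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def contingency(pred: np.ndarray, gt: np.ndarray,
                roi: np.ndarray | None = None) -> ContingencyCounts:
    """Exact TP/FP/TN/FN pixel counts, optionally restricted to a ROI."""
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if roi is not None:
        r = np.asarray(roi).astype(bool)
        if r.shape != p.shape:
            raise ValueError("roi shape must match the masks")
        p, g = p[r], g[r]
    return ContingencyCounts(tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
                             tn=int(np.sum(~p & ~g)), fn=int(np.sum(~p & g)))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: degenerate denominator, reporting 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def scalar_metrics(c: ContingencyCounts) -> dict[str, float]:
    """The six scalar indices of a contingency table, in percent."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "SEN": 100.0 * _safe_div(tp, tp + fn, "SEN"),
        "SPE": 100.0 * _safe_div(tn, tn + fp, "SPE"),
        "ACC": 100.0 * _safe_div(tp + tn, c.total, "ACC"),
        "DSC": 100.0 * _safe_div(2 * tp, 2 * tp + fp + fn, "DSC"),
        "JAC": 100.0 * _safe_div(tp, tp + fp + fn, "JAC"),
        "MCC": 100.0 * _safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
    }


def roc_pr_curves(prob: np.ndarray, gt: np.ndarray,
                  roi: np.ndarray | None = None) -> dict:
    """ROC points with trapezoidal AUC, and precision-recall points.

    ``prob`` holds foreground probabilities in [0,1]; arrays of any shape
    (or lists of per-item arrays) are flattened and pooled.
    """
    if isinstance(prob, (list, tuple)):
        scores = np.concatenate([np.asarray(p).ravel() for p in prob])
        labels = np.concatenate([np.asarray(g).ravel() for g in gt])
    else:
        p, g = np.asarray(prob), np.asarray(gt)
        if roi is not None:
            r = np.asarray(roi).astype(bool)
            p, g = p[r], g[r]
        scores, labels = p.ravel(), g.ravel()
    labels = labels.astype(int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if labels.min() == labels.max():
        raise ValueError("ROC/PR curves are undefined for single-class ground truth")
    fpr, tpr, roc_thr = skm.roc_curve(labels, scores)
    precision, recall, pr_thr = skm.precision_recall_curve(labels, scores)
    return {
        "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
        "auc": float(skm.auc(fpr, tpr)),
        "precision": precision, "recall": recall, "pr_thresholds": pr_thr,
    }


def aggregate(per_item_metrics: list[dict[str, float]],
              weights=None) -> dict:
    """Weighted mean of per-item metrics plus the raw per-item distributions.

    ``weights`` are sample sizes (e.g. pixels or slices per test item);
    uniform weights give the plain mean.
    """
    if not per_item_metrics:
        raise ValueError("no metrics to aggregate")
    if weights is None:
        weights = [1.0] * len(per_item_metrics)
    if len(weights) != len(per_item_metrics):
        raise ValueError("weights and metrics must have equal length")
    w = np.asarray(weights, dtype=np.float64)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    keys = per_item_metrics[0].keys()
    summary = {}
    distributions = {}
    for key in keys:
        vals = np.array([m[key] for m in per_item_metrics], dtype=np.float64)
        summary[key] = float(np.sum(w * vals) / w.sum())
        distributions[key] = vals.tolist()
    return {"weighted_mean": summary, "per_item": distributions,
            "weights": w.tolist()}


def write_metrics_csv(path, per_item_metrics, item_ids=None):
    """One CSV row per test item."""
    item_ids = item_ids or [str(i) for i in range(len(per_item_metrics))]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item", *METRIC_NAMES])
        for iid, m in zip(item_ids, per_item_metrics):
            writer.writerow([iid] + [f"{m[k]:.4f}" for k in METRIC_NAMES])


def write_summary_json(path, summary: dict):
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
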