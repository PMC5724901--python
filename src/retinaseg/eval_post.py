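"""Postprocessing of binary vessel masks and FOV-restricted evaluation.

Sensitivity, specificity and accuracy are the usual confusion-table ratios
computed over FOV pixels only; the ROC curve sweeps the classifier margin
over its unique values and the AUC is its trapezoidal area (equivalently
the Mann-Whitney pair statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from sklearn import metrics as skmetrics

__all__ = [
    "EvaluationReport",
    "postprocess",
    "confusion_counts",
    "basic_metrics",
    "roc_auc",
    "evaluate",
]

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class EvaluationReport:
    """FOV-restricted confusion counts, the three ratio metrics and the ROC."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    roc: np.ndarray  # (n, 2) array of (FPR, TPR) points
    auc: float


def postprocess(
    mask: np.ndarray, min_size: int = 30, elongation_min: float = 0.85
) -> np.ndarray:
    """Remove small blob-like false-positive components.

    8-connected components with fewer than ``min_size`` pixels are removed
    unless they are elongated (region eccentricity >= ``elongation_min``)
    and lie within 2 px (Chebyshev) of a surviving component -- i.e. thin
    fragments separated from a vessel by a 2-px classifier gap are
    reattached, isolated blobs are dropped.  Idempotent.
    """
    mask = np.asarray(mask, bool)
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask.copy()
    props = measure.regionprops(labels)
    big = np.zeros(n + 1, dtype=bool)
    for region in props:
        big[region.label] = region.area >= min_size
    kept = big[labels]
    near_kept = ndi.binary_dilation(kept, structure=np.ones((5, 5), bool))
    out = kept.copy()
    for region in props:
        if big[region.label]:
            continue
        if region.eccentricity >= elongation_min:
            component = labels == region.label
            if (component & near_kept).any():
                out |= component
    return out


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, fov: np.ndarray
) -> dict:
    """TP/FP/TN/FN pixel counts inside the FOV."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    fov = np.asarray(fov, bool)
    if not (pred.shape == truth.shape == fov.shape):
        raise ValueError("prediction, truth and FOV shapes must match")
    p, t = pred[fov], truth[fov]
    return {
        "tp": int((p & t).sum()),
        "fp": int((p & ~t).sum()),
        "tn": int((~p & ~t).sum()),
        "fn": int((~p & t).sum()),
    }


def basic_metrics(counts: dict) -> dict:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy
    (TP+TN)/total.  A zero denominator yields NaN (an undefined-metric
    flag), never an exception."""
    tp, fp = counts["tp"], counts["fp"]
    tn, fn = counts["tn"], counts["fn"]

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + fp + tn + fn),
    }


def roc_auc(
    scores: np.ndarray, truth: np.ndarray, fov: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points and AUC from the margin map, FOV-restricted.

    Returns ``(points, auc)`` with points an (n, 2) array of (FPR, TPR).
    Single-class truth inside the FOV yields an empty curve and NaN AUC.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    fov = np.asarray(fov, bool)
    s, t = scores[fov], truth[fov]
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if t.all() or not t.any():
        return np.empty((0, 2)), math.nan
    fpr, tpr, _ = skmetrics.roc_curve(t.astype(int), s)
    return np.column_stack([fpr, tpr]), float(skmetrics.auc(fpr, tpr))


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray,
    fov: np.ndarray,
    scores: np.ndarray | None = None,
) -> EvaluationReport:
    """Full FOV-restricted report; the ROC is computed when a margin map is
    supplied, otherwise from the binary prediction itself."""
    counts = confusion_counts(pred, truth, fov)
    m = basic_metrics(counts)
    score_map = scores if scores is not None else np.asarray(pred, float)
    roc, auc = roc_auc(score_map, truth, fov)
    return EvaluationReport(
        tp=counts["tp"],
        fp=counts["fp"],
        tn=counts["tn"],
        fn=counts["fn"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        roc=roc,
        auc=auc,
    )
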