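"""Classification performance metrics.

The AUC primitive is the normalized Mann-Whitney U statistic (tied scores
count 1/2), which equals the trapezoidal area under the ROC curve. Multiclass
AUC is the unweighted (macro) mean of one-vs-rest binary AUCs — the averaging
convention is stated in every report this package writes. Sensitivity and
specificity are per-class one-vs-rest; undefined ratios are reported as
missing (None), never as 0. Cross-entropy is the mean negative log-probability
of the true class with a 1e-12 probability floor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cohort import ordered_classes
from .errors import DataError

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


def binary_auc(labels, scores) -> float:
    """AUC for binary labels (0/1 or bool) from the rank-sum statistic."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise DataError("labels and scores differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("binary AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_ovr_auc(labels, prob_matrix, classes=None) -> float:
    """Unweighted mean of one-vs-rest binary AUCs over classes present."""
    labels = np.asarray(labels, dtype=object)
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    if classes is None:
        classes = ordered_classes(labels)
    if P.shape != (labels.size, len(classes)):
        raise DataError(f"probability matrix shape {P.shape} does not match "
                        f"{labels.size} subjects x {len(classes)} classes")
    aucs = []
    for j, cls in enumerate(classes):
        mask = labels == cls
        if not mask.any() or mask.all():
            logger.warning("class %s absent from labels (or the only class); "
                           "excluded from macro AUC", cls)
            continue
        aucs.append(binary_auc(mask, P[:, j]))
    if not aucs:
        raise DataError("no class with both positives and negatives")
    return float(np.mean(aucs))


def cross_entropy(labels, prob_matrix, classes=None) -> float:
    """Mean -log p(true class), probabilities floored at 1e-12."""
    labels = np.asarray(labels, dtype=object)
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    if classes is None:
        classes = ordered_classes(labels)
    if P.shape != (labels.size, len(classes)):
        raise DataError("probability matrix shape mismatch")
    if not np.isfinite(P).all() or (P < -1e-9).any():
        raise DataError("malformed probability rows")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise DataError("probability rows must sum to 1")
    idx = {c: j for j, c in enumerate(classes)}
    cols = np.array([idx[c] for c in labels])
    p_true = np.maximum(P[np.arange(labels.size), cols], PROB_FLOOR)
    return float(np.mean(-np.log(p_true)))


def confusion_metrics(labels, predictions, classes=None) -> dict:
    """Accuracy plus per-class one-vs-rest sensitivity and specificity.

    Zero-denominator ratios come back as None (missing), not 0.
    """
    labels = np.asarray(labels, dtype=object)
    predictions = np.asarray(predictions, dtype=object)
    if labels.shape != predictions.shape:
        raise DataError("labels and predictions differ in length")
    if classes is None:
        classes = ordered_classes(labels)
    outside = set(predictions) - set(classes)
    if outside:
        raise DataError(f"predictions outside class set: {sorted(outside)}")

    out = {"accuracy": float(np.mean(labels == predictions)),
           "sensitivity": {}, "specificity": {}}
    for cls in classes:
        pos = labels == cls
        pred_pos = predictions == cls
        tp = int((pos & pred_pos).sum())
        tn = int((~pos & ~pred_pos).sum())
        fn = int((pos & ~pred_pos).sum())
        fp = int((~pos & pred_pos).sum())
        out["sensitivity"][cls] = tp / (tp + fn) if tp + fn else None
        out["specificity"][cls] = tn / (tn + fp) if tn + fp else None
    return out


def roc_points(labels_binary, scores):
    """ROC curve points (FPR, TPR arrays), monotone non-decreasing."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels_binary).astype(int),
                            np.asarray(scores, dtype=float))
    return fpr, tpr


@dataclass
class MetricReport:
    """All reported performance metrics for one evaluation.

    `auc` is the macro one-vs-rest AUC (convention stated in `auc_convention`).
    """

    auc: float
    accuracy: float
    sensitivity: dict
    specificity: dict
    cross_entropy: float
    roc_curves: dict = field(default_factory=dict)  # class -> (fpr, tpr) lists
    auc_convention: str = "macro one-vs-rest"

    def to_json(self) -> str:
        payload = {
            "auc_convention": self.auc_convention,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cross_entropy": self.cross_entropy,
            "roc_curves": {c: {"fpr": list(map(float, f)),
                               "tpr": list(map(float, t))}
                           for c, (f, t) in self.roc_curves.items()},
        }
        return json.dumps(payload, indent=2)


def evaluate_predictions(labels, predictions, prob_matrix,
                         classes=None) -> MetricReport:
    """Assemble the full metric report from hard and soft predictions."""
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = ordered_classes(labels)
    conf = confusion_metrics(labels, predictions, classes)
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    curves = {}
    for j, cls in enumerate(classes):
        mask = labels == cls
        if mask.any() and not mask.all():
            fpr, tpr = roc_points(mask, P[:, j])
            curves[cls] = (fpr, tpr)
    return MetricReport(
        auc=macro_ovr_auc(labels, P, classes),
        accuracy=conf["accuracy"],
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        cross_entropy=cross_entropy(labels, P, classes),
        roc_curves=curves,
    )
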