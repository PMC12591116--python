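"""Weighted-voting ensemble over learned embeddings.

Three base classifiers — random forest, RBF-kernel SVM with probability
outputs, and gradient-boosted trees — are fitted on embedding features for
one of three modality configurations (mri_only / snp_only / combined). The
final prediction is

    y_hat = argmax_c  sum_k w_k 1(p_k = c)

with non-negative voting weights w_k summing to one; ties are broken by the
highest weighted mean predicted probability among the tied classes, then by
declared class order. Weights default to validation-accuracy-proportional,
with a uniform scheme behind a flag.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cohort import CohortTable, ordered_classes
from .errors import DataError, UsageError
from .train import AlignmentModel

logger = logging.getLogger(__name__)

MODALITIES = ("mri_only", "snp_only", "combined")

#: documented, seed-pinned base-model settings
RF_TREES = 500
XGB_ROUNDS = 300
XGB_DEPTH = 4


@dataclass
class EnsembleModel:
    """Fitted base classifiers plus their voting weights."""

    models: list                 # fitted sklearn-style classifiers
    names: list[str]
    weights: np.ndarray          # (K,), non-negative, sums to 1
    classes: tuple[str, ...]     # declared class order (canonical)
    modality: str

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.models) < 1:
            raise UsageError("ensemble needs at least one base model")
        if self.weights.shape != (len(self.models),) or np.any(self.weights < 0):
            raise UsageError("weights must be one non-negative value per model")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise UsageError("weights must sum to 1")


def embed_features(model: AlignmentModel, cohort: CohortTable,
                   modality: str) -> np.ndarray:
    """Embedding feature matrix for one modality configuration (eval mode).

    snp_only and combined use the SNP-side embeddings with the diagnosis
    slots zeroed, so no label information can leak into the features.
    """
    if modality not in MODALITIES:
        raise UsageError(f"modality must be one of {MODALITIES}, got {modality!r}")
    if not model.trained:
        raise UsageError("alignment model has not been trained")
    if modality == "mri_only":
        return model.encode_image(cohort.imaging)
    if modality == "snp_only":
        return model.encode_snp(cohort.genotypes, labels=None)
    return np.hstack([model.encode_image(cohort.imaging),
                      model.encode_snp(cohort.genotypes, labels=None)])


def _base_models(seed: int):
    rf = RandomForestClassifier(n_estimators=RF_TREES, random_state=seed)
    # RBF support-vector machine with Platt-scaled probability outputs
    svm = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                 ensemble=False, cv=3)
    xgb = XGBClassifier(n_estimators=XGB_ROUNDS, max_depth=XGB_DEPTH,
                        learning_rate=0.1, random_state=seed,
                        verbosity=0, n_jobs=1)
    return [rf, svm, xgb], ["random_forest", "svm", "xgboost"]


def fit_ensemble(X: np.ndarray, y, weight_scheme: str = "accuracy",
                 seed: int = 0, X_val=None, y_val=None,
                 modality: str = "combined") -> EnsembleModel:
    """Fit the three base classifiers and set voting weights.

    weight_scheme "uniform": w_k = 1/K. "accuracy": w_k proportional to
    held-out accuracy, computed on (X_val, y_val) when given, otherwise on an
    internal stratified 20% carve-out of the training data (seeded).
    Labels are strings in canonical class order; xgboost sees integer codes.
    """
    if weight_scheme not in ("uniform", "accuracy"):
        raise UsageError(f"unknown weight scheme {weight_scheme!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = ordered_classes(y)
    if len(classes) < 2:
        raise DataError(f"need >= 2 classes to fit a classifier, got {classes}")

    code = {c: i for i, c in enumerate(classes)}
    y_int = np.array([code[c] for c in y])

    if weight_scheme == "accuracy" and X_val is None:
        X, X_val, y_int, yv_int = train_test_split(
            X, y_int, test_size=0.2, random_state=seed, stratify=y_int)
    elif X_val is not None:
        yv = np.asarray(y_val, dtype=object)
        unknown = set(yv) - set(classes)
        if unknown:
            raise DataError(f"validation labels outside training classes: {unknown}")
        yv_int = np.array([code[c] for c in yv])

    models, names = _base_models(seed)
    for m in models:
        if not hasattr(m, "predict_proba"):
            raise UsageError(f"base model {m} lacks probability output")
        m.fit(X, y_int)

    if weight_scheme == "uniform":
        weights = np.full(len(models), 1.0 / len(models))
    else:
        accs = np.array([np.mean(m.predict(X_val) == yv_int) for m in models])
        if accs.sum() <= 0:
            logger.warning("all validation accuracies are 0; falling back to "
                           "uniform weights")
            weights = np.full(len(models), 1.0 / len(models))
        else:
            weights = accs / accs.sum()
    return EnsembleModel(models=models, names=names, weights=weights,
                         classes=classes, modality=modality)


def vote(predictions, weights, classes, tie_break_probs=None) -> str:
    """Weighted hard vote over one subject's base-model predictions.

    Ties on the weighted vote are broken by the highest weighted mean
    predicted probability among the tied classes (when probabilities are
    given), then by declared class order — fully deterministic.
    """
    classes = tuple(classes)
    weights = np.asarray(weights, dtype=float)
    predictions = list(predictions)
    if len(predictions) != weights.size:
        raise UsageError("one weight per prediction required")
    for p in predictions:
        if p not in classes:
            raise DataError(f"prediction {p!r} outside declared class set {classes}")
    score = np.zeros(len(classes))
    for p, w in zip(predictions, weights):
        score[classes.index(p)] += w
    best = np.flatnonzero(np.isclose(score, score.max(), rtol=0.0, atol=1e-12))
    if best.size == 1:
        return classes[best[0]]
    if tie_break_probs is not None:
        probs = np.asarray(tie_break_probs, dtype=float)  # (K, C)
        mean_p = weights @ probs
        tied = mean_p[best]
        best = best[np.flatnonzero(np.isclose(tied, tied.max(),
                                              rtol=0.0, atol=1e-12))]
    return classes[best[0]]  # earliest declared class among remaining ties


def _base_probs(model: EnsembleModel, X) -> np.ndarray:
    """(K, B, C) probability tensor in declared class order."""
    X = np.asarray(X, dtype=float)
    out = np.zeros((len(model.models), X.shape[0], len(model.classes)))
    for k, m in enumerate(model.models):
        P = m.predict_proba(X)
        for j, ci in enumerate(m.classes_):   # ci is the integer class code
            out[k, :, int(ci)] = P[:, j]
    return out


def predict_proba_ensemble(model: EnsembleModel, X) -> np.ndarray:
    """Weighted average of base-model probabilities; rows sum to 1."""
    probs = _base_probs(model, X)
    P = np.einsum("k,kbc->bc", model.weights, probs)
    # base models may emit float32 rows that sum to 1 only approximately
    return P / P.sum(axis=1, keepdims=True)


def predict_ensemble(model: EnsembleModel, X) -> np.ndarray:
    """Weighted-vote class per row (ties broken by probabilities)."""
    X = np.asarray(X, dtype=float)
    probs = _base_probs(model, X)
    hard = [[model.classes[int(c)] for c in m.predict(X)] for m in model.models]
    out = np.empty(X.shape[0], dtype=object)
    for b in range(X.shape[0]):
        out[b] = vote([hard[k][b] for k in range(len(model.models))],
                      model.weights, model.classes,
                      tie_break_probs=probs[:, b, :])
    return out


def save_ensemble(model: EnsembleModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_ensemble(path) -> EnsembleModel:
    try:
        with open(path, "rb") as fh:
            model = pickle.load(fh)
    except Exception as exc:
        raise DataError(f"cannot load ensemble from {path}: {exc}") from exc
    if not isinstance(model, EnsembleModel):
        raise DataError(f"{path} does not contain an EnsembleModel")
    return model
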