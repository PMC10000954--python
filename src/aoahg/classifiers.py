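"""Classifier back-ends and the benchmark metric set.

Four seeded back-ends are supported, named by short labels:

=======  =================================================
label    model
=======  =================================================
svm      RBF-kernel support vector machine, C = 1
knn      k-nearest neighbours, k = 5
rf       random forest, 100 trees
xgb      gradient-boosted trees (xgboost defaults)
=======  =================================================

Metrics follow the benchmark-table convention: accuracy, balanced accuracy
(mean per-class recall), and support-weighted precision/recall/F1 so a
single number summarises multiclass problems; macro averaging is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    precision_recall_fscore_support,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

CLASSIFIER_LABELS = ("svm", "knn", "rf", "xgb")

__all__ = ["CLASSIFIER_LABELS", "MetricsReport", "train_and_predict", "compute_metrics"]


@dataclass
class MetricsReport:
    """Fractional scores in [0, 1] plus wall-clock seconds, if timed."""

    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    elapsed: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _build_classifier(classifier_spec: str, seed: int):
    if classifier_spec == "svm":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if classifier_spec == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if classifier_spec == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if classifier_spec == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    raise ValueError(
        f"unknown classifier {classifier_spec!r}; choose from {CLASSIFIER_LABELS}"
    )


def train_and_predict(
    classifier_spec: str,
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_eval: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit the named classifier and return one predicted label per eval row.

    Deterministic given ``seed``.  Labels are re-encoded to a contiguous
    0..C-1 range internally (gradient-boosted trees require it) and decoded
    back before returning.
    """
    X_fit = np.asarray(X_fit, dtype=float)
    X_eval = np.asarray(X_eval, dtype=float)
    y_fit = np.asarray(y_fit)
    if X_fit.size == 0 or X_fit.shape[0] == 0:
        raise ValueError("empty training matrix")
    classes = np.unique(y_fit)
    if classes.size < 2:
        raise ValueError("training labels must contain at least two classes")
    if X_eval.shape[1] != X_fit.shape[1]:
        raise ValueError(
            f"column mismatch: fit has {X_fit.shape[1]}, eval has {X_eval.shape[1]}"
        )
    clf = _build_classifier(classifier_spec, seed)
    codes = np.searchsorted(classes, y_fit)
    clf.fit(X_fit, codes)
    return classes[clf.predict(X_eval)]


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, average: str = "weighted"
) -> MetricsReport:
    """Accuracy, balanced accuracy and averaged precision/recall/F1.

    ``average`` is "weighted" (class-support weights, the default used in
    the benchmark tables) or "macro".  Classes never predicted contribute
    zero precision rather than raising.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("need at least one label")
    if average not in ("weighted", "macro"):
        raise ValueError("average must be 'weighted' or 'macro'")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=average, zero_division=0
    )
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
        precision=float(p),
        recall=float(r),
        f1=float(f1),
    )
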