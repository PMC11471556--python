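"""Shallow neural-network classifier family and evaluation metrics.

Presets follow the reference family: the shallow wide network (SWNN) with one
ten-neuron fully-connected hidden layer, the medium network MN2 (25), the
narrow network N3 (100), and the bi-/tri-layered networks BiN2 / TiN2 (two
and three hidden layers of 100).  Classifiers are trained full-batch (L-BFGS)
with seeded initialization; evaluation pools out-of-fold predictions from a
stratified k-fold (default 10) into one confusion matrix, from which TPR,
PPV, F1, FPR (macro-averaged over classes), accuracy and a one-vs-rest macro
AUC are computed.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .training import FeatureMatrix

__all__ = [
    "PRESETS",
    "EvalReport",
    "build_classifier",
    "fit_predict_cv",
    "metrics_from_confusion",
]

# hidden-layer layouts of the shallow classifier family
PRESETS: dict[str, list[int]] = {
    "SWNN": [10],
    "MN2": [25],
    "N3": [100],
    "BiN2": [100, 100],
    "TiN2": [100, 100, 100],
}


@dataclass
class EvalReport:
    confusion: np.ndarray
    tpr_per_class: np.ndarray
    tpr: float
    ppv: float
    f1: float
    fpr: float
    accuracy: float
    auc: float | None = None
    time_sec: float | None = None  # informational only; hardware-dependent

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "tpr_per_class": self.tpr_per_class.tolist(),
            "tpr": self.tpr,
            "ppv": self.ppv,
            "f1": self.f1,
            "fpr": self.fpr,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "time_sec": self.time_sec,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_table(self) -> str:
        """One-row table mirroring the reference result layout."""
        auc = f"{self.auc:.4f}" if self.auc is not None else "n/a"
        t = f"{self.time_sec:.3f}" if self.time_sec is not None else "n/a"
        head = f"{'TPR (%)':>9}{'PPV (%)':>9}{'F1 (%)':>9}{'FPR':>9}{'AUC':>9}{'ACC (%)':>9}{'Time (s)':>10}"
        row = (
            f"{100 * self.tpr:>9.2f}{100 * self.ppv:>9.2f}{100 * self.f1:>9.2f}"
            f"{self.fpr:>9.4f}{auc:>9}{100 * self.accuracy:>9.2f}{t:>10}"
        )
        return head + "\n" + row


def build_classifier(
    preset: str, input_width: int, classes: int, seed: int = 0
) -> MLPClassifier:
    """Fully-connected network with the preset's hidden layout and ReLU units."""
    if input_width < 1:
        raise ValueError("input_width must be >= 1")
    if classes < 2:
        raise ValueError("classes must be >= 2")
    layout = None
    for name, widths in PRESETS.items():
        if name.lower() == preset.lower():
            layout = widths
    if layout is None:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return MLPClassifier(
        hidden_layer_sizes=tuple(layout),
        activation="relu",
        solver="lbfgs",
        max_iter=1000,
        tol=1e-6,
        random_state=seed,
    )


def metrics_from_confusion(confusion: np.ndarray) -> EvalReport:
    """Macro metrics from a K x K confusion matrix (rows = truth, cols = prediction).

    Per class: TPR = diag / row sum, PPV = diag / column sum, F1 their
    harmonic mean, FPR = off-diagonal column mass / negatives.  Macro values
    are unweighted class means; a zero denominator contributes 0 with a
    warning.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
        raise ValueError("confusion entries must be non-negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    diag = np.diag(c).astype(float)
    row = c.sum(axis=1).astype(float)
    col = c.sum(axis=0).astype(float)

    def safe(num, den, what):
        if np.any(den == 0):
            warnings.warn(f"zero denominator in {what}; affected classes contribute 0")
        return np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den > 0)

    tpr = safe(diag, row, "TPR")
    ppv = safe(diag, col, "PPV")
    f1 = safe(2 * tpr * ppv, tpr + ppv, "F1")
    fpr = safe(col - diag, total - row, "FPR")
    return EvalReport(
        confusion=c,
        tpr_per_class=tpr,
        tpr=float(tpr.mean()),
        ppv=float(ppv.mean()),
        f1=float(f1.mean()),
        fpr=float(fpr.mean()),
        accuracy=float(diag.sum() / total),
    )


def fit_predict_cv(
    features: FeatureMatrix,
    preset: str = "SWNN",
    folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    ``folds == N`` falls back to leave-one-out.  Every class must have at
    least ``folds`` members for stratification; the offending class is named
    otherwise.
    """
    x, y = features.values, features.labels
    n = features.n
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    classes = np.unique(y)
    if folds == n:
        splitter = LeaveOneOut()
    else:
        for cls in classes:
            if (y == cls).sum() < folds:
                raise ValueError(f"class {cls} has fewer than {folds} members")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    pred = np.empty(n, dtype=int)
    proba = np.zeros((n, len(classes)))
    start = time.perf_counter()
    for train_idx, test_idx in splitter.split(x, y):
        clf = build_classifier(preset, x.shape[1], len(classes), seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lbfgs convergence chatter
            clf.fit(x[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(x[test_idx])
        p = clf.predict_proba(x[test_idx])
        for j, cls in enumerate(clf.classes_):
            proba[test_idx, np.searchsorted(classes, cls)] = p[:, j]
    elapsed = time.perf_counter() - start

    conf = confusion_matrix(y, pred, labels=classes)
    report = metrics_from_confusion(conf)
    report.time_sec = elapsed
    try:
        if len(classes) == 2:
            report.auc = float(roc_auc_score(y, proba[:, 1]))
        else:
            report.auc = float(
                roc_auc_score(y, proba, multi_class="ovr", average="macro", labels=classes)
            )
    except ValueError:
        report.auc = None
    return report
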