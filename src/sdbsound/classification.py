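"""Severity classification under stratified 10-fold cross-validation.

Three classifier kinds are supported: L2-regularized multinomial logistic
regression (functional stand-in for Weka's "simple logistics"), a linear
SVM (polynomial kernel of exponent 1.0, C = 1.0), and a small feed-forward
network with 50/25 ReLU hidden layers and 20% dropout. Binary tasks cut
the roster at an AHI threshold of 5, 15 or 30.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("logistic", "svm", "mlp")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus its (serializable) hyperparameters."""

    kind: str = "logistic"
    C: float = 1.0
    hidden: tuple[int, int] = (50, 25)
    dropout: float = 0.2
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "C": self.C,
            "hidden": list(self.hidden),
            "dropout": self.dropout,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
        }


@dataclass
class EvaluationReport:
    """Pooled cross-validation outcome."""

    classes: list
    confusion: np.ndarray
    accuracy: float
    sensitivity: dict
    specificity: dict
    auc: dict
    macro_auc: float | None
    fold_assignments: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
            "auc": {str(k): v for k, v in self.auc.items()},
            "macro_auc": self.macro_auc,
            "fold_assignments": self.fold_assignments.tolist(),
            "seed": self.seed,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def make_binary_labels(ahi: Sequence[float] | pd.Series, threshold: float) -> np.ndarray:
    """Label 1 iff AHI >= threshold, else 0 (thresholds 5/15/30 are the group cuts)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ahi = np.asarray(ahi, dtype=np.float64)
    return (ahi >= threshold).astype(np.int64)


class DropoutMLP:
    """Minimal feed-forward softmax classifier with inverted dropout.

    Two ReLU hidden layers, dropout after each hidden layer, Adam updates,
    early stop on a training-loss plateau; fully deterministic for a fixed
    seed.
    """

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.classes_: np.ndarray | None = None

    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator):
        sizes = [n_in, *self.spec.hidden, n_out]
        self._W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self._b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X, rng=None):
        acts = [X]
        h = X
        masks = []
        for i, (W, b) in enumerate(zip(self._W, self._b)):
            z = h @ W + b
            if i < len(self._W) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and self.spec.dropout > 0:
                    keep = 1.0 - self.spec.dropout
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                z -= z.max(axis=1, keepdims=True)
                expz = np.exp(z)
                probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, acts, masks

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DropoutMLP":
        X = np.asarray(X, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = self.classes_.size
        rng = np.random.default_rng(self.seed)
        self._init_params(d, k, rng)
        onehot = np.eye(k)[y_idx]
        m = [np.zeros_like(w) for w in self._W + self._b]
        v = [np.zeros_like(w) for w in self._W + self._b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss, stall = np.inf, 0
        for _epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.spec.batch_size):
                idx = order[start : start + self.spec.batch_size]
                xb, yb = X[idx], onehot[idx]
                probs, acts, masks = self._forward(xb, rng)
                epoch_loss -= float(
                    np.sum(yb * np.log(np.clip(probs, 1e-12, None)))
                )
                delta = (probs - yb) / idx.size
                grads_W, grads_b = [], []
                for i in range(len(self._W) - 1, -1, -1):
                    grads_W.append(acts[i].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if i > 0:
                        delta = delta @ self._W[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                grads = list(reversed(grads_W)) + list(reversed(grads_b))
                params = self._W + self._b
                t += 1
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g**2
                    m_hat = m[j] / (1 - beta1**t)
                    v_hat = v[j] / (1 - beta2**t)
                    p -= self.spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            if epoch_loss < best_loss - 1e-5:
                best_loss, stall = epoch_loss, 0
            else:
                stall += 1
                if stall >= 20:
                    break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _, _ = self._forward(np.asarray(X, dtype=np.float64))
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit the requested classifier; the result exposes predict/predict_proba."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    if spec.kind == "logistic":
        model = LogisticRegression(C=spec.C, max_iter=5000, random_state=seed)
    elif spec.kind == "svm":
        # polynomial kernel with exponent 1.0 == linear kernel
        model = SVC(kernel="linear", C=spec.C, probability=True, random_state=seed)
    else:
        model = DropoutMLP(spec, seed=seed)
    return model.fit(X, y)


def compute_metrics(
    confusion: np.ndarray,
    classes: Sequence,
    y_true: np.ndarray | None = None,
    scores: np.ndarray | None = None,
):
    """Accuracy, one-vs-rest sensitivity/specificity, and rank-based ROC areas.

    A class with no positive (or no negative) subjects reports its undefined
    rate as ``None`` rather than 0.
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)
    sensitivity: dict = {}
    specificity: dict = {}
    auc: dict = {}
    for i, cls in enumerate(classes):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        sensitivity[cls] = float(tp / (tp + fn)) if (tp + fn) > 0 else None
        specificity[cls] = float(tn / (tn + fp)) if (tn + fp) > 0 else None
        if y_true is not None and scores is not None:
            pos = np.asarray(y_true) == cls
            if pos.any() and (~pos).any():
                auc[cls] = float(roc_auc_score(pos.astype(int), scores[:, i]))
            else:
                auc[cls] = None
    defined = [v for v in auc.values() if v is not None]
    macro_auc = float(np.mean(defined)) if defined else None
    return accuracy, sensitivity, specificity, auc, macro_auc


def crossval_evaluate(
    table: pd.DataFrame,
    labels: Sequence,
    spec: ClassifierSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    selector: Callable[[pd.DataFrame, np.ndarray], Sequence[str]] | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled predictions.

    Features are standardized with training-fold statistics only. Feature
    selection is either fixed upfront (``feature_names``, mirroring a
    once-on-all-subjects selection) or refit inside each training fold
    (``selector`` called with the fold's table and labels) to avoid leakage.
    """
    spec = spec or ClassifierSpec()
    labels = np.asarray(labels)
    if feature_names is not None and selector is not None:
        raise ValueError("pass either feature_names or selector, not both")
    classes, counts = np.unique(labels, return_counts=True)
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n = len(table)
    predictions = np.empty(n, dtype=classes.dtype)
    scores = np.zeros((n, classes.size))
    fold_assignments = np.empty(n, dtype=np.int64)
    for fold, (train_idx, test_idx) in enumerate(skf.split(table, labels)):
        fold_assignments[test_idx] = fold
        train_table = table.iloc[train_idx]
        if selector is not None:
            chosen = list(selector(train_table, labels[train_idx])) or list(table.columns)
        elif feature_names is not None:
            chosen = list(feature_names)
        else:
            chosen = list(table.columns)
        scaler = StandardScaler().fit(train_table[chosen].to_numpy(dtype=np.float64))
        x_train = scaler.transform(train_table[chosen].to_numpy(dtype=np.float64))
        x_test = scaler.transform(table.iloc[test_idx][chosen].to_numpy(dtype=np.float64))
        model = train_classifier(spec, x_train, labels[train_idx], seed=seed + fold)
        predictions[test_idx] = model.predict(x_test)
        proba = model.predict_proba(x_test)
        model_classes = list(getattr(model, "classes_"))
        for j, cls in enumerate(classes):
            scores[test_idx, j] = proba[:, model_classes.index(cls)]
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    for t, p in zip(labels, predictions):
        confusion[cls_index[t], cls_index[p]] += 1
    accuracy, sens, spec_, auc, macro_auc = compute_metrics(
        confusion, list(classes), labels, scores
    )
    return EvaluationReport(
        classes=list(classes),
        confusion=confusion,
        accuracy=accuracy,
        sensitivity=sens,
        specificity=spec_,
        auc=auc,
        macro_auc=macro_auc,
        fold_assignments=fold_assignments,
        seed=seed,
    )
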