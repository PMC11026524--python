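"""Per-motif logistic models mapping a feature vector to a read-level m6A probability.

The model is a single linear logistic layer per motif,

    P(m6A) = sigmoid(w . x + b),

applied to a feature vector ``x`` that has been normalized by its maximum
absolute value. Training minimizes the (sum-form) binary cross-entropy with
labels y=0 for unmodified (UNM) and y=1 for modified (MOD) reads; class
imbalance is removed beforehand by randomly subsampling the larger class.

``MotifLogisticClassifier`` is a scikit-learn estimator; the module-level
functions (:func:`normalize_features`, :func:`balance_classes`,
:func:`train_motif_model`, :func:`cross_validate_auc`) are the functional
surface used by the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted, validate_data

from .motifs import SUPPORTED_MOTIFS, normalize_motif

__all__ = [
    "normalize_features",
    "sigmoid",
    "log_loss_binary",
    "balance_classes",
    "MotifLogisticClassifier",
    "MotifModel",
    "ModelBundle",
    "train_motif_model",
    "pr_auc_score",
    "CVResult",
    "cross_validate_auc",
    "BUNDLE_FORMAT_VERSION",
]

BUNDLE_FORMAT_VERSION = 1

#: clipping bound for log arguments in the loss; probabilities reported by
#: the model itself are never clipped.
LOSS_EPS = 1e-12


def sigmoid(z):
    """Numerically stable logistic function."""
    return expit(z)


def normalize_features(X):
    """Normalize each feature vector by its maximum absolute value.

    Accepts a single vector or a 2-D array of row vectors. All-zero vectors
    are returned unchanged; non-finite entries are rejected. The operation is
    idempotent: after normalization the largest absolute entry of each
    non-zero row is exactly 1.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature vectors must contain only finite values")
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    scale = np.max(np.abs(X2), axis=1, keepdims=True)
    scale = np.where(scale == 0.0, 1.0, scale)
    out = X2 / scale
    return out[0] if single else out


def log_loss_binary(y, p, eps: float = LOSS_EPS) -> float:
    """Sum-form binary cross-entropy, -sum[y ln p + (1-y) ln(1-p)].

    Probabilities are clipped to [eps, 1-eps] so the loss is finite at
    p in {0, 1}.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    if y.size == 0:
        raise ValueError("log loss of an empty batch is undefined")
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def balance_classes(X, y, seed: int = 0, motif: str | None = None):
    """Subsample the more numerous class to match the smaller one.

    Returns ``(X_bal, y_bal, kept_idx)`` where ``kept_idx`` indexes into the
    input arrays (sorted ascending, so an already balanced batch is returned
    with its membership unchanged). Both classes must be present.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        where = f" for motif {motif}" if motif else ""
        raise ValueError(
            f"cannot balance classes{where}: need both UNM (y=0) and MOD (y=1) samples"
        )
    rng = np.random.default_rng(seed)
    n = min(idx0.size, idx1.size)
    if idx0.size > n:
        idx0 = rng.choice(idx0, size=n, replace=False)
    if idx1.size > n:
        idx1 = rng.choice(idx1, size=n, replace=False)
    kept = np.sort(np.concatenate([idx0, idx1]))
    return X[kept], y[kept], kept


class MotifLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Linear logistic read-level m6A classifier for one motif.

    Parameters
    ----------
    motif : str or None
        Canonical 5-mer this model is trained for (bookkeeping only; the fit
        itself is motif-agnostic).
    alpha : float
        Ridge penalty strength. The default 0 trains the plain unpenalized
        cross-entropy; a positive value maps to sklearn's ``C = 1/alpha``.
    tol, max_iter : float, int
        L-BFGS stopping tolerance and iteration cap.
    normalize : bool
        If True (default), apply per-vector max-abs normalization inside
        both ``fit`` and ``predict``.
    random_state : int or None
        Passed to the solver for reproducibility.

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
    intercept_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        motif: str | None = None,
        alpha: float = 0.0,
        tol: float = 1e-4,
        max_iter: int = 1000,
        normalize: bool = True,
        random_state: int | None = None,
    ):
        self.motif = motif
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all() or classes.size != 2:
            raise ValueError("labels must contain both classes, coded 0 (UNM) and 1 (MOD)")
        if self.normalize:
            X = normalize_features(X)
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.alpha == 0:
            lr = LogisticRegression(
                penalty=None,
                solver="lbfgs",
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=self.random_state,
            )
        else:
            lr = LogisticRegression(
                penalty="l2",
                C=1.0 / self.alpha,
                solver="lbfgs",
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=self.random_state,
            )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            lr.fit(X, y)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        if not converged:
            warnings.warn(
                f"logistic fit for motif {self.motif} did not converge "
                f"within {self.max_iter} iterations",
                ConvergenceWarning,
                stacklevel=2,
            )
        self.classes_ = lr.classes_
        self.weights_ = lr.coef_.ravel().copy()
        self.coef_ = lr.coef_.copy()
        self.intercept_ = float(lr.intercept_[0])
        self.n_iter_ = int(np.ravel(lr.n_iter_)[0])
        self.converged_ = converged
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if self.normalize:
            X = normalize_features(X)
        return X @ self.weights_ + self.intercept_

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict_m6a(self, X):
        """P(m6A) for each row of ``X`` — the positive-class probability."""
        return sigmoid(self.decision_function(X))

    def predict(self, X):
        return (self.predict_m6a(X) >= 0.5).astype(int)

    def to_model(self) -> "MotifModel":
        check_is_fitted(self)
        return MotifModel(
            motif=self.motif,
            weights=self.weights_.copy(),
            bias=self.intercept_,
            meta={
                "converged": self.converged_,
                "n_iter": self.n_iter_,
                "alpha": self.alpha,
            },
        )


@dataclass
class MotifModel:
    """Frozen weights of one motif's logistic layer: P(m6A) = sigmoid(w.x + b)."""

    motif: str
    weights: np.ndarray
    bias: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)

    @property
    def n_features(self) -> int:
        return self.weights.size

    def predict(self, X, normalize: bool = True):
        """Read-level P(m6A) for row vectors ``X``."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X2.shape[1]} does not match model for "
                f"{self.motif} (expected {self.n_features})"
            )
        if normalize:
            X2 = normalize_features(X2)
        p = sigmoid(X2 @ self.weights + self.bias)
        return float(p[0]) if single else p

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotifModel":
        return cls(
            motif=d["motif"],
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            meta=dict(d.get("meta", {})),
        )


class ModelBundle:
    """Collection of per-motif models; a full bundle holds exactly six.

    Prediction through the bundle dispatches on the (canonicalized) motif of
    each call; requesting a motif without a model is an error that names the
    missing motif.
    """

    def __init__(self, models: Iterable[MotifModel] = ()):
        self._models: dict[str, MotifModel] = {}
        for m in models:
            self.add(m)

    def add(self, model: MotifModel) -> None:
        canon = normalize_motif(model.motif)
        model.motif = canon
        self._models[canon] = model

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(sorted(self._models))

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, motif: str) -> bool:
        return normalize_motif(motif) in self._models

    def __getitem__(self, motif: str) -> MotifModel:
        canon = normalize_motif(motif)
        if canon not in self._models:
            raise KeyError(
                f"bundle has no model for motif {canon}; available: "
                + (", ".join(self.motifs) or "none")
            )
        return self._models[canon]

    def is_complete(self) -> bool:
        """True iff the bundle holds one model per supported motif."""
        return set(self._models) == set(SUPPORTED_MOTIFS)

    def predict(self, X, motif: str):
        return self[motif].predict(X)

    def to_dict(self) -> dict:
        return {
            "format_version": BUNDLE_FORMAT_VERSION,
            "models": {m: self._models[m].to_dict() for m in self.motifs},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelBundle":
        bundle = cls()
        for md in d["models"].values():
            bundle.add(MotifModel.from_dict(md))
        return bundle

    @classmethod
    def load_json(cls, path) -> "ModelBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_motif_model(
    X,
    y,
    motif: str,
    alpha: float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int | None = None,
) -> MotifModel:
    """Fit one motif's logistic layer on a (balanced) labelled batch."""
    canon = normalize_motif(motif)
    est = MotifLogisticClassifier(
        motif=canon, alpha=alpha, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X, y)
    model = est.to_model()
    y = np.asarray(y).astype(int)
    model.meta.update(
        {"n_unm": int(np.sum(y == 0)), "n_mod": int(np.sum(y == 1)), "seed": seed}
    )
    return model


def pr_auc_score(y_true, scores) -> float:
    """Precision-recall AUC by step-wise average precision."""
    y_true = np.asarray(y_true).astype(int)
    if np.unique(y_true).size < 2:
        raise ValueError("PR-AUC requires both classes to be present")
    return float(average_precision_score(y_true, scores))


@dataclass
class CVResult:
    """Per-fold validation AUCs of a k-fold cross-validation."""

    fold_aucs: list[float]
    mean_auc: float
    half_range: float
    n_folds_skipped: int = 0


def cross_validate_auc(
    X,
    y,
    k: int = 4,
    seed: int = 0,
    metric: str = "pr",
    **model_params,
) -> CVResult:
    """k-fold cross-validated read-level AUC for one motif's samples.

    Samples are shuffled once with ``seed`` and split into ``k`` contiguous
    blocks; each block serves as the validation 1/k in turn (the default
    k=4 reproduces a resampled 75/25 train-validation design). Folds whose
    train or validation part lacks a class are skipped with a warning.
    Returns the fold AUCs (PR-AUC by default, ``metric="roc"`` for ROC-AUC),
    their mean, and their half-range (max-min)/2.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    blocks = np.array_split(order, k)
    aucs: list[float] = []
    skipped = 0
    for i, val_idx in enumerate(blocks):
        train_idx = np.concatenate([b for j, b in enumerate(blocks) if j != i])
        y_tr, y_va = y[train_idx], y[val_idx]
        if np.unique(y_tr).size < 2 or np.unique(y_va).size < 2:
            warnings.warn(f"fold {i} skipped: a class is absent", stacklevel=2)
            skipped += 1
            continue
        est = MotifLogisticClassifier(random_state=seed, **model_params)
        est.fit(X[train_idx], y_tr)
        p = est.predict_m6a(X[val_idx])
        if metric == "pr":
            aucs.append(pr_auc_score(y_va, p))
        elif metric == "roc":
            aucs.append(float(roc_auc_score(y_va, p)))
        else:
            raise ValueError("metric must be 'pr' or 'roc'")
    if not aucs:
        raise ValueError("no usable folds")
    return CVResult(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        half_range=float((max(aucs) - min(aucs)) / 2.0),
        n_folds_skipped=skipped,
    )
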