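"""Gesture classifiers: scatter-matrix LDA and a probabilistic neural network.

Both are implemented from first principles — they are the modelling
core of the benchmark, not wrappers.

**LDA.** The within-class scatter ``Sw = sum_i sum_{x in X_i}
(x - mu_i)(x - mu_i)^T`` and between-class scatter ``Sb = sum_i m_i
(mu_i - mu)(mu_i - mu)^T`` define the generalized eigenproblem
``Sb w = lambda Sw w``; the projection ``W`` stacks the eigenvectors of
the d' largest eigenvalues (d' <= n_classes - 1). Test rows are
projected and assigned to the nearest projected class mean.

**PNN.** A kernel classifier: the radial layer stores every training
row as an exemplar; a query's Euclidean distances to the exemplars are
scaled by the polarization factor ``b = 0.8326 / sigma`` (so a query at
distance sigma activates 0.5) and passed through ``exp(-(d*b)^2)``; the
competition layer sums activations per class via the one-hot indicator
matrix ``T`` and picks the largest. Small sigma (large b) concentrates
mass on the nearest exemplar — overfitting; large sigma flattens the
kernel towards a majority vote — underfitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.spatial.distance import cdist

from .features import FEATURE_COLUMNS

#: b * sigma such that a query at distance sigma has activation 0.5:
#: exp(-(0.8326)^2) ~ 0.5.
_HALF_HEIGHT = 0.8326


def _as_xy(
    features, labels=None, columns: Sequence[str] | None = None
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Accept (DataFrame with a 'gesture' column) or (array, labels)."""
    if isinstance(features, pd.DataFrame):
        cols = list(
            columns
            if columns is not None
            else [c for c in FEATURE_COLUMNS if c in features.columns]
        )
        if labels is None:
            if "gesture" not in features.columns:
                raise ValueError("labeled DataFrame must carry a 'gesture' column")
            labels = features["gesture"].to_numpy()
        X = features[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if labels is None:
            raise ValueError("labels are required with array input")
        labels = np.asarray(labels)
        cols = [f"f{i}" for i in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X, np.asarray(labels), cols


@dataclass
class Prediction:
    """Predicted label plus per-class scores (model-convention ordered)."""

    label: str
    scores: np.ndarray
    classes: List[str]


@dataclass
class LDAModel:
    W: np.ndarray                    # (d, d') projection, eigenvalue-ordered
    class_means_projected: np.ndarray  # (n_classes, d')
    classes: List[str]
    Sw: np.ndarray
    Sb: np.ndarray
    regularization: float
    eigenvalues: np.ndarray
    feature_columns: List[str]


def scatter_matrices(
    X: np.ndarray, y: np.ndarray, classes: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Within/between-class scatter, class means and the overall mean."""
    d = X.shape[1]
    mu = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = np.zeros((len(classes), d))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        mi = Xi.mean(axis=0)
        means[i] = mi
        centered = Xi - mi
        Sw += centered.T @ centered
        dm = (mi - mu)[:, None]
        Sb += len(Xi) * (dm @ dm.T)
    return Sw, Sb, means, mu


def lda_fit(
    features,
    labels=None,
    n_components: int | None = None,
    regularization: float | None = None,
    columns: Sequence[str] | None = None,
) -> LDAModel:
    """Fit LDA by solving the generalized eigenproblem of (Sw, Sb).

    ``regularization`` defaults to ``1e-6 * trace(Sw)/d`` — a ridge on
    Sw that keeps the problem well posed when features are collinear
    while biasing the solution negligibly. Eigenvector signs are fixed
    (largest-magnitude component positive) for determinism.
    """
    X, y, cols = _as_xy(features, labels, columns)
    classes = sorted(set(map(str, y)))
    y = y.astype(str)
    if len(classes) < 2:
        raise ValueError("lda_fit needs at least two classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than two training rows")
    Sw, Sb, means, _ = scatter_matrices(X, y, classes)
    d = X.shape[1]
    lam = (
        regularization
        if regularization is not None
        else 1e-6 * (np.trace(Sw) / d if np.trace(Sw) > 0 else 1.0)
    )
    evals, evecs = sla.eigh(Sb, Sw + lam * np.eye(d))
    order = np.argsort(evals)[::-1]
    if n_components is None:
        # keep the largest non-zero eigenvalues, at most n_classes - 1:
        # directions with (relatively) vanishing between-class scatter
        # carry no class information, only noise
        d_prime = min(len(classes) - 1, d)
        top = max(evals[order[0]], 0.0)
        nonzero = int(np.sum(evals[order[:d_prime]] > 1e-3 * top))
        d_prime = max(1, nonzero)
    else:
        d_prime = n_components
    evals, evecs = evals[order[:d_prime]], evecs[:, order[:d_prime]]
    # deterministic sign: largest-|.| component of each eigenvector positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return LDAModel(
        W=evecs,
        class_means_projected=means @ evecs,
        classes=classes,
        Sw=Sw,
        Sb=Sb,
        regularization=lam,
        eigenvalues=evals,
        feature_columns=cols,
    )


def lda_predict(model: LDAModel, features, columns: Sequence[str] | None = None) -> List[Prediction]:
    """Project rows through W; assign the nearest projected class mean.

    Scores are Euclidean distances in the projected space (smaller is
    better); ties break to the first class in label order.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature frame lacks columns {missing}")
        X = features[model.feature_columns].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension {model.W.shape[0]}"
        )
    proj = X @ model.W
    dists = cdist(proj, model.class_means_projected)
    idx = np.argmin(dists, axis=1)  # argmin takes the first minimum: tie rule
    return [
        Prediction(label=model.classes[i], scores=row, classes=model.classes)
        for i, row in zip(idx, dists)
    ]


@dataclass
class PNNModel:
    exemplars: np.ndarray  # omega1: (Q, d) radial-layer weights = training rows
    b: float               # polarization factor
    T: np.ndarray          # (Q, n_classes) one-hot class indicators
    classes: List[str]
    sigma: float
    feature_columns: List[str]


def pnn_fit(features, labels=None, sigma: float = 0.3, columns: Sequence[str] | None = None) -> PNNModel:
    """Store the training set as the radial layer; b = 0.8326 / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X, y, cols = _as_xy(features, labels, columns)
    classes = sorted(set(map(str, y)))
    y = y.astype(str)
    T = np.zeros((len(y), len(classes)))
    for i, c in enumerate(classes):
        T[y == c, i] = 1.0
    return PNNModel(
        exemplars=X,
        b=_HALF_HEIGHT / sigma,
        T=T,
        classes=classes,
        sigma=sigma,
        feature_columns=cols,
    )


def pnn_predict(model: PNNModel, features, columns: Sequence[str] | None = None) -> List[Prediction]:
    """Radial activations summed per class; largest class score wins.

    Activations are rescaled per query by the nearest-exemplar distance
    before exponentiating — a positive common factor that leaves the
    class-score ordering unchanged but keeps the kernel finite at very
    small sigma (where the raw exponentials underflow), so the sigma->0
    limit is exactly one-nearest-neighbour.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature frame lacks columns {missing}")
        X = features[model.feature_columns].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.exemplars.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension "
            f"{model.exemplars.shape[1]}"
        )
    n1 = cdist(X, model.exemplars) * model.b  # scaled distances
    sq = np.square(n1)
    a1 = np.exp(-(sq - sq.min(axis=1, keepdims=True)))  # stabilized radial output
    scores = a1 @ model.T  # competition-layer input: per-class summed activations
    idx = np.argmax(scores, axis=1)  # first maximum: tie rule
    return [
        Prediction(label=model.classes[i], scores=row, classes=model.classes)
        for i, row in zip(idx, scores)
    ]


def predicted_labels(predictions: List[Prediction]) -> np.ndarray:
    return np.array([p.label for p in predictions])


def accuracy(predictions: List[Prediction], truth) -> float:
    truth = np.asarray(truth).astype(str)
    return float(np.mean(predicted_labels(predictions) == truth))


def fit(model_type: str, features, labels=None, sigma: float = 0.3, **kw):
    """Dispatch: ``'lda'`` or ``'pnn'``."""
    if model_type == "lda":
        return lda_fit(features, labels, **kw)
    if model_type == "pnn":
        return pnn_fit(features, labels, sigma=sigma, **kw)
    raise ValueError(f"unknown model type {model_type!r}; expected 'lda' or 'pnn'")


def predict(model, features) -> List[Prediction]:
    if isinstance(model, LDAModel):
        return lda_predict(model, features)
    if isinstance(model, PNNModel):
        return pnn_predict(model, features)
    raise TypeError(f"unsupported model {type(model).__name__}")
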