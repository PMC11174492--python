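"""The three classifier families used for leaf-sex discrimination.

* ``lda`` -- pooled full-covariance linear discriminant analysis.
* ``svm_quadratic`` -- support vector machine with a quadratic polynomial
  kernel, C = 1, automatic kernel scale, One-vs-One multiclass.
* ``sda`` -- subspace discriminant ensemble: 30 linear discriminants, each
  fit on a random feature subset of size floor(d/2), aggregated by majority
  vote with mean-posterior tie-breaking.

All models are wrapped in :class:`TrainedModel` so the pipeline can treat
them uniformly; SDA is fully seed-reproducible (subsets are drawn from the
stored seed).  An opt-in z-score switch standardizes features using training
statistics, useful for mixed-unit fusion vectors.
"""

from __future__ import annotations

import pickle
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

__all__ = [
    "TrainedModel",
    "SubspaceEnsemble",
    "train_lda",
    "train_svm_quadratic",
    "train_sda",
    "predict",
    "predict_proba",
    "majority_vote",
    "save_model",
    "load_model",
    "SDA_N_LEARNERS",
]

SDA_N_LEARNERS = 30


@dataclass
class SubspaceEnsemble:
    """Random-subspace discriminant committee (fit state of the sda family)."""

    members: list[tuple[np.ndarray, LinearDiscriminantAnalysis]]
    n_learners: int
    subspace_dim: int
    classes: np.ndarray
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.zeros((X.shape[0], self.classes.size))
        for idx, clf in self.members:
            probs += clf.predict_proba(X[:, idx])
        return probs / len(self.members)

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.stack(
            [clf.predict(X[:, idx]) for idx, clf in self.members], axis=1
        )
        out = np.empty(X.shape[0], dtype=self.classes.dtype)
        mean_proba = self.predict_proba(X)
        class_index = {c: k for k, c in enumerate(self.classes)}
        for r in range(votes.shape[0]):
            counts = Counter(votes[r])
            top = max(counts.values())
            tied = [c for c, n in counts.items() if n == top]
            if len(tied) == 1:
                out[r] = tied[0]
            else:  # tie-break on mean posterior across members
                out[r] = max(tied, key=lambda c: mean_proba[r, class_index[c]])
        return out


@dataclass
class TrainedModel:
    """A fitted classifier with its family tag and input signature."""

    family: str  # {lda, svm_quadratic, sda}
    estimator: object
    n_features: int
    classes: np.ndarray
    seed: int | None = None
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, std)
    info: dict = field(default_factory=dict)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return X
        mean, std = self.scaler
        return (X - mean) / std


def _validate_xy(X, y, min_per_class: int = 1):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples x n_features)")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y lengths differ")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if counts.min() < min_per_class:
        lacking = classes[counts.argmin()]
        raise ValueError(
            f"class {lacking!r} has {counts.min()} samples; need >= {min_per_class}"
        )
    return X, y, classes


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    return mean, std


def train_lda(X, y, standardize: bool = False) -> TrainedModel:
    """Pooled-covariance linear discriminant (SVD solver, robust to rank
    deficiency when features outnumber samples)."""
    X, y, classes = _validate_xy(X, y, min_per_class=2)
    scaler = _fit_scaler(X) if standardize else None
    if scaler is not None:
        X = (X - scaler[0]) / scaler[1]
    clf = LinearDiscriminantAnalysis(solver="svd")
    clf.fit(X, y)
    return TrainedModel(
        family="lda", estimator=clf, n_features=X.shape[1], classes=classes,
        scaler=scaler,
    )


def train_svm_quadratic(X, y, standardize: bool = False) -> TrainedModel:
    """Quadratic-kernel SVM: (gamma<x,z> + 1)^2 with gamma = 1/(d*Var(X)),
    C = 1, One-vs-One for multiclass."""
    X, y, classes = _validate_xy(X, y)
    scaler = _fit_scaler(X) if standardize else None
    if scaler is not None:
        X = (X - scaler[0]) / scaler[1]
    clf = SVC(
        kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0,
        decision_function_shape="ovo",
    )
    clf.fit(X, y)
    return TrainedModel(
        family="svm_quadratic", estimator=clf, n_features=X.shape[1],
        classes=classes, scaler=scaler,
        info={"kernel_scale_rule": "gamma = 1 / (n_features * Var(X))"},
    )


def train_sda(
    X,
    y,
    n_learners: int = SDA_N_LEARNERS,
    subspace_dim: int | None = None,
    seed: int = 0,
    standardize: bool = False,
) -> TrainedModel:
    """Random-subspace discriminant ensemble.

    Each member is an LDA fit on a uniformly random feature subset of size
    ``subspace_dim`` (default floor(d/2)); subsets are drawn without
    replacement from ``numpy.random.default_rng(seed)`` so the fit is
    bit-reproducible.
    """
    X, y, classes = _validate_xy(X, y, min_per_class=2)
    d = X.shape[1]
    if subspace_dim is None:
        subspace_dim = max(1, d // 2)
    if subspace_dim < 1:
        raise ValueError("subspace_dim must be >= 1")
    if subspace_dim > d:
        raise ValueError(f"subspace_dim {subspace_dim} exceeds feature count {d}")
    scaler = _fit_scaler(X) if standardize else None
    if scaler is not None:
        X = (X - scaler[0]) / scaler[1]
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_learners):
        idx = np.sort(rng.choice(d, size=subspace_dim, replace=False))
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X[:, idx], y)
        members.append((idx, clf))
    ens = SubspaceEnsemble(
        members=members, n_learners=n_learners, subspace_dim=subspace_dim,
        classes=classes, seed=seed,
    )
    return TrainedModel(
        family="sda", estimator=ens, n_features=d, classes=classes, seed=seed,
        scaler=scaler,
    )


def predict(model: TrainedModel, X) -> np.ndarray:
    """One label per row; deterministic given the model."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[0] == 0:
        return np.array([], dtype=model.classes.dtype)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    return np.asarray(model.estimator.predict(model._transform(X)))


def predict_proba(model: TrainedModel, X) -> np.ndarray:
    """Class-posterior estimates (LDA and SDA only)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    if not hasattr(model.estimator, "predict_proba"):
        raise TypeError(f"family '{model.family}' does not expose posteriors")
    return np.asarray(model.estimator.predict_proba(model._transform(X)))


def majority_vote(predictions: list[np.ndarray]) -> np.ndarray:
    """Per-sample modal label across models.

    With an even committee, ties are broken by the earliest-listed model
    whose prediction belongs to the tied label set.
    """
    if len(predictions) < 1:
        raise ValueError("need at least one model's predictions")
    arrays = [np.asarray(p) for p in predictions]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all prediction lists must have equal length")
    out = []
    for r in range(n):
        votes = [a[r] for a in arrays]
        counts = Counter(votes)
        top = max(counts.values())
        tied = {c for c, k in counts.items() if k == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(v for v in votes if v in tied))
    return np.array(out, dtype=arrays[0].dtype)


_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Serialize a trained model to a single versioned file."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"format_version": _FORMAT_VERSION, "model": model}, fh)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    return payload["model"]
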