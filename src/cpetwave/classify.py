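"""Kernel maximum-margin classifiers: binary SVMs and one-vs-one ECOC.

The soft-margin dual problem is solved by scikit-learn's SVC; everything
around it — per-learner standardization, the one-vs-one coding matrix,
hinge-loss decoding, persistence — is explicit here, and predictions are
computed from the stored support vectors and dual coefficients (not by the
solver object), so a model reloaded from JSON predicts identically.

Kernels: linear ``x.z``; polynomial ``(offset + x.z)^degree``; RBF
``exp(-||x - z||^2 / scale^2)``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from cpetwave.errors import DataError, FitError, SchemaError
from cpetwave.features import FeatureMatrix
from cpetwave.records import Condition


class KernelKind(enum.Enum):
    LINEAR = "linear"
    POLYNOMIAL = "polynomial"
    RBF = "rbf"


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyperparameters (defaults mirror common solver
    defaults: box constraint 1, cubic polynomial with unit offset, unit RBF
    scale)."""

    kind: KernelKind = KernelKind.LINEAR
    degree: int = 3
    offset: float = 1.0
    scale: float = 1.0
    box_constraint: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            object.__setattr__(self, "kind", KernelKind(self.kind))
        if self.degree < 1:
            raise DataError("polynomial degree must be >= 1")
        if not self.scale > 0:
            raise DataError("rbf scale must be > 0")
        if not self.box_constraint > 0:
            raise DataError("box constraint must be > 0")

    def gram(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Kernel matrix K[i, j] = K(X[i], Z[j])."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.kind is KernelKind.LINEAR:
            return X @ Z.T
        if self.kind is KernelKind.POLYNOMIAL:
            return (self.offset + X @ Z.T) ** self.degree
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Z**2, axis=1)[None, :]
            - 2.0 * (X @ Z.T)
        )
        return np.exp(-np.maximum(sq, 0.0) / self.scale**2)


@dataclass
class Standardizer:
    """Per-feature (mean, sd) affine map; zero-sd features map to exactly 0."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        return cls(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = np.asarray(X, dtype=float) - self.mean
        nonzero = self.sd > 0
        out[:, nonzero] /= self.sd[nonzero]
        out[:, ~nonzero] = 0.0
        return out


@dataclass
class _PairwiseSVM:
    """One trained binary learner; decision > 0 votes for the positive class."""

    standardizer: Standardizer
    support_vectors: np.ndarray  # standardized
    dual_coef: np.ndarray
    intercept: float

    def decision(self, kernel: KernelSpec, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(np.atleast_2d(X))
        return kernel.gram(Xs, self.support_vectors) @ self.dual_coef + self.intercept


def _sklearn_params(kernel: KernelSpec) -> dict:
    if kernel.kind is KernelKind.LINEAR:
        return {"kernel": "linear"}
    if kernel.kind is KernelKind.POLYNOMIAL:
        return {"kernel": "poly", "degree": kernel.degree, "gamma": 1.0, "coef0": kernel.offset}
    return {"kernel": "rbf", "gamma": 1.0 / kernel.scale**2}


def _train_pair(X: np.ndarray, y_sign: np.ndarray, kernel: KernelSpec, seed: int | None) -> _PairwiseSVM:
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    svc = SVC(
        C=kernel.box_constraint,
        tol=1e-6,
        random_state=seed,
        **_sklearn_params(kernel),
    )
    svc.fit(Xs, y_sign)
    return _PairwiseSVM(
        standardizer=std,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
    )


@dataclass
class FittedClassifier:
    """Binary SVM or a one-vs-one ECOC ensemble of pairwise SVMs.

    ``coding_matrix`` has one row per class and one column per learner with
    entries in {-1, 0, +1}.  Decoding minimizes the mean binary hinge loss
    ``max(0, 1 - m * f) / 2`` over the learners a class participates in;
    ties break to the lowest class index.
    """

    kernel: KernelSpec
    classes: list[Condition]
    feature_names: list[str]
    learners: list[_PairwiseSVM]
    coding_matrix: np.ndarray
    seed: int | None = None

    @property
    def is_binary(self) -> bool:
        return len(self.classes) == 2

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([learner.decision(self.kernel, X) for learner in self.learners])

    def decode(self, decisions: np.ndarray) -> np.ndarray:
        """Class index per row minimizing the mean hinge decoding loss."""
        losses = np.zeros((decisions.shape[0], len(self.classes)))
        for c, row in enumerate(self.coding_matrix):
            active = row != 0
            margin = row[active][None, :] * decisions[:, active]
            losses[:, c] = np.mean(np.maximum(0.0, 1.0 - margin) / 2.0, axis=1)
        return np.argmin(losses, axis=1)  # argmin takes the first (lowest) index on ties

    # -- persistence ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kernel": {
                "kind": self.kernel.kind.value,
                "degree": self.kernel.degree,
                "offset": self.kernel.offset,
                "scale": self.kernel.scale,
                "box_constraint": self.kernel.box_constraint,
            },
            "classes": [c.value for c in self.classes],
            "feature_names": self.feature_names,
            "coding_matrix": self.coding_matrix.tolist(),
            "seed": self.seed,
            "learners": [
                {
                    "mean": learner.standardizer.mean.tolist(),
                    "sd": learner.standardizer.sd.tolist(),
                    "support_vectors": learner.support_vectors.tolist(),
                    "dual_coef": learner.dual_coef.tolist(),
                    "intercept": learner.intercept,
                }
                for learner in self.learners
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedClassifier":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        payload = json.loads(text)
        kernel = KernelSpec(
            kind=KernelKind(payload["kernel"]["kind"]),
            degree=payload["kernel"]["degree"],
            offset=payload["kernel"]["offset"],
            scale=payload["kernel"]["scale"],
            box_constraint=payload["kernel"]["box_constraint"],
        )
        learners = [
            _PairwiseSVM(
                standardizer=Standardizer(
                    mean=np.array(item["mean"]), sd=np.array(item["sd"])
                ),
                support_vectors=np.array(item["support_vectors"]),
                dual_coef=np.array(item["dual_coef"]),
                intercept=float(item["intercept"]),
            )
            for item in payload["learners"]
        ]
        return cls(
            kernel=kernel,
            classes=[Condition(c) for c in payload["classes"]],
            feature_names=list(payload["feature_names"]),
            learners=learners,
            coding_matrix=np.array(payload["coding_matrix"]),
            seed=payload["seed"],
        )


def _check_features(fm: FeatureMatrix) -> None:
    if not np.isfinite(fm.values).all():
        raise DataError("feature matrix contains non-finite values")


def fit_binary(features: FeatureMatrix, kernel: KernelSpec, seed: int | None = None) -> FittedClassifier:
    """Train a soft-margin kernel SVM on a two-label feature matrix.

    The first label in cohort order is the positive class: the decision
    function is positive on its side of the margin.
    """
    _check_features(features)
    classes = features.classes()
    if len(classes) != 2:
        raise FitError(f"fit_binary needs exactly 2 classes, got {len(classes)}")
    y_sign = np.array([1.0 if label == classes[0] else -1.0 for label in features.labels])
    learner = _train_pair(features.values, y_sign, kernel, seed)
    coding = np.array([[1], [-1]])
    return FittedClassifier(
        kernel=kernel,
        classes=classes,
        feature_names=list(features.feature_names),
        learners=[learner],
        coding_matrix=coding,
        seed=seed,
    )


def fit_multiclass(features: FeatureMatrix, kernel: KernelSpec, seed: int | None = None) -> FittedClassifier:
    """Train a one-vs-one ECOC ensemble: one binary SVM per unordered class
    pair, each standardized on its own training rows."""
    _check_features(features)
    classes = features.classes()
    if len(classes) < 3:
        raise FitError(f"fit_multiclass needs >= 3 classes, got {len(classes)}; use fit_binary")
    labels = np.array([classes.index(label) for label in features.labels])

    pairs = list(combinations(range(len(classes)), 2))
    coding = np.zeros((len(classes), len(pairs)), dtype=int)
    learners = []
    for column, (i, j) in enumerate(pairs):
        coding[i, column] = 1
        coding[j, column] = -1
        mask = (labels == i) | (labels == j)
        y_sign = np.where(labels[mask] == i, 1.0, -1.0)
        learners.append(_train_pair(features.values[mask], y_sign, kernel, seed))
    return FittedClassifier(
        kernel=kernel,
        classes=classes,
        feature_names=list(features.feature_names),
        learners=learners,
        coding_matrix=coding,
        seed=seed,
    )


def predict(model: FittedClassifier, features: FeatureMatrix | np.ndarray) -> list[Condition]:
    """Deterministic label per row (binary: decision sign; multi-class:
    hinge-loss ECOC decoding)."""
    if isinstance(features, FeatureMatrix):
        if features.feature_names != model.feature_names:
            raise SchemaError("feature columns do not match the fitted model")
        X = features.values
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
            )
    decisions = model.decision_values(X)
    if model.is_binary:
        indices = np.where(decisions[:, 0] >= 0, 0, 1)
    else:
        indices = model.decode(decisions)
    return [model.classes[i] for i in indices]
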