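"""Repeated unstratified k-fold cross-validation and confusion-matrix metrics.

Confusion-matrix orientation (important, fixed throughout): rows index the
PREDICTED label, columns the TRUE label.  The per-label one-vs-rest
reduction of an n x n matrix C is then

    TP_m = C[m, m]
    FP_m = (sum of row m)    - TP_m      (predicted m but not m)
    FN_m = (sum of column m) - TP_m      (true m missed)
    TN_m = N - TP_m - FP_m - FN_m

with 1-based label index m (m=1 HF, m=2 MS, m=3 H for the standard cohort).

Each repeat pools the k held-out folds into one confusion matrix; metrics
are computed per repeat from the pooled matrix and then averaged over
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cpetwave.classify import KernelSpec, fit_binary, fit_multiclass, predict
from cpetwave.errors import ConfigError, DataError, FitError
from cpetwave.features import FeatureMatrix


@dataclass
class CVConfig:
    k: int = 5
    repeats: int = 5
    stratified: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.repeats < 1:
            raise ConfigError(f"repeats must be >= 1, got {self.repeats}")


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of samples predicted classes[i] with true classes[j]."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise DataError("confusion matrix shape does not match class count")
        if (self.counts < 0).any():
            raise DataError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LabelReduction:
    """One-vs-rest counts for a single label index m (1-based)."""

    m: int
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class LabelMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()  # metrics that were 0/0 and reported as 0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.accuracy, self.precision, self.recall, self.f1)


@dataclass
class MetricsReport:
    """Per-label and macro metrics (percent), averaged over CV repeats."""

    classes: list
    per_label: dict
    macro: LabelMetrics
    confusion_per_repeat: list[ConfusionMatrix]
    k: int
    repeats: int
    seed: int | None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def metrics_dict(m: LabelMetrics) -> dict:
            return {
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "undefined": list(m.undefined),
            }

        return {
            "classes": [getattr(c, "value", c) for c in self.classes],
            "per_label": {
                getattr(label, "value", label): metrics_dict(m) for label, m in self.per_label.items()
            },
            "macro": metrics_dict(self.macro),
            "confusion_per_repeat": [cm.counts.tolist() for cm in self.confusion_per_repeat],
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def make_folds(n: int, cfg: CVConfig) -> list[list[np.ndarray]]:
    """Per-repeat fold index sets: a seeded random permutation of 0..n-1 cut
    into k contiguous blocks whose sizes differ by at most one.

    Unstratified by default; no class information is consulted.
    """
    if n < cfg.k:
        raise ConfigError(f"cannot split n={n} samples into k={cfg.k} folds")
    rng = np.random.default_rng(cfg.seed)
    all_repeats = []
    for _ in range(cfg.repeats):
        perm = rng.permutation(n)
        all_repeats.append([np.sort(block) for block in np.array_split(perm, cfg.k)])
    return all_repeats


def confusion(pred: list, truth: list, classes: list) -> ConfusionMatrix:
    """Count (predicted, true) label pairs; rows predicted, columns true."""
    if len(pred) != len(truth):
        raise DataError("pred and truth must have equal length")
    index = {label: i for i, label in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(pred, truth):
        if p not in index or t not in index:
            raise DataError(f"unknown label: {p if p not in index else t}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def reduce_label(C: ConfusionMatrix, m: int) -> LabelReduction:
    """One-vs-rest reduction of label index ``m`` (1-based)."""
    n = len(C.classes)
    if not 1 <= m <= n:
        raise DataError(f"label index m={m} out of range 1..{n}")
    i = m - 1
    tp = int(C.counts[i, i])
    fp = int(C.counts[i, :].sum()) - tp
    fn = int(C.counts[:, i].sum()) - tp
    tn = C.total - tp - fp - fn
    return LabelReduction(m=m, TP=tp, FP=fp, FN=fn, TN=tn)


def binary_metrics(r: LabelReduction) -> LabelMetrics:
    """Accuracy / precision / recall / F1 in percent; 0/0 ratios are
    reported as 0 and flagged in ``undefined``."""
    total = r.total
    if total <= 0:
        raise DataError("empty reduction: N must be > 0")
    undefined = []
    accuracy = 100.0 * (r.TP + r.TN) / total
    if r.TP + r.FP > 0:
        precision = 100.0 * r.TP / (r.TP + r.FP)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if r.TP + r.FN > 0:
        recall = 100.0 * r.TP / (r.TP + r.FN)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return LabelMetrics(accuracy, precision, recall, f1, undefined=tuple(undefined))


def macro_average(per_label: list[LabelMetrics] | list[tuple]) -> LabelMetrics:
    """Arithmetic mean of each metric across labels."""
    if not per_label:
        raise DataError("macro_average needs at least one label")
    tuples = [m.as_tuple() if isinstance(m, LabelMetrics) else tuple(m) for m in per_label]
    means = np.mean(np.array(tuples, dtype=float), axis=0)
    return LabelMetrics(*[float(v) for v in means])


def _report_from_confusions(
    confusions: list[ConfusionMatrix],
    classes: list,
    cfg: CVConfig,
    notes: list[str],
) -> MetricsReport:
    # metrics per repeat from the pooled matrix, then averaged over repeats
    per_label_acc: dict = {label: [] for label in classes}
    for cm in confusions:
        for m, label in enumerate(classes, start=1):
            per_label_acc[label].append(binary_metrics(reduce_label(cm, m)))
    per_label = {}
    for label in classes:
        reps = per_label_acc[label]
        means = np.mean([m.as_tuple() for m in reps], axis=0)
        flags = tuple(sorted({flag for m in reps for flag in m.undefined}))
        per_label[label] = LabelMetrics(*[float(v) for v in means], undefined=flags)
    macro = macro_average(list(per_label.values()))
    return MetricsReport(
        classes=list(classes),
        per_label=per_label,
        macro=macro,
        confusion_per_repeat=confusions,
        k=cfg.k,
        repeats=cfg.repeats,
        seed=cfg.seed,
        warnings=notes,
    )


def _stratified_folds(labels: list, classes: list, cfg: CVConfig) -> list[list[np.ndarray]]:
    rng = np.random.default_rng(cfg.seed)
    per_class = {c: np.flatnonzero([l == c for l in labels]) for c in classes}
    all_repeats = []
    for _ in range(cfg.repeats):
        folds = [[] for _ in range(cfg.k)]
        offset = 0
        for c in classes:
            idx = rng.permutation(per_class[c])
            for j, value in enumerate(idx):
                folds[(j + offset) % cfg.k].append(value)
            offset += idx.size % cfg.k
        all_repeats.append([np.sort(np.array(f, dtype=int)) for f in folds])
    return all_repeats


def cross_validate(features: FeatureMatrix, kernel: KernelSpec, cfg: CVConfig) -> MetricsReport:
    """Repeated k-fold CV of the SVM pipeline on a feature matrix.

    Per repeat: each fold is held out once, the model (binary for two
    classes, one-vs-one ECOC otherwise) is trained on the remaining folds
    with standardization refit inside the training split, and the held-out
    predictions are pooled into one confusion matrix.  A training split
    missing a class skips that fold with a recorded warning.
    """
    classes = features.classes()
    if len(classes) < 2:
        raise FitError("cross_validate needs >= 2 classes")
    n = features.n_subjects
    labels = features.labels

    folds_per_repeat = (
        _stratified_folds(labels, classes, cfg) if cfg.stratified else make_folds(n, cfg)
    )
    fit = fit_binary if len(classes) == 2 else fit_multiclass

    notes: list[str] = []
    confusions: list[ConfusionMatrix] = []
    for repeat, folds in enumerate(folds_per_repeat):
        pred_all: list = []
        truth_all: list = []
        for fold_idx, test_idx in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            train_labels = [labels[i] for i in np.flatnonzero(mask)]
            if any(c not in train_labels for c in classes):
                notes.append(
                    f"repeat {repeat}, fold {fold_idx}: training split missing a class; fold skipped"
                )
                continue
            train_fm = FeatureMatrix(
                layout=features.layout,
                values=features.values[mask],
                feature_names=list(features.feature_names),
                labels=train_labels,
                row_ids=[features.row_ids[i] for i in np.flatnonzero(mask)],
                variables=features.variables,
            )
            model = fit(train_fm, kernel, cfg.seed)
            pred_all.extend(predict(model, features.values[test_idx]))
            truth_all.extend(labels[i] for i in test_idx)
        confusions.append(confusion(pred_all, truth_all, classes))
    return _report_from_confusions(confusions, classes, cfg, notes)


def rank_models(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Ranking table sorted by macro accuracy (desc), ties broken by macro
    F1 (desc) then model name (asc)."""
    if not reports:
        raise DataError("rank_models needs at least one report")
    rows = [
        {
            "method": name,
            "accuracy": report.macro.accuracy,
            "precision": report.macro.precision,
            "recall": report.macro.recall,
            "f1": report.macro.f1,
        }
        for name, report in reports.items()
    ]
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["accuracy", "f1", "method"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame
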