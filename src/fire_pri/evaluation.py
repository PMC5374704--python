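"""Classifier training, stratified cross-validation and metrics.

Metrics follow the class-imbalance conventions: sensitivity
SE = TP/(TP+FN), specificity SP = TN/(TN+FP), geometric mean
GM = sqrt(SE*SP), accuracy ACC = (TP+TN)/total, plus ROC AUC from the
classifier's continuous score.  Cross-validation is stratified (each fold
preserves the positive:negative ratio) and metrics are pooled over the
out-of-fold predictions (micro-averaged), which is stable for small
datasets.  The improvement ratio IR is the signed percent change of a
metric between two evaluation runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .exceptions import UndefinedMetricError, ValidationError

CLASSIFIER_NAMES = ("svm", "rf", "nb")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    se: float
    sp: float
    gm: float
    acc: float
    auc: float | None = None
    classifier: str = ""
    dataset: str = ""
    pnr: float | None = None  # ratio of positives to negatives

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "dataset": self.dataset,
            "pnr": self.pnr,
            "se": self.se,
            "sp": self.sp,
            "gm": self.gm,
            "acc": self.acc,
            "auc": self.auc,
        }


def confusion_metrics(counts: ConfusionCounts, **meta) -> MetricsReport:
    """SE/SP/GM/ACC from a confusion table; both classes must be present."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("SE undefined: no positive samples (TP+FN = 0)")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("SP undefined: no negative samples (TN+FP = 0)")
    se = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    return MetricsReport(
        se=se,
        sp=sp,
        gm=float(np.sqrt(se * sp)),
        acc=(counts.tp + counts.tn) / counts.total,
        **meta,
    )


def improvement_ratio(reliable: float, random: float) -> float:
    """IR = (reliable - random) / random * 100, in percent; negative when
    the reliable-negative run is worse."""
    if random == 0:
        raise UndefinedMetricError("IR undefined: the random-baseline value is 0")
    return (reliable - random) / random * 100.0


def make_classifier(name: str, seed: int = 0, **overrides):
    """Instantiate one of the three supported classifiers.

    Hyperparameters are the ecosystem defaults — SVM: RBF kernel, C = 1,
    gamma = 1/n_features; RF: 500 trees; NB: Gaussian — and can be
    overridden per call.
    """
    if name == "svm":
        params = dict(kernel="rbf", C=1.0, gamma="auto", random_state=seed)
        params.update(overrides)
        return SVC(**params)
    if name == "rf":
        params = dict(n_estimators=500, random_state=seed, n_jobs=1)
        params.update(overrides)
        return RandomForestClassifier(**params)
    if name == "nb":
        return GaussianNB(**overrides)
    raise ValidationError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


def _continuous_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return estimator.decision_function(X)
    return estimator.predict_proba(X)[:, 1]


def cross_val_predictions(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm",
    folds: int = 10,
    seed: int = 0,
    **clf_params,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold hard predictions and continuous scores from
    stratified k-fold cross-validation (each fold preserves the class
    ratio of ``y``)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < folds or n_neg < folds:
        raise ValidationError(
            f"need >= {folds} samples per class for {folds}-fold stratified "
            f"CV, got {n_pos} positives / {n_neg} negatives"
        )
    base = make_classifier(classifier, seed=seed, **clf_params)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    y_score = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        est = clone(base)
        est.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = est.predict(X[test_idx])
        y_score[test_idx] = _continuous_scores(est, X[test_idx])
    return y_pred, y_score


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray | None = None, **meta
) -> MetricsReport:
    """Confusion metrics (and AUC when scores are given) for a prediction
    vector against reference labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )
    report = confusion_metrics(counts, **meta)
    if y_score is not None:
        report.auc = float(roc_auc_score(y_true, y_score))
    return report


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm",
    folds: int = 10,
    seed: int = 0,
    dataset: str = "",
    **clf_params,
) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled out-of-fold metrics.

    Every fold preserves the positive:negative ratio; predictions and
    continuous scores from all folds are pooled into one confusion table
    and one ROC curve.  Reproducible for a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    y_pred, y_score = cross_val_predictions(
        X, y, classifier=classifier, folds=folds, seed=seed, **clf_params
    )
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    counts = ConfusionCounts(
        tp=int(((y == 1) & (y_pred == 1)).sum()),
        tn=int(((y == 0) & (y_pred == 0)).sum()),
        fp=int(((y == 0) & (y_pred == 1)).sum()),
        fn=int(((y == 1) & (y_pred == 0)).sum()),
    )
    report = confusion_metrics(
        counts, classifier=classifier, dataset=dataset, pnr=n_pos / n_neg
    )
    report.auc = float(roc_auc_score(y, y_score))
    return report


def train_and_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    classifier: str = "rf",
    seed: int = 0,
    dataset: str = "",
    **clf_params,
) -> MetricsReport:
    """Fit on a training split, report metrics on an independent test split."""
    est = make_classifier(classifier, seed=seed, **clf_params)
    est.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=int))
    y_test = np.asarray(y_test, dtype=int)
    y_pred = est.predict(np.asarray(X_test, dtype=float))
    counts = ConfusionCounts(
        tp=int(((y_test == 1) & (y_pred == 1)).sum()),
        tn=int(((y_test == 0) & (y_pred == 0)).sum()),
        fp=int(((y_test == 0) & (y_pred == 1)).sum()),
        fn=int(((y_test == 1) & (y_pred == 0)).sum()),
    )
    n_pos, n_neg = int((y_train == 1).sum()), int((y_train == 0).sum())
    report = confusion_metrics(
        counts, classifier=classifier, dataset=dataset, pnr=n_pos / max(n_neg, 1)
    )
    report.auc = float(roc_auc_score(y_test, _continuous_scores(est, X_test)))
    return report


def write_report(report: MetricsReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in report.as_dict().items():
            fh.write(f"{key}\t{value}\n")


def read_report(path: str | Path) -> MetricsReport:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                key, value = line.rstrip("\n").split("\t")
                fields[key] = value
    return MetricsReport(
        se=float(fields["se"]),
        sp=float(fields["sp"]),
        gm=float(fields["gm"]),
        acc=float(fields["acc"]),
        auc=None if fields.get("auc") in (None, "", "None") else float(fields["auc"]),
        classifier=fields.get("classifier", ""),
        dataset=fields.get("dataset", ""),
        pnr=None if fields.get("pnr") in (None, "", "None") else float(fields["pnr"]),
    )
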