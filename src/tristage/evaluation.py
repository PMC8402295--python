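"""Shared model-evaluation utilities.

Stratified cross-validation with pooled predictions, the four headline
classification metrics, and the one-sample t-test used to compare a method's
accuracy against a set of published reference accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data_io import Dataset


def make_classifier(spec: str, seed: int = 0, knn_k: int = 5):
    """Instantiate one of the pipeline's classifiers by name.

    Names: ``knn`` (K nearest neighbours, default K=5), ``svm`` (RBF SVC),
    ``nb`` (Gaussian naive Bayes), ``xgb`` (gradient-boosted trees).
    Library defaults otherwise, for reproducibility pinned only by seed.
    """
    spec = spec.lower()
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if spec == "svm":
        return SVC(random_state=seed)
    if spec == "nb":
        return GaussianNB()
    if spec == "xgb":
        return XGBClassifier(
            n_jobs=1,
            verbosity=0,
            tree_method="hist",
            random_state=seed,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown classifier spec {spec!r}")


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> list:
    """Seeded stratified fold assignment shared across evaluations."""
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratification infeasible: smallest class has {counts.min()} "
            f"samples for {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled cross-validated metrics, each in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_fold_accuracy: tuple
    seed: int

    def as_percent(self) -> dict:
        return {
            k: round(getattr(self, k) * 100, 2)
            for k in ("accuracy", "precision", "recall", "f1")
        }


def cross_val_predictions(
    X: np.ndarray, y: np.ndarray, model_factory, fold_indices
) -> np.ndarray:
    """Out-of-fold predictions with a fresh model per fold."""
    pred = np.empty(len(y), dtype=y.dtype)
    for train, test in fold_indices:
        model = model_factory()
        model.fit(X[train], y[train])
        pred[test] = model.predict(X[test])
    return pred


def pooled_accuracy(
    X: np.ndarray, y: np.ndarray, model_factory, fold_indices
) -> float:
    return float(
        accuracy_score(y, cross_val_predictions(X, y, model_factory, fold_indices))
    )


def stratified_cv_evaluate(
    d: Dataset,
    feature_mask,
    classifier_spec: str,
    folds: int = 10,
    seed: int = 0,
    positive_class=None,
    knn_k: int = 5,
) -> EvaluationReport:
    """Evaluate one classifier on a feature subset with stratified CV.

    Predictions are pooled over folds before computing accuracy, precision,
    recall and F1. For binary problems the positive class defaults to the
    second label in sorted order; multiclass uses macro averaging.
    """
    feature_mask = np.asarray(feature_mask)
    if feature_mask.dtype == bool:
        cols = np.flatnonzero(feature_mask)
    else:
        cols = feature_mask.astype(int)
    if cols.size == 0:
        raise ValueError("feature mask selects no features")
    X = d.features[:, cols]
    classes, y = np.unique(d.labels, return_inverse=True)
    fold_indices = stratified_folds(y, folds, seed)

    def factory():
        return make_classifier(classifier_spec, seed=seed, knn_k=knn_k)

    pred = cross_val_predictions(X, y, factory, fold_indices)
    per_fold = tuple(
        float(accuracy_score(y[test], pred[test])) for _, test in fold_indices
    )
    if len(classes) == 2:
        if positive_class is None:
            pos = 1
        else:
            pos = int(np.flatnonzero(classes == positive_class)[0])
        p, r, f, _ = precision_recall_fscore_support(
            y, pred, average="binary", pos_label=pos, zero_division=0
        )
    else:
        p, r, f, _ = precision_recall_fscore_support(
            y, pred, average="macro", zero_division=0
        )
    return EvaluationReport(
        accuracy=float(accuracy_score(y, pred)),
        precision=float(p),
        recall=float(r),
        f1=float(f),
        per_fold_accuracy=per_fold,
        seed=seed,
    )


def one_sample_t_test(sample, reference_mean: float) -> dict:
    """One-sample t-test of a set of accuracies against a reference value.

    Returns the t statistic, the one-sided lower-tail p-value (probability
    under H0 of a t at least this far below zero) and the degrees of
    freedom. Used to ask whether published competitor accuracies fall
    significantly below a method's accuracy.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least 2 observations")
    if sample.std(ddof=1) == 0:
        raise ValueError("zero-variance sample: t statistic undefined")
    res = stats.ttest_1samp(sample, reference_mean, alternative="less")
    return {
        "t_statistic": float(res.statistic),
        "p_value_one_sided": float(res.pvalue),
        "degrees_of_freedom": int(sample.size - 1),
    }
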