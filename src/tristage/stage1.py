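"""Phase 1: ranker union, per-feature accuracy screening, plateau truncation.

The four filter rankings each contribute their top-m features to a union
pool. Every pooled feature is then scored on its own by three classifiers
(KNN, SVM, naive Bayes) under one shared stratified fold assignment, the
pool is sorted by mean accuracy, and a gradient-boosting evaluation over
nested prefixes picks the smallest prefix size k whose cross-validated
accuracy attains the maximum ("the plateau rule").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset
from .evaluation import make_classifier, pooled_accuracy, stratified_folds
from .filters import RankedList

STAGE1_CLASSIFIERS = ("knn", "svm", "nb")


@dataclass(frozen=True)
class FeatureAccuracyRecord:
    feature_index: int
    per_classifier_accuracy: dict
    mean_accuracy: float


@dataclass(frozen=True)
class StageResult:
    """An ordered feature subset plus the prefix-accuracy trace behind it.

    ``selected_size`` is the smallest evaluated prefix size attaining the
    maximum accuracy in ``prefix_accuracy_trace``.
    """

    ordered_features: np.ndarray
    selected_size: int
    prefix_accuracy_trace: dict

    @property
    def selected_features(self) -> np.ndarray:
        return self.ordered_features[: self.selected_size]

    def to_dict(self, feature_names=None) -> dict:
        order = self.ordered_features.tolist()
        if feature_names is not None:
            names = np.asarray(feature_names, dtype=object)
            order = [str(names[i]) for i in order]
        return {
            "ordered_features": order,
            "selected_size": int(self.selected_size),
            "prefix_accuracy_trace": {
                str(k): v for k, v in sorted(self.prefix_accuracy_trace.items())
            },
        }


def default_m(n_features: int) -> int:
    """Per-ranker top-m pool size, scaled with dataset width."""
    if n_features <= 1000:
        return min(50, n_features)
    if n_features <= 6000:
        return 100
    return 200


def union_top_m(ranked_lists, m: int) -> np.ndarray:
    """Set union of the four rankers' top-m features, ascending indices."""
    ranked_lists = list(ranked_lists)
    if len(ranked_lists) != 4:
        raise ValueError(f"expected exactly 4 ranked lists, got {len(ranked_lists)}")
    n_features = ranked_lists[0].order.size
    if m > n_features:
        raise ValueError(f"m={m} exceeds feature count {n_features}")
    if m < 1:
        raise ValueError("m must be positive")
    pool: set[int] = set()
    for rl in ranked_lists:
        if not isinstance(rl, RankedList):
            raise TypeError("union_top_m expects RankedList inputs")
        pool.update(int(i) for i in rl.top(m))
    return np.array(sorted(pool), dtype=int)


def score_features_individually(
    d: Dataset,
    candidates,
    cv_folds: int = 10,
    seed: int = 0,
    knn_k: int = 5,
) -> list[FeatureAccuracyRecord]:
    """Cross-validated accuracy of each candidate feature on its own.

    The identical stratified fold assignment is reused across all features
    and all three classifiers so that the mean accuracies are comparable.
    """
    candidates = np.asarray(list(candidates), dtype=int)
    if candidates.size == 0:
        raise ValueError("no candidate features to score")
    _, y = np.unique(d.labels, return_inverse=True)
    folds = stratified_folds(y, cv_folds, seed)
    records = []
    for j in candidates:
        col = d.features[:, [j]]
        per = {
            name: pooled_accuracy(
                col, y, lambda: make_classifier(name, seed=seed, knn_k=knn_k), folds
            )
            for name in STAGE1_CLASSIFIERS
        }
        records.append(
            FeatureAccuracyRecord(
                feature_index=int(j),
                per_classifier_accuracy=per,
                mean_accuracy=float(np.mean(list(per.values()))),
            )
        )
    return records


def sort_by_mean_accuracy(records) -> np.ndarray:
    """Descending by mean accuracy; ties broken by ascending feature index."""
    if not records:
        raise ValueError("no records to sort")
    idx = np.array([r.feature_index for r in records])
    means = np.array([r.mean_accuracy for r in records])
    return idx[np.lexsort((idx, -means))]


def plateau_select(
    d: Dataset | None,
    ordered_features,
    coarse_step: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
    evaluator=None,
) -> StageResult:
    """Pick the smallest prefix of an ordered feature list that attains the
    maximum cross-validated accuracy.

    Prefix sizes ``coarse_step, 2*coarse_step, ...`` up to the full length
    are evaluated with an XGBoost classifier under seeded stratified CV;
    every size within +/- coarse_step of the best coarse size is then
    evaluated, and the smallest size attaining the global maximum over all
    evaluated sizes wins. A custom ``evaluator(prefix_indices) -> accuracy``
    may replace the XGBoost evaluation.
    """
    ordered_features = np.asarray(list(ordered_features), dtype=int)
    L = ordered_features.size
    if L == 0:
        raise ValueError("ordered_features is empty")
    if coarse_step < 1:
        raise ValueError("coarse_step must be positive")

    if evaluator is None:
        if d is None:
            raise ValueError("a Dataset is required without a custom evaluator")
        _, y = np.unique(d.labels, return_inverse=True)
        folds = stratified_folds(y, cv_folds, seed)

        def evaluator(prefix):
            return pooled_accuracy(
                d.features[:, prefix],
                y,
                lambda: make_classifier("xgb", seed=seed),
                folds,
            )

    trace: dict[int, float] = {}

    def evaluate(size: int) -> None:
        if size not in trace:
            trace[size] = float(evaluator(ordered_features[:size]))

    coarse = list(range(coarse_step, L + 1, coarse_step))
    if not coarse or coarse[-1] != L:
        coarse.append(L)
    for size in coarse:
        evaluate(size)
    best_coarse = min(s for s in coarse if trace[s] == max(trace.values()))
    for size in range(max(1, best_coarse - coarse_step), min(L, best_coarse + coarse_step) + 1):
        evaluate(size)
    best = max(trace.values())
    selected = min(s for s, a in trace.items() if a == best)
    return StageResult(ordered_features, int(selected), trace)
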