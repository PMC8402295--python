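"""Filter rankers: mutual information, chi-square, ReliefF, and Xvariance.

All four rank descending: a larger score always means a more desirable
feature, with ties broken by ascending feature index. Mutual information and
chi-square operate on equal-frequency discretized features; ReliefF and
Xvariance use the continuous values (features are expected on [0, 1] after
preprocessing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency

from .data_io import Dataset


@dataclass(frozen=True)
class RankedList:
    """One filter's ordering of all features.

    `order` is a permutation of feature indices sorted by descending score,
    ties broken by ascending index.
    """

    method: str
    scores: np.ndarray
    order: np.ndarray

    @classmethod
    def from_scores(cls, method: str, scores: np.ndarray) -> "RankedList":
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((np.arange(scores.size), -scores))
        return cls(method, scores, order)

    def top(self, m: int) -> np.ndarray:
        return self.order[:m]

    def to_tsv(self, path, feature_names) -> None:
        names = np.asarray(feature_names, dtype=object)[self.order]
        pd.DataFrame({"feature_name": names, "score": self.scores[self.order]}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class ContingencyTable:
    """Discretized-feature x class counts with independence expectations."""

    counts: np.ndarray
    expected: np.ndarray
    z: int
    p_class: np.ndarray

    @classmethod
    def from_codes(cls, bins: np.ndarray, class_codes: np.ndarray) -> "ContingencyTable":
        n_bins = int(bins.max()) + 1
        n_classes = int(class_codes.max()) + 1
        counts = np.zeros((n_bins, n_classes), dtype=int)
        np.add.at(counts, (bins, class_codes), 1)
        z = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / z
        return cls(counts, expected, int(z), counts.sum(axis=0) / z)


def discretize(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into at most `n_bins` bins.

    Identical values always share a bin; bin ids are contiguous from 0.
    """
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValueError("cannot discretize an empty column")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.unique(column).size == 1:
        return np.zeros(column.size, dtype=int)
    codes = pd.qcut(column, q=n_bins, labels=False, duplicates="drop")
    codes = np.asarray(codes, dtype=int)
    # qcut can merge edges; re-densify ids so they are contiguous from 0
    _, dense = np.unique(codes, return_inverse=True)
    return dense.astype(int)


def _class_codes(labels: np.ndarray) -> np.ndarray:
    _, codes = np.unique(labels, return_inverse=True)
    return codes.astype(int)


def _contingency(feature: np.ndarray, labels: np.ndarray, n_bins: int) -> ContingencyTable:
    return ContingencyTable.from_codes(discretize(feature, n_bins), _class_codes(labels))


def mutual_information_bits(table: ContingencyTable) -> float:
    """Plug-in mutual information of the empirical joint, in bits."""
    joint = table.counts / table.z
    outer = table.expected / table.z
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def chi_square_statistic(table: ContingencyTable) -> float:
    """Pearson chi-square of the observed counts against independence."""
    if table.counts.shape[0] < 2 or table.counts.shape[1] < 2:
        return 0.0
    return float(chi2_contingency(table.counts, correction=False).statistic)


def rank_mutual_information(d: Dataset, n_bins: int = 10) -> RankedList:
    """Score each feature by its mutual information with the class label.

    Features are discretized by equal-frequency binning first; the score is
    the plug-in estimate over the resulting contingency table. Zero means
    the empirical joint factorizes (feature carries no class information).
    """
    scores = np.array(
        [
            mutual_information_bits(_contingency(d.features[:, j], d.labels, n_bins))
            for j in range(d.n_features)
        ]
    )
    return RankedList.from_scores("MI", scores)


def rank_chi_square(d: Dataset, n_bins: int = 10) -> RankedList:
    """Score each feature by the chi-square statistic of its binned values
    against the class label; higher means stronger dependence."""
    scores = np.array(
        [
            chi_square_statistic(_contingency(d.features[:, j], d.labels, n_bins))
            for j in range(d.n_features)
        ]
    )
    return RankedList.from_scores("CS", scores)


def rank_xvariance(d: Dataset) -> RankedList:
    """Xvariance: sum over classes of the within-class sample variance.

    Uses the n-1 denominator; a singleton class contributes 0.
    """
    scores = np.zeros(d.n_features)
    for cls in d.classes:
        block = d.features[d.labels == cls]
        if block.shape[0] >= 2:
            scores += block.var(axis=0, ddof=1)
    return RankedList.from_scores("XV", scores)


def rank_relieff(
    d: Dataset,
    k_neighbors: int = 10,
    n_sampled_instances: int | None = None,
    seed: int = 0,
) -> RankedList:
    """Multiclass ReliefF feature weights.

    For each sampled instance the k nearest same-class hits pull a feature's
    weight down by the mean absolute value difference, and the k nearest
    misses of every other class push it up, weighted by that class's prior
    over (1 - prior of the instance's class). Neighbors are found with
    Manhattan distance; distance ties break by ascending sample index. By
    default all instances are used, making the ranking deterministic.
    """
    X, labels = d.features, d.labels
    n = X.shape[0]
    classes, codes = np.unique(labels, return_inverse=True)
    priors = np.bincount(codes) / n
    smallest = np.bincount(codes).min()
    if smallest <= k_neighbors:
        raise ValueError(
            f"each class needs > k_neighbors={k_neighbors} samples (smallest has {smallest})"
        )
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0  # constant features contribute zero diffs anyway

    if n_sampled_instances is None or n_sampled_instances >= n:
        sampled = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sampled = np.sort(rng.choice(n, size=n_sampled_instances, replace=False))

    dist = cdist(X[sampled], X, metric="cityblock")
    weights = np.zeros(X.shape[1])
    for row, i in enumerate(sampled):
        for c in range(len(classes)):
            pool = np.flatnonzero(codes == c)
            pool = pool[pool != i]
            picked = pool[np.lexsort((pool, dist[row, pool]))][:k_neighbors]
            diffs = np.abs(X[i] - X[picked]).mean(axis=0) / span
            if c == codes[i]:
                weights -= diffs
            else:
                weights += priors[c] / (1.0 - priors[codes[i]]) * diffs
    weights /= len(sampled)
    return RankedList.from_scores("RFF", weights)


def rank_all(
    d: Dataset,
    n_bins: int = 10,
    relieff_k: int = 10,
    seed: int = 0,
) -> dict[str, RankedList]:
    """All four rankings keyed by method name, in the canonical order."""
    return {
        "MI": rank_mutual_information(d, n_bins),
        "CS": rank_chi_square(d, n_bins),
        "RFF": rank_relieff(d, k_neighbors=relieff_k, seed=seed),
        "XV": rank_xvariance(d),
    }
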