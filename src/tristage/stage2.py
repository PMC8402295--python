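"""Phase 2: Pearson-correlation redundancy pruning and re-truncation.

Among the Phase-1 features, any pair whose absolute Pearson correlation
exceeds the threshold (default 0.7) is considered redundant; the member less
correlated with the class is discarded. Pairs are visited in the Phase-1
accuracy rank order and only tested between currently-kept features, so a
feature whose only redundant partner was already discarded survives. The
surviving features are then re-truncated with the same plateau rule as
Phase 1 to give the top-j subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset
from .stage1 import StageResult, plateau_select


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise feature correlations plus feature-to-class correlations.

    ``features`` holds the dataset column indices, in the order the matrix
    rows refer to them. Constant features get correlation 0 everywhere.
    """

    features: np.ndarray
    r: np.ndarray
    class_r: np.ndarray


@dataclass(frozen=True)
class PruneResult:
    kept: np.ndarray
    discarded: list  # (discarded_feature, retained_feature, r_value)

    def to_dict(self, feature_names=None) -> dict:
        def name(i):
            return str(feature_names[i]) if feature_names is not None else int(i)

        return {
            "kept": [name(i) for i in self.kept],
            "discarded": [
                {"feature": name(a), "against": name(b), "r": float(r)}
                for a, b, r in self.discarded
            ],
        }


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    _, codes = np.unique(labels, return_inverse=True)
    return codes.astype(float)


def correlation_matrix(d: Dataset, features) -> CorrelationMatrix:
    """Pairwise Pearson r over the given features, and each feature's
    Pearson r against the integer-encoded class (binary: 0/1)."""
    features = np.asarray(list(features), dtype=int)
    if features.size < 2:
        raise ValueError("need at least 2 features")
    if d.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = d.features[:, features]
    sd = X.std(axis=0)
    constant = sd == 0
    y = _encode_labels(d.labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        stack = np.corrcoef(np.column_stack([X, y]), rowvar=False)
    r = stack[: features.size, : features.size]
    class_r = stack[: features.size, -1]
    r = np.where(np.isnan(r), 0.0, r)
    class_r = np.where(np.isnan(class_r), 0.0, class_r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    class_r[constant] = 0.0
    return CorrelationMatrix(features, r, class_r)


def prune_correlated(cm: CorrelationMatrix, threshold: float = 0.7) -> PruneResult:
    """Greedy redundancy pruning in rank order.

    For each pair (outer index ascending, inner ascending) with both members
    still kept and |r| strictly above the threshold, the member with the
    smaller |class_r| is discarded; on a tie the later-ranked one goes.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    k = cm.features.size
    kept = np.ones(k, dtype=bool)
    discarded = []
    for i in range(k):
        if not kept[i]:
            continue
        for j in range(i + 1, k):
            if not (kept[i] and kept[j]):
                continue
            if abs(cm.r[i, j]) > threshold:
                # earlier rank wins ties on |class_r|
                if abs(cm.class_r[j]) > abs(cm.class_r[i]):
                    drop, keep = i, j
                else:
                    drop, keep = j, i
                kept[drop] = False
                discarded.append(
                    (int(cm.features[drop]), int(cm.features[keep]), float(cm.r[i, j]))
                )
            if not kept[i]:
                break
    return PruneResult(cm.features[kept], discarded)


def select_top_j(
    d: Dataset,
    kept_features,
    coarse_step: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
    evaluator=None,
) -> StageResult:
    """Plateau truncation of the pruned, rank-ordered feature list
    (same contract as Phase 1's prefix selection)."""
    return plateau_select(
        d,
        kept_features,
        coarse_step=coarse_step,
        cv_folds=cv_folds,
        seed=seed,
        evaluator=evaluator,
    )
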