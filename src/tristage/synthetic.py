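"""Synthetic gene-expression-like classification tables with planted truth.

Emulates the shape of small-sample microarray studies: tens of samples,
hundreds of features, two classes, a handful of class-informative features,
correlated redundant copies of each, and a large majority of independent
noise features. Every stage of the selection pipeline can be validated
against the planted ground truth without external downloads.

Defaults match the package's reference recovery experiment: 60 samples,
500 features of which 5 are informative (standardized mean shift 1.5
between classes) with 2 redundant copies each at correlation 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 60
    n_classes: int = 2
    n_informative: int = 5
    n_redundant_per_informative: int = 2
    n_noise: int = 485
    effect_size: float = 1.5
    redundancy_rho: float = 0.9
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_informative, self.n_redundant_per_informative, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class")
        if not (-1 < self.redundancy_rho < 1):
            raise ValueError("redundancy_rho must be in (-1, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_informative * (1 + self.n_redundant_per_informative) + self.n_noise


@dataclass(frozen=True)
class GroundTruth:
    """Planted feature roles; the three index sets partition all columns."""

    informative_indices: np.ndarray
    redundancy_groups: dict = field(default_factory=dict)
    noise_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def group_members(self, informative_index: int) -> np.ndarray:
        copies = self.redundancy_groups.get(int(informative_index), [])
        return np.array([int(informative_index), *copies], dtype=int)

    def to_json(self, path) -> None:
        payload = {
            "informative_indices": [int(i) for i in self.informative_indices],
            "redundancy_groups": {
                str(k): [int(v) for v in vals]
                for k, vals in self.redundancy_groups.items()
            },
            "noise_indices": [int(i) for i in self.noise_indices],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Sample a dataset from the planted model.

    Informative features are class-conditional normals (unit variance,
    class means spaced ``effect_size`` apart). Each redundant copy is
    ``rho * x + sqrt(1 - rho^2) * sigma_x * eps`` so its population
    correlation with its source is exactly ``redundancy_rho``. Noise
    features are iid standard normal, independent of the class. Columns are
    then shuffled (seeded) so feature order carries no signal.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    # near-balanced classes, deterministic assignment
    labels = np.array([f"C{i % spec.n_classes}" for i in range(n)], dtype=object)

    class_codes = np.array([i % spec.n_classes for i in range(n)])
    class_means = np.arange(spec.n_classes, dtype=float) * spec.effect_size
    centered = class_means - class_means.mean()
    # total variance of an informative feature: within (1) + between classes
    var_between = float(np.mean(centered**2))
    sigma_x = np.sqrt(1.0 + var_between)

    columns = []
    informative, groups, noise_idx = [], {}, []
    for g in range(spec.n_informative):
        x = centered[class_codes] + rng.normal(size=n)
        informative.append(len(columns))
        columns.append(x)
        copies = []
        for _ in range(spec.n_redundant_per_informative):
            eps = rng.normal(size=n)
            copies.append(len(columns))
            columns.append(
                spec.redundancy_rho * x
                + np.sqrt(1.0 - spec.redundancy_rho**2) * sigma_x * eps
            )
        groups[informative[-1]] = copies
    for _ in range(spec.n_noise):
        noise_idx.append(len(columns))
        columns.append(rng.normal(size=n))

    X = np.column_stack(columns) if columns else np.empty((n, 0))
    perm = rng.permutation(p)
    where = np.empty(p, dtype=int)  # original position -> shuffled column
    where[perm] = np.arange(p)
    X = X[:, perm]

    if spec.missing_rate > 0:
        miss = rng.random(X.shape) < spec.missing_rate
        # never blank out an entire feature or a whole (class, feature) cell
        for c in range(spec.n_classes):
            rows = np.flatnonzero(class_codes == c)
            all_gone = miss[rows].all(axis=0)
            miss[rows[0], all_gone] = False
        X = np.where(miss, np.nan, X)

    names = np.array([f"gene_{j:04d}" for j in range(p)], dtype=object)
    truth = GroundTruth(
        informative_indices=where[np.array(informative, dtype=int)]
        if informative
        else np.array([], dtype=int),
        redundancy_groups={
            int(where[k]): [int(where[v]) for v in vals] for k, vals in groups.items()
        },
        noise_indices=where[np.array(noise_idx, dtype=int)]
        if noise_idx
        else np.array([], dtype=int),
    )
    return Dataset(X, labels, names), truth


def recovery_score(selected_features, truth: GroundTruth) -> float:
    """Fraction of planted informative groups represented in a selection.

    A group counts as recovered if the selection contains its informative
    feature or any of its redundant copies.
    """
    if truth.informative_indices.size == 0:
        return 1.0
    selected = set(int(i) for i in np.asarray(list(selected_features), dtype=int))
    hit = sum(
        1
        for g in truth.informative_indices
        if selected & set(truth.group_members(g).tolist())
    )
    return hit / truth.informative_indices.size
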