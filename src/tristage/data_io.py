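"""Dataset container, tabular loaders, and preprocessing.

The preprocessing contract mirrors how microarray-style tables are usually
prepared for filter ranking: missing entries are imputed with class-wise
feature means, then every feature is z-scored and min-max rescaled to [0, 1]
so that distance-based rankers see commensurate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

#: Cell values treated as missing when reading CSV files.
MISSING_SENTINELS = {"?", "", "NA"}


class DataError(ValueError):
    """Raised for malformed or unusable input tables."""


@dataclass(frozen=True)
class Dataset:
    """A numeric feature matrix with one categorical label per sample.

    Attributes
    ----------
    features : ndarray, shape (n_samples, n_features)
        Real-valued matrix; NaN marks missing cells before imputation.
    labels : ndarray, shape (n_samples,)
        Class identifiers, kept as opaque categories (strings or numbers).
    feature_names : ndarray of str, shape (n_features,)
    missing_mask : ndarray of bool, shape (n_samples, n_features)
        True where the original table had a missing cell.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        names = np.asarray(self.feature_names, dtype=object)
        mask = self.missing_mask
        if mask is None:
            mask = np.isnan(features)
        mask = np.asarray(mask, dtype=bool)
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "missing_mask", mask)
        self._validate()

    def _validate(self) -> None:
        if self.features.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        n, p = self.features.shape
        if self.labels.shape != (n,):
            raise DataError(
                f"labels has {self.labels.shape[0] if self.labels.ndim else 0} "
                f"entries for {n} sample rows"
            )
        if self.feature_names.shape != (p,):
            raise DataError("feature_names count must equal feature columns")
        if len(set(map(str, self.feature_names))) != p:
            raise DataError("feature_names must be unique")
        if self.missing_mask.shape != (n, p):
            raise DataError("missing_mask shape must match features")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise DataError("at least 2 distinct classes are required")
        if counts.min() < 2:
            raise DataError("every class needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def load_tabular(path, label_column: str, dialect: str = "csv") -> Dataset:
    """Read a CSV or ARFF classification table into a :class:`Dataset`.

    Non-label columns must parse as numeric; the sentinels ``"?"``, ``""``
    and ``"NA"`` (CSV) or ``?`` (ARFF) mark missing cells.
    """
    if dialect == "csv":
        frame = pd.read_csv(
            path,
            na_values=sorted(MISSING_SENTINELS),
            keep_default_na=False,
            skipinitialspace=True,
        )
    elif dialect == "arff":
        data, meta = scipy_arff.loadarff(path)
        frame = pd.DataFrame(data)
        for col in frame.columns:
            if frame[col].dtype == object:
                decoded = frame[col].str.decode("utf-8")
                frame[col] = decoded.replace("?", np.nan)
    else:
        raise DataError(f"unknown dialect {dialect!r}")

    if label_column not in frame.columns:
        raise DataError(f"label column {label_column!r} not found in {path}")
    labels = frame[label_column].to_numpy()
    if pd.isna(labels).any():
        raise DataError("label column contains missing values")
    feats = frame.drop(columns=[label_column])
    names = feats.columns.to_numpy(dtype=object)
    if len(set(names)) != len(names):
        raise DataError("duplicate feature names in header")
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = [
        str(c)
        for c in numeric.columns
        if numeric[c].isna().all() or (numeric[c].isna() & feats[c].notna()).any()
    ]
    if bad:
        raise DataError(f"non-numeric feature columns: {bad}")
    matrix = numeric.to_numpy(dtype=float)
    return Dataset(matrix, labels, names, np.isnan(matrix))


def impute_classwise_mean(d: Dataset) -> Dataset:
    """Replace missing cells with the feature mean within the same class.

    A (class, feature) group with no observed value falls back to the global
    feature mean. A feature missing in every sample cannot be imputed.
    """
    if not d.missing_mask.any():
        return d
    X = d.features.copy()
    observed = ~d.missing_mask
    if not observed.any(axis=0).all():
        dead = d.feature_names[~observed.any(axis=0)]
        raise DataError(f"features entirely missing: {list(map(str, dead))}")
    filled = np.where(observed, X, 0.0)
    global_mean = filled.sum(axis=0) / observed.sum(axis=0)
    for cls in d.classes:
        rows = d.labels == cls
        counts = observed[rows].sum(axis=0)
        class_mean = np.where(
            counts > 0,
            filled[rows].sum(axis=0) / np.maximum(counts, 1),
            global_mean,
        )
        block = X[rows]
        block[d.missing_mask[rows]] = np.broadcast_to(class_mean, block.shape)[
            d.missing_mask[rows]
        ]
        X[rows] = block
    return replace(d, features=X)


def standardize_then_normalize(d: Dataset) -> Dataset:
    """Z-score every feature (sample sd, n-1) then min-max rescale to [0, 1].

    Constant columns map to all-0.5 so they stay inert for distance-based
    rankers. Requires a fully imputed matrix.
    """
    if np.isnan(d.features).any():
        raise DataError("matrix contains missing values; impute first")
    X = d.features
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd_safe
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    span = np.where(constant, 1.0, hi - lo)
    out = (Z - lo) / span
    out[:, constant] = 0.5
    return replace(d, features=out)


def preprocess(d: Dataset) -> Dataset:
    """Full pipeline order: impute, then standardize + normalize."""
    return standardize_then_normalize(impute_classwise_mean(d))


def write_csv(d: Dataset, path, label_column: str = "class") -> None:
    """Write a Dataset back to CSV (missing cells as empty)."""
    frame = pd.DataFrame(d.features, columns=[str(n) for n in d.feature_names])
    frame = frame.mask(d.missing_mask)
    frame[label_column] = d.labels
    frame.to_csv(path, index=False)
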