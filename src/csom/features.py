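"""Descriptor-table preparation: correlation pruning, sigmoid scaling,
and a linear (SVD) auto-associative reduction.

These operators prepare molecular-descriptor tables for mapping: redundant
descriptors (|Pearson r| above a cutoff, default 0.9) are removed, the
survivors are squashed into (0, 1) with a per-feature logistic curve
centered on the training mean, and optionally projected onto the top
right-singular vectors of the centered table — the linear autoencoder that
minimizes reconstruction error among all rank-``n_out`` maps. All
parameters are fit on training data and reusable on test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass
class FeatureTable:
    """Numeric feature matrix with aligned, unique column names."""

    values: np.ndarray  # (n_examples, n_features)
    feature_names: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Column subset by name, in the requested order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.values[:, idx], list(names))


def prune_correlated(t: FeatureTable, r_max: float = 0.9) -> FeatureTable:
    """Drop columns whose |Pearson r| with an already-kept column exceeds ``r_max``.

    Columns are scanned left to right and the earlier column of a redundant
    pair is kept, so the result is order-preserving and idempotent.
    Constant columns have undefined correlation; they are treated as r=0,
    kept, and a warning is emitted.
    """
    if t.n_examples < 2:
        raise ValueError("need at least 2 examples to estimate correlations")
    if not (0 < r_max <= 1):
        raise ValueError("r_max must be in (0, 1]")
    X = t.values
    std = X.std(axis=0)
    constant = std == 0
    if constant.any():
        names = [n for n, c in zip(t.feature_names, constant) if c]
        warnings.warn(f"constant feature(s) kept with undefined correlation: {names}")
    # correlation with constant columns defined as 0
    Xc = X - X.mean(axis=0)
    denom = np.where(std > 0, std, 1.0) * np.sqrt(X.shape[0])
    Z = Xc / denom
    corr = Z.T @ Z
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)

    kept: List[int] = []
    for j in range(t.n_features):
        if all(abs(corr[j, i]) <= r_max for i in kept):
            kept.append(j)
    return FeatureTable(X[:, kept], [t.feature_names[j] for j in kept])


@dataclass
class SigmoidScaler:
    """Per-feature logistic squashing x -> 1 / (1 + exp(-(x - center)/slope))."""

    center: np.ndarray  # per-feature mean at fit time
    slope: np.ndarray  # per-feature std at fit time (1.0 where degenerate)

    def transform(self, t: FeatureTable) -> FeatureTable:
        if t.n_features != self.center.shape[0]:
            raise ValueError("feature count does not match fitted scaler")
        z = (t.values - self.center) / self.slope
        return FeatureTable(1.0 / (1.0 + np.exp(-z)), list(t.feature_names))


def sigmoid_scale(t: FeatureTable) -> Tuple[FeatureTable, SigmoidScaler]:
    """Fit and apply the sigmoid scaling; returns (scaled table, scaler).

    The curve is centered on each feature's mean with slope equal to its
    standard deviation, so the training mean maps to exactly 0.5 and all
    outputs lie strictly in (0, 1). Zero-variance features get slope 1 with
    a warning.
    """
    if t.n_examples < 2:
        raise ValueError("need at least 2 examples to fit the scaler")
    center = t.values.mean(axis=0)
    slope = t.values.std(axis=0)
    if (slope == 0).any():
        names = [n for n, s in zip(t.feature_names, slope) if s == 0]
        warnings.warn(f"zero-variance feature(s), slope set to 1: {names}")
        slope = np.where(slope > 0, slope, 1.0)
    scaler = SigmoidScaler(center=center, slope=slope)
    return scaler.transform(t), scaler


@dataclass
class ReducerModel:
    """Rank-``n_out`` linear reduction fitted by SVD on centered data.

    ``components`` has orthonormal columns (top right-singular vectors);
    scores are ``(X - center) @ components`` and the reconstruction
    ``scores @ components.T + center`` is Frobenius-optimal among all
    rank-``n_out`` linear maps.
    """

    center: np.ndarray  # (n_features,)
    components: np.ndarray  # (n_features, n_out)

    @property
    def n_out(self) -> int:
        return self.components.shape[1]


def fit_reducer(t: FeatureTable, n_out: int = 10) -> ReducerModel:
    """Fit the SVD reduction to ``n_out`` output variables."""
    if not (1 <= n_out <= min(t.n_examples, t.n_features)):
        raise ValueError(
            f"n_out must be in [1, min(n_examples, n_features)]; "
            f"got {n_out} for {t.n_examples}x{t.n_features}"
        )
    center = t.values.mean(axis=0)
    _, _, vt = np.linalg.svd(t.values - center, full_matrices=False)
    return ReducerModel(center=center, components=vt[:n_out].T.copy())


def apply_reducer(model: ReducerModel, t: FeatureTable) -> FeatureTable:
    """Project a table onto the fitted components."""
    if t.n_features != model.center.shape[0]:
        raise ValueError("feature count does not match fitted reducer")
    scores = (t.values - model.center) @ model.components
    names = [f"z{i}" for i in range(model.n_out)]
    return FeatureTable(scores, names)
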