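"""Validation protocol: stratified k-fold CV, k-NN baselines (in raw feature
space or on SOM coordinates), and paired significance testing.

The cross-validation harness mirrors the protocol used to compare the
consensus mapper against nearest-neighbor classification: resampling (e.g.
SMOTE) is fit on the training portion of each fold only, the model is fit,
and the held-out portion is scored with the imbalance-aware metrics. The
paired Student t-test compares the per-fold mean-recall series of two
methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .consensus import (
    NON_CONCLUSIVE,
    CsomModel,
    Prediction,
    fit_csom,
    predict_batch,
)
from .data import LabelledDataset
from .imbalance import (
    MetricsReport,
    balanced_target_counts,
    compute_metrics,
    random_undersample,
    smote,
    tally,
)
from .som import Coordinate, SomConfig, SomGrid, project, torus_distance, train_som

METHODS = ("csom", "som+knn", "knn")


class ZeroVarianceError(ValueError):
    """Raised when a paired t statistic is undefined (zero-variance, nonzero-mean
    differences)."""


@dataclass
class CvResult:
    """Per-fold metrics for one method on one dataset."""

    method: str
    reports: List[MetricsReport]
    fold_of: np.ndarray  # example -> fold index
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.reports)

    def mean_recalls(self) -> np.ndarray:
        return np.array([r.mean_recall for r in self.reports])

    def summary(self) -> Dict[str, float]:
        keys = ("accuracy", "mean_recall", "gmean_recall", "f_measure", "pct_out")
        return {k: float(np.mean([r.to_dict()[k] for r in self.reports])) for k in keys}


@dataclass
class PairedTestResult:
    """Classical paired Student t-test on per-fold score series."""

    t_statistic: float
    p_value: float
    df: int
    mean_difference: float


def stratified_kfold(data: LabelledDataset, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each example to one of ``k`` folds, stratified by label set.

    Per stratum the members are shuffled and dealt round-robin starting at a
    seeded offset, so per-stratum fold sizes differ by at most one. Strata
    smaller than ``k`` are spread round-robin with a warning rather than
    rejected (unavoidable under extreme imbalance).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(data.n_examples, -1, dtype=int)
    groups: Dict[frozenset, List[int]] = {}
    for i, ls in enumerate(data.labels):
        groups.setdefault(ls, []).append(i)
    for ls in sorted(groups, key=lambda s: sorted(s)):
        idx = np.array(groups[ls])
        if len(idx) < k:
            warnings.warn(
                f"stratum {sorted(ls)} has {len(idx)} member(s) for {k} folds; "
                "spreading round-robin"
            )
        rng.shuffle(idx)
        offset = int(rng.integers(k))
        for j, i in enumerate(idx):
            folds[i] = (offset + j) % k
    return folds


def _train_bmu_coords(grid: SomGrid, train: LabelledDataset) -> List[Coordinate]:
    occ = project(grid, train)
    coords: List[Optional[Coordinate]] = [None] * train.n_examples
    for c, members in occ.cells.items():
        for i in members:
            coords[i] = c
    return coords  # type: ignore[return-value]


def _vote(
    train: LabelledDataset, neighbor_idx: Sequence[int]
) -> Prediction:
    """Majority vote over neighbors; multi-label neighbors split their vote.

    Vote ties break toward the smallest class index; the result is always
    conclusive with probabilities equal to vote fractions.
    """
    votes = np.zeros(train.n_classes)
    dists = train.label_distributions()
    for i in neighbor_idx:
        votes += dists[i]
    probs = votes / votes.sum()
    best = int(np.argmax(probs))  # argmax takes the first (smallest) index on ties
    return Prediction(probabilities=probs, decision=train.class_names[best])


def knn_classify_batch(
    train: LabelledDataset,
    X: np.ndarray,
    k: int = 5,
    space: str = "raw",
    grid: Optional[SomGrid] = None,
) -> List[Prediction]:
    """k-NN classification of the rows of ``X`` against a training set.

    ``space="raw"`` uses Euclidean distance on the features; ``space="som"``
    maps everything through a trained grid and measures torus distance
    between BMU coordinates. Distance ties at the k-th neighbor include all
    co-distant training points.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train.n_examples:
        raise ValueError(f"k={k} exceeds the {train.n_examples} training examples")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if space == "raw":
        D = cdist(X, train.X)
    elif space == "som":
        if grid is None:
            raise ValueError("som space requires a trained grid")
        w, h = grid.config.width, grid.config.height
        train_coords = _train_bmu_coords(grid, train)
        Xs = (X - grid.scaler_mean) / grid.scaler_scale
        W = grid.weights
        d2 = (
            np.einsum("ij,ij->i", Xs, Xs)[:, None]
            - 2.0 * Xs @ W.T
            + np.einsum("ij,ij->i", W, W)[None, :]
        )
        q_coords = [grid.coordinate(int(b)) for b in np.argmin(d2, axis=1)]
        D = np.array(
            [[torus_distance(q, t, w, h) for t in train_coords] for q in q_coords]
        )
    else:
        raise ValueError(f"unknown space {space!r}")
    out = []
    for row in D:
        kth = np.partition(row, k - 1)[k - 1]
        neighbors = np.flatnonzero(row <= kth + 1e-12)
        out.append(_vote(train, neighbors))
    return out


def knn_classify(
    train: LabelledDataset,
    x: np.ndarray,
    k: int = 5,
    space: str = "raw",
    grid: Optional[SomGrid] = None,
) -> Prediction:
    """Single-query convenience wrapper around :func:`knn_classify_batch`."""
    return knn_classify_batch(train, np.atleast_2d(x), k=k, space=space, grid=grid)[0]


def _resample(
    train: LabelledDataset, resampling: Optional[str], seed: int
) -> LabelledDataset:
    if resampling is None:
        return train
    if resampling == "smote":
        return smote(train, balanced_target_counts(train), seed=seed)
    if resampling == "undersample":
        counts = {k: min(len(v) for v in _counts(train).values())
                  for k in _counts(train)}
        return random_undersample(train, counts, seed=seed)
    raise ValueError(f"unknown resampling {resampling!r}")


def _counts(data: LabelledDataset):
    from .imbalance import _strata

    return _strata(data)


def cross_validate(
    method: str,
    data: LabelledDataset,
    config: SomConfig,
    n_folds: int = 10,
    seed: int = 0,
    n_runs: int = 10,
    threshold: float = 0.9,
    resampling: Optional[str] = "smote",
    knn_k: int = 5,
) -> CvResult:
    """Run the full per-fold protocol for one method.

    Per fold: resampling is fit on the training portion only, the model is
    fit (``csom`` = consensus mapper; ``som+knn`` = one SOM plus k-NN on BMU
    coordinates; ``knn`` = k-NN on raw features), and the held-out portion
    is tallied and scored. Deterministic end-to-end for fixed seeds.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    folds = stratified_kfold(data, k=n_folds, seed=seed)
    reports: List[MetricsReport] = []
    for f in range(n_folds):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        fold_seed = seed * 1009 + f
        train = _resample(train, resampling, seed=fold_seed)
        cfg = SomConfig(**{**config.to_dict(), "seed": fold_seed})
        if method == "csom":
            model = fit_csom(train, cfg, n_runs=n_runs, threshold=threshold)
            preds = predict_batch(model, test.X)
        elif method == "som+knn":
            grid = train_som(train, cfg)
            preds = knn_classify_batch(train, test.X, k=knn_k, space="som", grid=grid)
        else:
            preds = knn_classify_batch(train, test.X, k=knn_k, space="raw")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(
                compute_metrics(tally(test.labels, preds, data.class_names))
            )
    return CvResult(method=method, reports=reports, fold_of=folds, seed=seed)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Student t-test on matched score series.

    Identical series give t = 0, p = 1. Differences with zero variance but
    nonzero mean leave the statistic undefined and raise
    :class:`ZeroVarianceError` rather than returning a silent 0 or 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length series with at least 2 entries")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTestResult(t_statistic=0.0, p_value=1.0, df=n - 1,
                                    mean_difference=0.0)
        raise ZeroVarianceError(
            "paired differences are constant and nonzero; t is undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(
        t_statistic=float(t), p_value=float(p), df=n - 1,
        mean_difference=float(d.mean()),
    )
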