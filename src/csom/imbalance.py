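"""Resampling for imbalanced data and imbalance-aware evaluation metrics.

SMOTE oversampling synthesizes minority-class points on random segments
between a minority example and one of its k nearest same-class neighbors;
random undersampling thins majority classes by seeded sampling without
replacement. Metrics center on per-class recall (its arithmetic and
geometric means are insensitive to class sizes, unlike accuracy) plus a
macro-averaged F measure, with non-conclusive predictions kept out of the
confusion matrix and reported separately as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Union

import numpy as np

from .consensus import NON_CONCLUSIVE, Prediction
from .data import LABEL_SEPARATOR, LabelledDataset
from .features import FeatureTable

_EPS = 1e-12


class ResamplingError(ValueError):
    """Raised when a resampling request cannot be satisfied."""


class AllNonConclusiveError(ValueError):
    """Raised when metrics are requested but no prediction was conclusive."""


def _stratum_key(labels: FrozenSet[str]) -> str:
    return LABEL_SEPARATOR.join(sorted(labels))


def _strata(data: LabelledDataset) -> Dict[str, List[int]]:
    """Example indices grouped by exact label set (multi-label sets form
    their own stratum, keyed by the '|'-joined sorted labels)."""
    groups: Dict[str, List[int]] = {}
    for i, ls in enumerate(data.labels):
        groups.setdefault(_stratum_key(ls), []).append(i)
    return groups


def balanced_target_counts(data: LabelledDataset) -> Dict[str, int]:
    """Target counts that raise every stratum to the size of the largest."""
    groups = _strata(data)
    top = max(len(v) for v in groups.values())
    return {k: top for k in groups}


def smote(
    data: LabelledDataset,
    target_counts: Dict[str, int],
    k: int = 5,
    seed: int = 0,
) -> LabelledDataset:
    """Oversample minority classes with synthetic points on neighbor segments.

    For every needed synthetic point a seeded-random class member ``x`` and
    one of its ``k`` nearest same-class neighbors ``x'`` (Euclidean) are
    chosen and the point ``x + u (x' - x)`` with ``u ~ U[0, 1]`` is emitted.
    Originals are preserved verbatim and come first; output class counts
    equal ``target_counts`` exactly. Classes with fewer than ``k + 1``
    members use all available neighbors.
    """
    if k < 1:
        raise ResamplingError("k must be >= 1")
    rng = np.random.default_rng(seed)
    groups = _strata(data)
    X = data.X
    new_rows: List[np.ndarray] = []
    new_labels: List[FrozenSet[str]] = []
    for key in sorted(target_counts):
        if key not in groups:
            raise ResamplingError(f"unknown class {key!r} in target counts")
        idx = groups[key]
        deficit = target_counts[key] - len(idx)
        if deficit < 0:
            raise ResamplingError(
                f"class {key!r}: target {target_counts[key]} below current count {len(idx)}"
            )
        if deficit == 0:
            continue
        if len(idx) < 2:
            raise ResamplingError(
                f"class {key!r} has {len(idx)} example(s); SMOTE needs at least 2"
            )
        pts = X[idx]
        # pairwise distances within the class; k nearest excluding self
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        kk = min(k, len(idx) - 1)
        nn = np.argsort(d2, axis=1)[:, :kk]
        label = frozenset(key.split(LABEL_SEPARATOR))
        for _ in range(deficit):
            a = rng.integers(len(idx))
            b = nn[a][rng.integers(kk)]
            u = rng.random()
            new_rows.append(pts[a] + u * (pts[b] - pts[a]))
            new_labels.append(label)
    if not new_rows:
        return data
    values = np.vstack([X, np.array(new_rows)])
    return LabelledDataset(
        features=FeatureTable(values, list(data.features.feature_names)),
        labels=list(data.labels) + new_labels,
        class_names=list(data.class_names),
    )


def random_undersample(
    data: LabelledDataset,
    target_counts: Dict[str, int],
    seed: int = 0,
) -> LabelledDataset:
    """Seeded uniform subsample without replacement per class; counts exact.

    Classes absent from ``target_counts`` are kept untouched. Row order of
    the retained examples is preserved.
    """
    rng = np.random.default_rng(seed)
    groups = _strata(data)
    keep: List[int] = []
    for key in sorted(groups):
        idx = groups[key]
        if key not in target_counts:
            keep.extend(idx)
            continue
        want = target_counts[key]
        if want > len(idx):
            raise ResamplingError(
                f"class {key!r}: target {want} exceeds available {len(idx)}"
            )
        chosen = rng.choice(len(idx), size=want, replace=False)
        keep.extend(idx[i] for i in sorted(chosen))
    keep.sort()
    return data.subset(keep)


@dataclass
class ConfusionResult:
    """Confusion counts over conclusive predictions plus the non-conclusive tally."""

    matrix: np.ndarray  # (n_classes, n_classes); rows = true, cols = predicted
    n_nonconclusive: int
    n_total: int
    class_names: List[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.sum() + self.n_nonconclusive != self.n_total:
            raise ValueError("matrix sum plus non-conclusive count must equal n_total")
        if (self.matrix < 0).any() or self.n_nonconclusive < 0:
            raise ValueError("counts must be non-negative")


def tally(
    y_true: Sequence[Union[str, FrozenSet[str]]],
    predictions: Sequence[Prediction],
    class_names: Sequence[str],
) -> ConfusionResult:
    """Build the confusion bookkeeping from gated predictions.

    Non-conclusive predictions are counted only in ``n_nonconclusive``.
    Multi-label truths are credited when the decision hits any of their
    labels; a conclusive miss on a multi-label truth is charged to the
    truth's first label in vocabulary order.
    """
    if len(y_true) != len(predictions):
        raise ValueError("y_true and predictions must have equal length")
    index = {c: j for j, c in enumerate(class_names)}
    n = len(class_names)
    m = np.zeros((n, n), dtype=int)
    n_out = 0
    for t, p in zip(y_true, predictions):
        tset = frozenset([t]) if isinstance(t, str) else frozenset(t)
        for lab in tset:
            if lab not in index:
                raise ValueError(f"unknown true label {lab!r}")
        if not p.conclusive:
            n_out += 1
            continue
        if p.decision not in index:
            raise ValueError(f"unknown predicted label {p.decision!r}")
        j = index[p.decision]
        if p.decision in tset:
            i = j
        else:
            i = min(index[lab] for lab in tset)
        m[i, j] += 1
    return ConfusionResult(
        matrix=m, n_nonconclusive=n_out, n_total=len(y_true),
        class_names=list(class_names),
    )


@dataclass
class MetricsReport:
    """Imbalance-aware summary of one evaluation."""

    accuracy: float
    mean_recall: float
    gmean_recall: float
    f_measure: float
    pct_out: float
    zero_recall_classes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mean_recall": self.mean_recall,
            "gmean_recall": self.gmean_recall,
            "f_measure": self.f_measure,
            "pct_out": self.pct_out,
        }


def compute_metrics(c: ConfusionResult) -> MetricsReport:
    """Accuracy, arithmetic/geometric mean recall, and macro F over conclusive
    predictions; the non-conclusive fraction is reported as ``pct_out``.

    Per-class recall of a class with no conclusive examples is 0; the
    geometric mean substitutes a tiny epsilon for zero recalls (flagged via
    ``zero_recall_classes``) instead of silently collapsing to 0.
    """
    m = c.matrix
    total = m.sum()
    if total == 0:
        raise AllNonConclusiveError(
            "no conclusive predictions; conclusive-set metrics are undefined"
        )
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    diag = np.diag(m).astype(float)
    recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
    precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
    with np.errstate(invalid="ignore"):
        f_per = np.where(
            precision + recall > 0,
            2 * precision * recall / np.maximum(precision + recall, _EPS),
            0.0,
        )
    zero_classes = [c.class_names[i] for i in range(len(recall)) if recall[i] == 0]
    if zero_classes:
        warnings.warn(
            f"class(es) with zero recall, geometric mean uses eps: {zero_classes}"
        )
    gmean = float(np.exp(np.mean(np.log(np.maximum(recall, _EPS)))))
    return MetricsReport(
        accuracy=float(diag.sum() / total),
        mean_recall=float(recall.mean()),
        gmean_recall=gmean,
        f_measure=float(f_per.mean()),
        pct_out=100.0 * c.n_nonconclusive / c.n_total,
        zero_recall_classes=zero_classes,
    )
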