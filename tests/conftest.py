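import numpy as np
import pytest

from csom import FeatureTable, LabelledDataset
from csom.som import Coordinate, OccupancyMap


def make_dataset(X, labels, class_names=None):
    """Build a LabelledDataset from a matrix and per-example label strings
    (or iterables of strings for multi-label examples)."""
    X = np.asarray(X, dtype=float)
    label_sets = [
        frozenset([ls]) if isinstance(ls, str) else frozenset(ls) for ls in labels
    ]
    if class_names is None:
        class_names = sorted({c for ls in label_sets for c in ls})
    return LabelledDataset(
        features=FeatureTable(X, [f"x{i}" for i in range(X.shape[1])]),
        labels=label_sets,
        class_names=list(class_names),
    )


def random_occupancy(rng, width, height, n_classes, n_examples=None):
    """A random partial occupancy plus per-example one-hot distributions.

    Returns (OccupancyMap, dists, oracle_input) where oracle_input maps
    (row, col) -> list of distribution vectors for the brute-force oracle.
    """
    if n_examples is None:
        n_examples = int(rng.integers(1, width * height))
    cells = {}
    oracle_input = {}
    dists = np.zeros((n_examples, n_classes))
    for i in range(n_examples):
        r = int(rng.integers(height))
        c = int(rng.integers(width))
        k = int(rng.integers(n_classes))
        dists[i, k] = 1.0
        cells.setdefault(Coordinate(r, c), []).append(i)
        oracle_input.setdefault((r, c), []).append(dists[i].copy())
    occ = OccupancyMap(cells=cells, n_examples=n_examples, width=width, height=height)
    return occ, dists, oracle_input


@pytest.fixture
def two_cluster_dataset():
    """Two well-separated 2-D Gaussian clusters, 30 examples each."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 0.3, size=(30, 2))
    b = rng.normal([10.0, 10.0], 0.3, size=(30, 2))
    return make_dataset(np.vstack([a, b]), ["a"] * 30 + ["b"] * 30)
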