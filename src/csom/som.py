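"""Toroidal self-organizing map: grid initialization, training, projection.

The map is a two-dimensional lattice of neurons whose opposite edges are
identified, so every neuron has a full neighborhood and no cell sits on a
boundary. Training is the classical online (per-presentation) Kohonen
update: for each example the best-matching unit (BMU) is found by Euclidean
distance in feature space, and every neuron within the current adaptation
radius of the BMU on the torus is pulled toward the example through a
Gaussian neighborhood kernel.

Schedules
---------
* learning rate: geometric interpolation ``lr_start -> lr_end`` over epochs;
  the effective rate is clamped to 1.0 inside the update so that
  ``w <- w + a*(x - w)`` remains a contraction even when the configured
  starting rate exceeds 1.
* adaptation radius: linear interpolation ``radius_start -> radius_end``.

Input features are standardized per feature (z-score) before training and
the scaler is stored on the grid, so all queries must go through
:meth:`SomGrid.scale`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Tuple

import numpy as np

try:  # pragma: no cover - exercised implicitly by whichever path is active
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class SomConfigError(ValueError):
    """Raised for invalid SOM configuration values."""


class Coordinate(NamedTuple):
    """0-based (row, col) position on the grid."""

    row: int
    col: int


@dataclass(frozen=True)
class SomConfig:
    """Training configuration for a toroidal SOM.

    Defaults follow the benchmark protocol used throughout this package:
    50 training rounds, learning rate decaying from 2.0 to 0.01 and an
    initial adaptation radius of 20 grid units shrinking to 1.
    """

    width: int = 20
    height: int = 20
    rounds: int = 50
    lr_start: float = 2.0
    lr_end: float = 0.01
    radius_start: float = 20.0
    radius_end: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise SomConfigError("grid dimensions must be positive")
        if self.rounds < 0:
            raise SomConfigError("rounds must be non-negative")
        if not (self.lr_start >= self.lr_end > 0):
            raise SomConfigError("require lr_start >= lr_end > 0")
        if not (self.radius_start >= self.radius_end > 0):
            raise SomConfigError("require radius_start >= radius_end > 0")

    @property
    def n_neurons(self) -> int:
        return self.width * self.height

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "rounds": self.rounds,
            "lr_start": self.lr_start,
            "lr_end": self.lr_end,
            "radius_start": self.radius_start,
            "radius_end": self.radius_end,
            "seed": self.seed,
        }


@dataclass
class SomGrid:
    """A (trained or freshly initialized) toroidal SOM.

    ``weights`` is row-major: neuron at ``(row, col)`` lives at index
    ``row * width + col``. ``scaler_mean``/``scaler_scale`` record the
    per-feature z-score parameters applied at fit time (identity until
    training).
    """

    config: SomConfig
    weights: np.ndarray  # (n_neurons, dim)
    scaler_mean: np.ndarray  # (dim,)
    scaler_scale: np.ndarray  # (dim,)

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def coordinate(self, index: int) -> Coordinate:
        return Coordinate(index // self.config.width, index % self.config.width)

    def index(self, c: Coordinate) -> int:
        return c.row * self.config.width + c.col

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Apply the stored per-feature z-score to raw feature values."""
        x = np.asarray(x, dtype=float)
        return (x - self.scaler_mean) / self.scaler_scale


@dataclass
class OccupancyMap:
    """Partition of training examples over grid cells by BMU."""

    cells: Dict[Coordinate, List[int]]
    n_examples: int
    width: int
    height: int

    def __post_init__(self) -> None:
        total = sum(len(v) for v in self.cells.values())
        if total != self.n_examples:
            raise ValueError(
                f"occupancy does not partition the data: {total} != {self.n_examples}"
            )


def _check_coordinate(c: Coordinate, width: int, height: int) -> None:
    if not (0 <= c[0] < height and 0 <= c[1] < width):
        raise ValueError(f"coordinate {tuple(c)} out of bounds for {height}x{width} grid")


def torus_distance(a: Coordinate, b: Coordinate, width: int, height: int) -> float:
    """Euclidean distance between two cells on the torus.

    Per axis the displacement is the shorter way around:
    ``min(|delta|, extent - |delta|)``.
    """
    _check_coordinate(a, width, height)
    _check_coordinate(b, width, height)
    dr = abs(a[0] - b[0])
    dr = min(dr, height - dr)
    dc = abs(a[1] - b[1])
    dc = min(dc, width - dc)
    return math.hypot(dr, dc)


def init_grid(config: SomConfig, dim: int) -> SomGrid:
    """Create a grid with weights i.i.d. uniform on [0, 1) from the seeded RNG.

    Deterministic for a fixed ``config.seed``; the scaler is identity.
    """
    if dim < 1:
        raise SomConfigError("feature dimension must be positive")
    rng = np.random.default_rng(config.seed)
    weights = rng.random((config.n_neurons, dim))
    return SomGrid(
        config=config,
        weights=weights,
        scaler_mean=np.zeros(dim),
        scaler_scale=np.ones(dim),
    )


def find_bmu(grid: SomGrid, x: np.ndarray) -> Coordinate:
    """Best-matching unit of an (already scaled) feature vector.

    Ties are broken toward the smallest (row, col) lexicographically, which
    for row-major storage is simply the first minimizing index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.dim,):
        raise ValueError(f"expected vector of dim {grid.dim}, got shape {x.shape}")
    diff = grid.weights - x
    idx = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
    return grid.coordinate(idx)


def _epoch_schedules(config: SomConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Per-epoch learning rate (geometric) and radius (linear)."""
    rounds = config.rounds
    if rounds == 0:
        return np.empty(0), np.empty(0)
    if rounds == 1:
        return np.array([config.lr_start]), np.array([config.radius_start])
    e = np.arange(rounds)
    frac = e / (rounds - 1)
    lr = config.lr_start * (config.lr_end / config.lr_start) ** frac
    radius = config.radius_start + (config.radius_end - config.radius_start) * frac
    return lr, radius


def _run_epoch_numpy(W, X, order, alpha, radius, rows, cols, width, height):
    r2 = radius * radius
    sig2 = 2.0 * (radius / 2.0) ** 2
    for i in order:
        x = X[i]
        diff = x - W
        bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
        dr = np.abs(rows - rows[bmu])
        dr = np.minimum(dr, height - dr)
        dc = np.abs(cols - cols[bmu])
        dc = np.minimum(dc, width - dc)
        d2 = (dr * dr + dc * dc).astype(float)
        mask = d2 <= r2
        h = np.exp(-d2[mask] / sig2)
        W[mask] += (alpha * h)[:, None] * diff[mask]


if _HAVE_NUMBA:

    @njit(cache=True)
    def _run_epoch_jit(W, X, order, alpha, radius, rows, cols, width, height):  # pragma: no cover
        n = order.shape[0]
        m, d = W.shape
        r2 = radius * radius
        sig2 = 2.0 * (radius / 2.0) ** 2
        for t in range(n):
            x = X[order[t]]
            best = 0
            bestd = np.inf
            for j in range(m):
                s = 0.0
                for c in range(d):
                    delta = x[c] - W[j, c]
                    s += delta * delta
                if s < bestd:
                    bestd = s
                    best = j
            br = rows[best]
            bc = cols[best]
            for j in range(m):
                dr = abs(rows[j] - br)
                if height - dr < dr:
                    dr = height - dr
                dc = abs(cols[j] - bc)
                if width - dc < dc:
                    dc = width - dc
                d2 = float(dr * dr + dc * dc)
                if d2 <= r2:
                    a = alpha * np.exp(-d2 / sig2)
                    for c in range(d):
                        W[j, c] += a * (x[c] - W[j, c])

    _run_epoch = _run_epoch_jit
else:  # pragma: no cover
    _run_epoch = _run_epoch_numpy


def train_som(data, config: SomConfig) -> SomGrid:
    """Fit a toroidal SOM on a labelled dataset (labels are never used).

    Features are z-scored per feature and the scaler stored on the returned
    grid. Each epoch visits the examples in a fresh seeded permutation;
    each presentation updates every neuron within the current adaptation
    radius of the BMU on the torus with a Gaussian kernel
    ``h = exp(-d^2 / (2 (r/2)^2))``. Deterministic for a fixed seed.
    """
    X = np.asarray(data.X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("training data must be a non-empty 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = np.ascontiguousarray((X - mean) / std)

    rng = np.random.default_rng(config.seed)
    W = rng.random((config.n_neurons, X.shape[1]))

    idx = np.arange(config.n_neurons)
    rows = (idx // config.width).astype(np.int64)
    cols = (idx % config.width).astype(np.int64)

    lr, radius = _epoch_schedules(config)
    for e in range(config.rounds):
        order = rng.permutation(X.shape[0]).astype(np.int64)
        alpha = min(1.0, float(lr[e]))  # keep the per-step update a contraction
        _run_epoch(W, Xs, order, alpha, float(radius[e]), rows, cols,
                   config.width, config.height)

    return SomGrid(config=config, weights=W, scaler_mean=mean, scaler_scale=std)


def project(grid: SomGrid, data) -> OccupancyMap:
    """Assign every example to the cell of its BMU."""
    X = np.asarray(data.X, dtype=float)
    if X.shape[1] != grid.dim:
        raise ValueError(f"dimension mismatch: data {X.shape[1]} vs grid {grid.dim}")
    Xs = (X - grid.scaler_mean) / grid.scaler_scale
    # squared Euclidean distances to every neuron, argmin row-wise
    d2 = (
        np.einsum("ij,ij->i", Xs, Xs)[:, None]
        - 2.0 * Xs @ grid.weights.T
        + np.einsum("ij,ij->i", grid.weights, grid.weights)[None, :]
    )
    bmus = np.argmin(d2, axis=1)
    cells: Dict[Coordinate, List[int]] = {}
    for i, b in enumerate(bmus):
        cells.setdefault(grid.coordinate(int(b)), []).append(i)
    return OccupancyMap(cells=cells, n_examples=X.shape[0],
                        width=grid.config.width, height=grid.config.height)


def quantization_error(grid: SomGrid, data) -> float:
    """Mean Euclidean distance from each (scaled) example to its BMU weight."""
    X = np.asarray(data.X, dtype=float)
    Xs = (X - grid.scaler_mean) / grid.scaler_scale
    d2 = (
        np.einsum("ij,ij->i", Xs, Xs)[:, None]
        - 2.0 * Xs @ grid.weights.T
        + np.einsum("ij,ij->i", grid.weights, grid.weights)[None, :]
    )
    return float(np.mean(np.sqrt(np.maximum(d2.min(axis=1), 0.0))))
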