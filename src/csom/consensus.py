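"""Consensus self-organizing maps: probability expansion over the toroidal
grid, consensus priors from repeated runs, and threshold-gated prediction.

After projecting labelled data onto a trained toroidal SOM, occupied cells
cover only part of the lattice. The *probability expansion* algorithm fills
every empty cell with a class-probability vector by wavefront propagation:
each occupied cell transfers its class content to the adjacent (Moore,
8-connected) unoccupied cells, contributions are summed and renormalized,
and cells filled at one wave act as unit-weight sources for the next, until
the whole torus is covered. Occupied cells keep their own (example-derived)
vectors and are never overwritten.

Because competitive learning starts from random weights, consecutive SOM
runs place examples differently. The *consensus prior* of a training
example is the average, over P independently seeded runs, of the normalized
class tally of its neighbors (same cell plus the Moore ring, itself
excluded). Examples that keep landing inside their own class get nearly
one-hot priors; examples that live on class boundaries get mixed ones.
These priors replace the hard labels inside the expansion, so boundary
examples spread their ambiguity into the map.

Prediction reads the probability vector at the BMU of a query point and
commits to the argmax class only when its probability strictly exceeds a
confidence threshold t; otherwise the query is reported as non-conclusive
rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .data import LabelledDataset
from .som import (
    Coordinate,
    OccupancyMap,
    SomConfig,
    SomGrid,
    _check_coordinate,
    find_bmu,
    project,
    train_som,
)

#: Sentinel decision for predictions whose best class probability does not
#: exceed the confidence threshold.
NON_CONCLUSIVE = "NON_CONCLUSIVE"


def moore_neighbors(c: Coordinate, width: int, height: int) -> Set[Coordinate]:
    """The 8 toroidally wrapped cells at Chebyshev distance 1 from ``c``.

    Never contains ``c`` itself; on grids smaller than 3 in an axis the
    wrapped positions coincide and the set deduplicates accordingly.
    """
    _check_coordinate(c, width, height)
    out: Set[Coordinate] = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            out.add(Coordinate((c[0] + dr) % height, (c[1] + dc) % width))
    out.discard(Coordinate(c[0], c[1]))
    return out


@dataclass
class ProbabilityMap:
    """Per-cell class-probability vectors covering the whole grid.

    ``probs`` has shape (height, width, n_classes); every cell's vector sums
    to 1. ``occupied`` flags the cells that held training examples — their
    vectors come straight from the examples and were frozen during
    expansion. ``wave`` records the expansion wave at which each cell was
    filled (0 for occupied cells).
    """

    probs: np.ndarray
    occupied: np.ndarray  # (height, width) bool
    wave: np.ndarray  # (height, width) int

    @property
    def height(self) -> int:
        return self.probs.shape[0]

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]


@dataclass
class PriorTable:
    """Per-example class distributions averaged over repeated SOM runs."""

    priors: np.ndarray  # (n_examples, n_classes)
    n_runs: int

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not np.allclose(self.priors.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every prior row must sum to 1")


@dataclass
class Prediction:
    """Class-probability vector plus the gated decision for one query."""

    probabilities: np.ndarray
    decision: str  # a class name, or NON_CONCLUSIVE

    @property
    def conclusive(self) -> bool:
        return self.decision != NON_CONCLUSIVE


@dataclass
class CsomModel:
    """A fitted consensus SOM classifier."""

    grid: SomGrid
    prob_map: ProbabilityMap
    priors: PriorTable
    threshold: float
    class_names: List[str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        if self.prob_map.probs.shape[:2] != (self.grid.config.height, self.grid.config.width):
            raise ValueError("probability map does not match the grid")


def expand_probabilities(
    occupancy: OccupancyMap,
    example_dists: np.ndarray,
    width: int,
    height: int,
) -> ProbabilityMap:
    """Fill every grid cell with a class-probability vector by wavefront expansion.

    Wave 0: each occupied cell's vector is the mean of its examples'
    distributions (equivalently the example-count-weighted average), and is
    frozen. Wave k >= 1: every still-empty cell with at least one filled
    Moore neighbor receives the weighted sum of those neighbors' vectors —
    weight = number of examples for occupied sources, 1 for expanded
    sources — renormalized to sum 1. All cells of a wave are computed
    simultaneously from the previous waves' state. The torus is connected,
    so the loop always terminates with a full map.
    """
    if not occupancy.cells:
        raise ValueError("occupancy is empty; nothing to expand")
    dists = np.asarray(example_dists, dtype=float)
    if dists.ndim != 2 or dists.shape[0] != occupancy.n_examples:
        raise ValueError("need one class distribution per projected example")
    if not np.allclose(dists.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("every example distribution must sum to 1")
    n_classes = dists.shape[1]

    probs = np.zeros((height, width, n_classes))
    weight = np.zeros((height, width))
    wave = np.full((height, width), -1, dtype=int)

    for c, members in occupancy.cells.items():
        _check_coordinate(c, width, height)
        probs[c[0], c[1]] = dists[members].sum(axis=0) / len(members)
        weight[c[0], c[1]] = len(members)
        wave[c[0], c[1]] = 0

    k = 0
    while (wave < 0).any():
        k += 1
        frontier: List[Tuple[Coordinate, np.ndarray]] = []
        for r in range(height):
            for col in range(width):
                if wave[r, col] >= 0:
                    continue
                acc = np.zeros(n_classes)
                found = False
                for nb in moore_neighbors(Coordinate(r, col), width, height):
                    if 0 <= wave[nb[0], nb[1]] < k:
                        acc += weight[nb[0], nb[1]] * probs[nb[0], nb[1]]
                        found = True
                if found:
                    frontier.append((Coordinate(r, col), acc))
        # commit the whole wave at once so cells of the same wave never feed
        # each other
        for c, acc in frontier:
            probs[c[0], c[1]] = acc / acc.sum()
            weight[c[0], c[1]] = 1.0
            wave[c[0], c[1]] = k

    return ProbabilityMap(probs=probs, occupied=(wave == 0), wave=wave)


def _neighbor_tallies(
    grid: SomGrid, data: LabelledDataset, dists: np.ndarray
) -> np.ndarray:
    """Per-example normalized class tally of BMU-cell + Moore-ring neighbors.

    Each neighbor contributes its own label distribution (one-hot for
    single-label examples, uniform over the set for multi-label ones); the
    example itself is excluded. Examples with no neighbors in a run fall
    back to their own distribution, so every row normalizes.
    """
    occ = project(grid, data)
    w, h = grid.config.width, grid.config.height
    n_classes = dists.shape[1]
    cell_sum: Dict[Coordinate, np.ndarray] = {}
    bmu_of: Dict[int, Coordinate] = {}
    for c, members in occ.cells.items():
        cell_sum[c] = dists[members].sum(axis=0)
        for i in members:
            bmu_of[i] = c
    out = np.zeros((data.n_examples, n_classes))
    for i in range(data.n_examples):
        c = bmu_of[i]
        tally = cell_sum[c] - dists[i]
        for nb in moore_neighbors(c, w, h):
            if nb in cell_sum:
                tally = tally + cell_sum[nb]
        total = tally.sum()
        if total <= 0:
            out[i] = dists[i]
        else:
            out[i] = tally / total
    return out


def consensus_priors(
    data: LabelledDataset,
    config: SomConfig,
    n_runs: int = 10,
    base_seed: Optional[int] = None,
) -> PriorTable:
    """Estimate per-example class priors from ``n_runs`` repeated SOM runs.

    Runs use seeds ``base_seed .. base_seed + n_runs - 1`` (default
    ``config.seed``). Per run, each example's neighbors (same BMU cell plus
    the 8 Moore-adjacent cells, itself excluded) are tallied by label and
    normalized; the tallies are averaged over runs. Around 10 runs is
    enough for the row distributions to stabilize.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    dists = data.label_distributions()
    acc = np.zeros((data.n_examples, data.n_classes))
    for p in range(n_runs):
        cfg = SomConfig(**{**config.to_dict(), "seed": base_seed + p})
        grid = train_som(data, cfg)
        acc += _neighbor_tallies(grid, data, dists)
    return PriorTable(priors=acc / n_runs, n_runs=n_runs)


def fit_csom(
    data: LabelledDataset,
    config: SomConfig,
    n_runs: int = 10,
    threshold: float = 0.9,
    base_seed: Optional[int] = None,
    priors: Optional[PriorTable] = None,
) -> CsomModel:
    """Fit the full consensus SOM classifier.

    Consensus priors are computed from ``n_runs`` repeated SOM runs, a fresh
    final SOM (seed ``base_seed + n_runs``) is trained, the training data is
    projected onto it, and the expansion is run with each example
    contributing its prior row instead of its hard label. Passing
    ``priors`` explicitly skips the consensus stage (useful for the
    reduction to plain label expansion).
    """
    if base_seed is None:
        base_seed = config.seed
    if priors is None:
        priors = consensus_priors(data, config, n_runs=n_runs, base_seed=base_seed)
    final_cfg = SomConfig(**{**config.to_dict(), "seed": base_seed + priors.n_runs})
    grid = train_som(data, final_cfg)
    occ = project(grid, data)
    prob_map = expand_probabilities(
        occ, priors.priors, grid.config.width, grid.config.height
    )
    return CsomModel(
        grid=grid,
        prob_map=prob_map,
        priors=priors,
        threshold=threshold,
        class_names=list(data.class_names),
    )


def predict(model: CsomModel, x: np.ndarray) -> Prediction:
    """Classify one raw feature vector, gating on the confidence threshold.

    The probability vector is read at the BMU cell of the (scaler-applied)
    query; the decision is the argmax class iff its probability strictly
    exceeds the threshold, otherwise the sentinel ``NON_CONCLUSIVE``.
    """
    xs = model.grid.scale(x)
    c = find_bmu(model.grid, xs)
    p = model.prob_map.probs[c.row, c.col]
    best = int(np.argmax(p))
    if p[best] > model.threshold:
        decision = model.class_names[best]
    else:
        decision = NON_CONCLUSIVE
    return Prediction(probabilities=p.copy(), decision=decision)


def predict_batch(model: CsomModel, X: np.ndarray) -> List[Prediction]:
    """Vectorized :func:`predict` over the rows of a feature matrix."""
    X = np.asarray(X, dtype=float)
    Xs = (X - model.grid.scaler_mean) / model.grid.scaler_scale
    W = model.grid.weights
    d2 = (
        np.einsum("ij,ij->i", Xs, Xs)[:, None]
        - 2.0 * Xs @ W.T
        + np.einsum("ij,ij->i", W, W)[None, :]
    )
    bmus = np.argmin(d2, axis=1)
    out = []
    width = model.grid.config.width
    for b in bmus:
        p = model.prob_map.probs[int(b) // width, int(b) % width]
        best = int(np.argmax(p))
        decision = model.class_names[best] if p[best] > model.threshold else NON_CONCLUSIVE
        out.append(Prediction(probabilities=p.copy(), decision=decision))
    return out
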