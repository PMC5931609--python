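import itertools

import numpy as np
import pytest

from csom import (
    SomConfig,
    find_bmu,
    init_grid,
    project,
    quantization_error,
    torus_distance,
    train_som,
)
from csom.som import Coordinate, SomConfigError

from conftest import make_dataset


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"width": 0},
            {"height": -1},
            {"lr_start": 0.5, "lr_end": 1.0},
            {"lr_start": 1.0, "lr_end": 0.0},
            {"radius_start": 1.0, "radius_end": 2.0},
            {"radius_end": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SomConfigError):
            SomConfig(**kwargs)


class TestInitGrid:
    def test_shape_and_range(self):
        grid = init_grid(SomConfig(width=5, height=5, seed=7), dim=2)
        assert grid.weights.shape == (25, 2)
        assert np.all((grid.weights >= 0) & (grid.weights < 1))

    def test_deterministic_for_seed(self):
        cfg = SomConfig(width=4, height=3, seed=11)
        a = init_grid(cfg, dim=6)
        b = init_grid(cfg, dim=6)
        assert np.array_equal(a.weights, b.weights)

    def test_single_neuron_grid(self):
        grid = init_grid(SomConfig(width=1, height=1), dim=3)
        assert grid.weights.shape == (1, 3)

    def test_bad_dimension_rejected(self):
        with pytest.raises(SomConfigError):
            init_grid(SomConfig(), dim=0)


class TestTorusDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 0), (4, 4), np.sqrt(2)),  # wraps both axes
            ((0, 0), (0, 0), 0.0),
            ((0, 0), (2, 0), 2.0),  # interior path shorter than wrap (3)
            ((0, 1), (0, 4), 2.0),  # wrap shorter than interior
        ],
    )
    def test_wraparound_distances_on_5x5(self, a, b, expected):
        d = torus_distance(Coordinate(*a), Coordinate(*b), 5, 5)
        assert d == pytest.approx(expected)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            torus_distance(Coordinate(0, 5), Coordinate(0, 0), 5, 5)

    def test_metric_axioms_exhaustive_4x4(self):
        """Identity, symmetry and triangle inequality over all coordinate
        triples of a 4x4 torus."""
        coords = [Coordinate(r, c) for r in range(4) for c in range(4)]
        d = {(a, b): torus_distance(a, b, 4, 4) for a in coords for b in coords}
        for a, b in itertools.product(coords, repeat=2):
            assert (d[a, b] == 0) == (a == b)
            assert d[a, b] == d[b, a]
        for a, b, c in itertools.product(coords, repeat=3):
            assert d[a, c] <= d[a, b] + d[b, c] + 1e-12


class TestFindBmu:
    def test_exact_weight_match_wins(self):
        grid = init_grid(SomConfig(width=5, height=5, seed=3), dim=2)
        target = grid.weights[2 * 5 + 3].copy()
        assert find_bmu(grid, target) == Coordinate(2, 3)

    def test_tie_breaks_lexicographically(self):
        grid = init_grid(SomConfig(width=3, height=3, seed=0), dim=2)
        grid.weights[:] = 0.5
        assert find_bmu(grid, np.array([0.1, 0.9])) == Coordinate(0, 0)

    def test_single_neuron_always_wins(self):
        grid = init_grid(SomConfig(width=1, height=1, seed=0), dim=2)
        assert find_bmu(grid, np.array([100.0, -50.0])) == Coordinate(0, 0)

    def test_dimension_mismatch_rejected(self):
        grid = init_grid(SomConfig(width=2, height=2, seed=0), dim=2)
        with pytest.raises(ValueError):
            find_bmu(grid, np.array([1.0, 2.0, 3.0]))


class TestTrainSom:
    def test_zero_rounds_returns_initial_grid(self):
        data = make_dataset([[0.0, 0.0], [1.0, 1.0]], ["a", "b"])
        cfg = SomConfig(width=4, height=4, rounds=0, seed=5)
        trained = train_som(data, cfg)
        assert np.array_equal(trained.weights, init_grid(cfg, 2).weights)

    def test_single_example_contracts_onto_it(self):
        """With one example the BMU weight follows the geometric contraction
        w <- w + a (x - w) toward the (z-scored) example, i.e. the origin."""
        data = make_dataset([[3.0, -2.0]], ["a"])
        cfg = SomConfig(width=3, height=3, rounds=200, seed=1)
        grid = train_som(data, cfg)
        xs = grid.scale(np.array([3.0, -2.0]))
        assert np.allclose(xs, 0.0)
        bmu = find_bmu(grid, xs)
        w = grid.weights[grid.index(bmu)]
        assert np.linalg.norm(w - xs) < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_separated_clusters_map_to_distant_regions(self, seed, two_cluster_dataset):
        """Topology preservation: two well-separated clusters occupy disjoint
        BMU sets more than one cell apart on the torus."""
        cfg = SomConfig(width=10, height=10, rounds=30, radius_start=5.0, seed=seed)
        grid = train_som(two_cluster_dataset, cfg)
        occ = project(grid, two_cluster_dataset)
        cells_a, cells_b = set(), set()
        for cell, members in occ.cells.items():
            for i in members:
                (cells_a if i < 30 else cells_b).add(cell)
        assert cells_a.isdisjoint(cells_b)
        min_d = min(
            torus_distance(a, b, 10, 10) for a in cells_a for b in cells_b
        )
        assert min_d > 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_training_reduces_quantization_error(self, seed):
        rng = np.random.default_rng(seed)
        data = make_dataset(rng.normal(size=(60, 3)), ["a"] * 60)
        cfg = SomConfig(width=6, height=6, rounds=20, radius_start=4.0, seed=seed)
        trained = train_som(data, cfg)
        untrained = train_som(
            data, SomConfig(width=6, height=6, rounds=0, radius_start=4.0, seed=seed)
        )
        assert quantization_error(trained, data) <= quantization_error(untrained, data)

    def test_deterministic_for_fixed_seed(self, two_cluster_dataset):
        cfg = SomConfig(width=6, height=6, rounds=10, seed=9)
        a = train_som(two_cluster_dataset, cfg)
        b = train_som(two_cluster_dataset, cfg)
        assert np.array_equal(a.weights, b.weights)

    def test_feature_rescaling_preserves_bmus(self, two_cluster_dataset):
        """Per-feature unit changes are absorbed by the z-score, so BMU
        assignments are unchanged. Power-of-two scale factors keep the
        check bitwise exact (generic affine maps agree only up to
        round-off, which can flip argmin ties during training)."""
        cfg = SomConfig(width=6, height=6, rounds=10, seed=2)
        base = train_som(two_cluster_dataset, cfg)
        X2 = two_cluster_dataset.X * np.array([4.0, 0.25])
        shifted_data = make_dataset(X2, ["a"] * 30 + ["b"] * 30)
        shifted = train_som(shifted_data, cfg)
        occ_a = project(base, two_cluster_dataset)
        occ_b = project(shifted, shifted_data)
        assert {c: tuple(v) for c, v in occ_a.cells.items()} == {
            c: tuple(v) for c, v in occ_b.cells.items()
        }

    def test_empty_and_nonfinite_data_rejected(self):
        cfg = SomConfig(width=2, height=2)
        with pytest.raises(ValueError):
            train_som(make_dataset(np.empty((0, 2)), []), cfg)
        bad = make_dataset([[1.0, 2.0]], ["a"])
        bad.features.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_som(bad, cfg)


class TestProject:
    def test_single_example_occupies_one_cell(self, two_cluster_dataset):
        cfg = SomConfig(width=4, height=4, rounds=5, seed=0)
        grid = train_som(two_cluster_dataset, cfg)
        one = make_dataset([[0.0, 0.0]], ["a"])
        occ = project(grid, one)
        assert len(occ.cells) == 1
        assert list(occ.cells.values()) == [[0]]

    def test_duplicated_example_shares_a_cell(self):
        data = make_dataset([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], ["a", "a", "b"])
        grid = train_som(data, SomConfig(width=4, height=4, rounds=5, seed=1))
        occ = project(grid, data)
        cell_of = {i: c for c, members in occ.cells.items() for i in members}
        assert cell_of[0] == cell_of[1]

    def test_partition_conserves_examples(self, two_cluster_dataset):
        grid = train_som(two_cluster_dataset, SomConfig(width=5, height=5, rounds=5, seed=0))
        occ = project(grid, two_cluster_dataset)
        assert sum(len(v) for v in occ.cells.values()) == 60
        assert sorted(i for v in occ.cells.values() for i in v) == list(range(60))

    def test_dimension_mismatch_rejected(self, two_cluster_dataset):
        grid = train_som(two_cluster_dataset, SomConfig(width=3, height=3, rounds=2, seed=0))
        with pytest.raises(ValueError):
            project(grid, make_dataset([[1.0, 2.0, 3.0]], ["a"]))
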