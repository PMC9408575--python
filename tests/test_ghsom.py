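import json

import numpy as np
import pytest

from moodmap.ghsom import (
    GhsomConfig,
    GhsomError,
    build_tree,
    grow_step,
    mean_deviation,
    should_grow,
    unit_deviations,
)
from moodmap.som import SomGrid


def brute_force_mean_deviation(weights_flat, data):
    """Oracle: mean over inputs of Euclidean distance to the closest unit."""
    total = 0.0
    for x in data:
        best = min(float(np.linalg.norm(x - w)) for w in weights_flat)
        total += best
    return total / len(data)


def planted_groups(seed, n_groups=4, sizes=(4, 4, 4, 3), dim=6, spread=0.15):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 5, size=(n_groups, dim))
    X, labels = [], []
    for g, (c, n) in enumerate(zip(centers, sizes)):
        X.append(c + rng.normal(0, spread, size=(n, dim)))
        labels += [g] * n
    return np.vstack(X), labels


class TestMeanDeviation:
    def test_perfect_quantization_is_zero(self):
        w = np.array([[[0.0, 0.0]], [[1.0, 1.0]]])
        data = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert mean_deviation(SomGrid(weights=w), data) == 0.0

    def test_single_distance(self):
        grid = SomGrid(weights=np.zeros((1, 1, 2)))
        assert mean_deviation(grid, np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            w = rng.normal(size=(3, 3, 2))
            data = rng.normal(size=(7, 2))
            grid = SomGrid(weights=w)
            assert mean_deviation(grid, data) == pytest.approx(
                brute_force_mean_deviation(w.reshape(-1, 2), data)
            )

    def test_empty_errors(self):
        grid = SomGrid(weights=np.zeros((1, 1, 2)))
        with pytest.raises(GhsomError):
            mean_deviation(grid, np.empty((0, 2)))


class TestShouldGrow:
    def test_zero_deviation_never_grows(self):
        assert should_grow(0.0, 1.0, 0.08) is False

    def test_equal_deviations_grow(self):
        assert should_grow(1.0, 1.0, 0.08) is True  # ratio 1 > 0.08

    def test_small_ratio_stops(self):
        assert should_grow(0.05, 1.0, 0.08) is False  # 0.05 < 0.08

    def test_zero_parent_never_grows(self):
        assert should_grow(0.5, 0.0, 0.08) is False


class TestGrowStep:
    def test_growth_adds_row_or_column(self, rng):
        data = np.vstack(
            [rng.normal((0, 0), 0.1, (5, 2)), rng.normal((5, 5), 0.1, (5, 2))]
        )
        cfg = GhsomConfig(seed=0, epochs=30)
        tree_rng = np.random.default_rng(0)
        from moodmap.ghsom import _build_node

        node = _build_node(data, np.arange(10), 10.0, 1, GhsomConfig(seed=0, epochs=5, t_m=0.9), tree_rng)
        before = node.shape
        node = grow_step(node, data, cfg, tree_rng)
        after = node.shape
        assert sorted((after[0] - before[0], after[1] - before[1])) == [0, 1]

    def test_growth_reduces_quantization_error(self, rng):
        from moodmap.ghsom import _build_node

        data = np.vstack(
            [rng.normal((0, 0), 0.05, (6, 2)), rng.normal((8, 8), 0.05, (6, 2)),
             rng.normal((0, 8), 0.05, (6, 2)), rng.normal((8, 0), 0.05, (6, 2)),
             rng.normal((4, 4), 0.05, (6, 2))]
        )
        cfg = GhsomConfig(seed=1, epochs=60)
        tree_rng = np.random.default_rng(1)
        node = _build_node(data, np.arange(len(data)), 100.0, 1, GhsomConfig(seed=1, epochs=60, t_m=0.99), tree_rng)
        qe_before = mean_deviation(node.grid, data)
        node = grow_step(node, data, cfg, tree_rng)
        qe_after = mean_deviation(node.grid, data)
        assert qe_after < qe_before

    def test_at_cap_is_noop_with_warning(self, rng):
        from moodmap.ghsom import GhsomNode, _assign

        data = rng.normal(size=(10, 2))
        grid = SomGrid(weights=rng.normal(size=(4, 4, 2)))
        node = GhsomNode(
            grid=grid, depth=1, input_indices=np.arange(10),
            assignments=_assign(grid, data), parent_deviation=1.0,
        )
        cfg = GhsomConfig(max_units=16)
        with pytest.warns(UserWarning):
            out = grow_step(node, data, cfg, np.random.default_rng(0))
        assert out.shape == (4, 4)


class TestBuildTree:
    def test_identical_inputs_single_leaf(self):
        X = np.ones((8, 3))
        tree = build_tree(X, GhsomConfig(seed=0, epochs=10))
        assert tree.G == 1
        assert tree.layer1.depth == 1
        assert not tree.layer1.children

    def test_leaves_partition_inputs(self, rng):
        for seed in range(5):
            X = rng.normal(size=(12, 4))
            tree = build_tree(X, GhsomConfig(seed=seed, epochs=30))
            flat = sorted(i for leaf in tree.leaf_memberships() for i in leaf)
            assert flat == list(range(12))

    def test_recovers_four_planted_groups(self):
        hits = 0
        for seed in range(20):
            X, labels = planted_groups(seed)
            tree = build_tree(X, GhsomConfig(seed=seed))
            parts = sorted(tree.leaf_memberships())
            gt = sorted(
                sorted(i for i, l in enumerate(labels) if l == g) for g in range(4)
            )
            hits += parts == gt
        assert hits >= 16  # >= 80% of seeds

    def test_fresh_sublayers_are_2x2(self, rng):
        # force hierarchy: two tight groups far apart inside one parent unit
        X, _ = planted_groups(0, n_groups=6, sizes=(3, 3, 3, 2, 2, 2), spread=0.05)
        tree = build_tree(X, GhsomConfig(seed=0, epochs=60))

        def initial_shapes(node):
            for child in node.children.values():
                # children may have grown laterally, but start from 2x2:
                # at least one dimension stays 2 unless grown twice
                yield child
                yield from initial_shapes(child)

        for child in initial_shapes(tree.layer1):
            assert min(child.shape) >= 2

    def test_child_deviation_not_above_parent_unit(self, rng):
        for seed in range(5):
            X = rng.normal(size=(14, 3))
            tree = build_tree(X, GhsomConfig(seed=seed, epochs=40))

            def check(node):
                members = tree.inputs[node.input_indices]
                devs = unit_deviations(node.grid, members)
                for flat, child in node.children.items():
                    child_members = tree.inputs[child.input_indices]
                    child_v = mean_deviation(child.grid, child_members)
                    assert child_v <= devs[flat] + 1e-9
                    check(child)

            check(tree.layer1)

    def test_terminates_within_caps(self, rng):
        X = rng.normal(size=(40, 3))
        cfg = GhsomConfig(seed=0, epochs=20, max_depth=3, max_units=9)
        tree = build_tree(X, cfg)

        def check(node):
            assert node.depth <= 3
            assert node.grid.J * node.grid.K <= 9
            for child in node.children.values():
                check(child)

        check(tree.layer1)

    def test_deterministic_serialization(self, rng):
        X = rng.normal(size=(15, 4))
        t1 = build_tree(X, GhsomConfig(seed=9, epochs=30))
        t2 = build_tree(X, GhsomConfig(seed=9, epochs=30))
        assert json.dumps(t1.to_dict(), sort_keys=True) == json.dumps(
            t2.to_dict(), sort_keys=True
        )

    def test_g_equals_leaf_count(self, rng):
        X = rng.normal(size=(15, 4))
        tree = build_tree(X, GhsomConfig(seed=2, epochs=30))
        assert tree.G == len(tree.leaf_memberships())

    def test_two_level_five_cluster_structure_representable(self):
        """A 5-cluster layer-1 with one cluster splitting at depth 2 can be
        built and serialized as a 2-level tree."""
        rng = np.random.default_rng(4)
        centers = np.array(
            [[0, 0], [20, 0], [0, 20], [20, 20], [10, 40]], dtype=float
        )
        X = np.vstack(
            [c + rng.normal(0, 0.1, size=(3, 2)) for c in centers]
        )
        # split the fourth cluster into two sub-blobs
        X[9:12] += np.array([[0, 0], [1.2, 0], [0, 1.2]])
        cfg = GhsomConfig(seed=4, epochs=60, max_per_layer=6, t_m=0.04)
        tree = build_tree(X, cfg)
        rendered = tree.render_text()
        assert tree.G >= 5
        assert "map" in rendered and "depth" in rendered

    def test_empty_inputs_error(self):
        with pytest.raises(GhsomError):
            build_tree(np.empty((0, 2)))
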