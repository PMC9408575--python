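import numpy as np
import pytest

from moodmap.psychometrics import MoodPoint
from moodmap.som import SomGrid
from moodmap.umatrix import (
    UMatrixError,
    UMatrixField,
    assign_semantic_labels,
    compute_umatrix,
    segment_categories,
)


def brute_force_umatrix(weights):
    """Independent recomputation oracle: mean of all in-bounds neighbor
    components; diagonals average the diagonal and cross-pair distances."""
    J, K, _ = weights.shape
    U = np.zeros((J, K))
    for j in range(J):
        for k in range(K):
            parts = []
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if dj == dk == 0:
                        continue
                    nj, nk = j + dj, k + dk
                    if not (0 <= nj < J and 0 <= nk < K):
                        continue
                    if dj == 0 or dk == 0:
                        parts.append(((weights[j, k] - weights[nj, nk]) ** 2).sum())
                    else:
                        diag = ((weights[j, k] - weights[nj, nk]) ** 2).sum()
                        cross = ((weights[j, nk] - weights[nj, k]) ** 2).sum()
                        parts.append(0.5 * diag + 0.5 * cross)
            U[j, k] = np.mean(parts)
    return U


class TestComputeUmatrix:
    def test_identical_weights_give_zero(self):
        grid = SomGrid(weights=np.ones((4, 5, 3)))
        field = compute_umatrix(grid)
        np.testing.assert_array_equal(field.values, 0.0)

    def test_two_unit_grid_hand_value(self):
        # single lateral component: (0 - 3)^2 = 9 for both units
        grid = SomGrid(weights=np.array([[[0.0]], [[3.0]]]))
        field = compute_umatrix(grid)
        np.testing.assert_allclose(field.values, [[9.0], [9.0]])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            grid = SomGrid(weights=rng.normal(size=(6, 6, 3)))
            field = compute_umatrix(grid)
            np.testing.assert_allclose(field.values, brute_force_umatrix(grid.weights))

    def test_depends_only_on_weights(self, rng):
        w = rng.normal(size=(5, 5, 2))
        f1 = compute_umatrix(SomGrid(weights=w.copy(), epoch=3, seed=1))
        f2 = compute_umatrix(SomGrid(weights=w.copy(), epoch=9, seed=2))
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_scaling_weights_scales_u_quadratically(self, rng):
        w = rng.normal(size=(4, 4, 3))
        base = compute_umatrix(SomGrid(weights=w))
        scaled = compute_umatrix(SomGrid(weights=2.5 * w))
        np.testing.assert_allclose(scaled.values, 2.5**2 * base.values, rtol=1e-9)

    def test_symmetric_pairwise(self, rng):
        # 2x1 grids measure the same single distance from both ends
        w = rng.normal(size=(2, 1, 4))
        field = compute_umatrix(SomGrid(weights=w))
        assert field.values[0, 0] == pytest.approx(field.values[1, 0])


class TestSegmentCategories:
    def test_flat_field_is_one_category(self):
        grid = SomGrid(weights=np.ones((6, 6, 2)))
        field = UMatrixField(values=np.zeros((6, 6)))
        seg = segment_categories(field, grid)
        assert len(seg.categories) == 1
        assert np.all(seg.label_map == 1)

    def test_single_wall_gives_two_categories(self):
        # weights step across a full-height column; U peaks there
        w = np.zeros((7, 7, 1))
        w[4:, :, 0] = 10.0
        grid = SomGrid(weights=w)
        field = compute_umatrix(grid)
        seg = segment_categories(field, grid, 0.7)
        assert len(seg.categories) == 2

    def test_every_unit_labeled_exactly_once(self, rng):
        grid = SomGrid(weights=rng.normal(size=(8, 8, 2)))
        field = compute_umatrix(grid)
        seg = segment_categories(field, grid, 0.8)
        assert np.all(seg.label_map >= 1)
        total = sum(len(c.units) for c in seg.categories)
        assert total == 64

    def test_bad_quantile(self, rng):
        grid = SomGrid(weights=rng.normal(size=(3, 3, 1)))
        field = compute_umatrix(grid)
        with pytest.raises(UMatrixError):
            segment_categories(field, grid, 1.5)

    def test_category_count_monotone_in_quantile(self, rng):
        # raw wall-partition stage (merge disabled): lower quantile means
        # more wall units, hence the same or more components
        w = rng.normal(size=(10, 10, 2))
        grid = SomGrid(weights=w)
        field = compute_umatrix(grid)
        counts = []
        for q in (0.9, 0.7, 0.5, 0.3):
            seg = segment_categories(field, grid, q, merge_factor=0.0)
            counts.append(len(seg.categories))
        assert all(a <= b for a, b in zip(counts, counts[1:]))


def _uniform_seg(shape):
    labels = np.ones(shape, dtype=int)
    from moodmap.umatrix import Category, CategorySegmentation

    cats = [Category(id=1, units=[tuple(u) for u in np.argwhere(labels == 1)])]
    return CategorySegmentation(label_map=labels, categories=cats)


class TestSemanticLabels:
    def points(self, tmd, f, n=4):
        return [
            MoodPoint(subject_id="s", session_index=i + 1, TMD=tmd, F=f)
            for i in range(n)
        ]

    def test_positive_quadrant(self):
        seg = _uniform_seg((3, 3))
        pts = self.points(30.0, 60.0)
        bmus = [(0, 0)] * len(pts)
        assign_semantic_labels(seg, pts, bmus, tmd_ref=51, f_ref=52)
        assert seg.categories[0].semantic == "positive"

    def test_negative_quadrant(self):
        seg = _uniform_seg((3, 3))
        pts = self.points(70.0, 40.0)
        assign_semantic_labels(seg, pts, [(0, 0)] * len(pts), tmd_ref=51, f_ref=52)
        assert seg.categories[0].semantic == "negative"

    def test_neutral_center(self):
        seg = _uniform_seg((3, 3))
        pts = self.points(50.0, 50.0)
        assign_semantic_labels(seg, pts, [(0, 0)] * len(pts), tmd_ref=51, f_ref=52)
        assert seg.categories[0].semantic == "neutral"

    def test_empty_category_warns_neutral(self):
        from moodmap.umatrix import Category, CategorySegmentation

        labels = np.ones((2, 2), dtype=int)
        labels[1, 1] = 2
        seg = CategorySegmentation(
            label_map=labels,
            categories=[
                Category(id=1, units=[(0, 0), (0, 1), (1, 0)]),
                Category(id=2, units=[(1, 1)]),
            ],
        )
        pts = self.points(30.0, 60.0, n=2)
        with pytest.warns(UserWarning):
            assign_semantic_labels(seg, pts, [(0, 0), (0, 1)], 51, 52)
        assert seg.categories[1].semantic == "neutral"

    def test_five_synthetic_clusters_recover_quadrant_semantics(self):
        """End-to-end: clusters planted in the five quadrant positions map to
        two positive, one neutral, two negative categories."""
        import moodmap.psychometrics as psych
        from moodmap import som, synthetic
        from moodmap.som import bmu_indices
        from moodmap.umatrix import compute_umatrix

        records, gt = synthetic.generate_cohort(synthetic.CohortSpec(seed=5))
        points = psych.mood_points(records)
        X = np.array([[p.TMD, p.F] for p in points])
        Xn = (X - X.mean(0)) / X.std(0)
        grid = som.train(
            Xn, som.TrainConfig(alpha0=0.1, psi0=8, epochs=60, seed=5), shape=(20, 20)
        )
        field = compute_umatrix(grid)
        seg = segment_categories(field, grid, 0.6, min_region=4)
        bmus = bmu_indices(grid, Xn)
        assign_semantic_labels(seg, points, bmus)
        tags = sorted(c.semantic for c in seg.categories if c.members)
        assert "positive" in tags and "negative" in tags
        # cluster means must respect planted semantics for represented clusters
        for cat in seg.categories:
            if not cat.members:
                continue
            if cat.mean_tmd > 60:
                assert cat.semantic == "negative"
            if cat.mean_tmd < 42:
                assert cat.semantic == "positive"
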