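"""U-Matrix boundary extraction and category segmentation for trained SOMs.

Each lattice unit gets a boundary-depth value aggregating squared distances
to its in-bounds neighbors (lateral plus diagonal cross-pair components);
high-value walls separate clusters. Segmentation thresholds the field at a
quantile, labels the remaining units by 4-connected components, and absorbs
the wall units into the most similar adjacent component. Semantic tags
(positive / neutral / negative) come from per-category mean mood scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .psychometrics import MoodPoint
from .som import SomGrid

__all__ = [
    "UMatrixField",
    "Category",
    "CategorySegmentation",
    "compute_umatrix",
    "segment_categories",
    "assign_semantic_labels",
    "render_umatrix",
]

#: Default semantic reference points in T-score units (configurable): a
#: category is negative when its mean TMD exceeds TMD_REF; otherwise
#: positive when its mean F exceeds F_REF, else neutral.
TMD_REF = 51.0
F_REF = 52.0


class UMatrixError(ValueError):
    pass


@dataclass
class UMatrixField:
    """Per-unit aggregated boundary values on a J x K lattice (all >= 0)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise UMatrixError(f"U field must be 2-D, got shape {self.values.shape}")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise UMatrixError("U field must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Category:
    id: int
    units: list[tuple[int, int]]
    mean_tmd: float | None = None
    mean_f: float | None = None
    semantic: str | None = None
    members: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class CategorySegmentation:
    """Exhaustive unit-to-category labeling of a SOM lattice."""

    label_map: np.ndarray
    categories: list[Category]

    def category_of(self, unit: tuple[int, int]) -> int:
        return int(self.label_map[unit])

    def to_dict(self) -> dict:
        return {
            "label_map": self.label_map.tolist(),
            "categories": [
                {
                    "id": c.id,
                    "units": [list(u) for u in c.units],
                    "mean_tmd": c.mean_tmd,
                    "mean_f": c.mean_f,
                    "semantic": c.semantic,
                    "members": [list(m) for m in c.members],
                }
                for c in self.categories
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))


def _pairwise_sq(weights: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    d = weights[a] - weights[b]
    return float(np.dot(d, d))


def compute_umatrix(grid: SomGrid) -> UMatrixField:
    """Aggregate neighbor-distance components into a per-unit boundary field.

    Lateral components are squared Euclidean distances to the four
    horizontal/vertical neighbors. Each diagonal component averages, with
    weight 1/2 each, the squared distance along the diagonal itself and the
    squared distance between the two units flanking it (the cross pair).
    The per-unit value is the mean of all in-bounds components: eight for
    interior units, fewer at the lattice edge.
    """
    w = grid.weights
    J, K = grid.J, grid.K
    U = np.zeros((J, K))
    counts = np.zeros((J, K))
    totals = np.zeros((J, K))

    for j in range(J):
        for k in range(K):
            for dj, dk in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nj, nk = j + dj, k + dk
                if 0 <= nj < J and 0 <= nk < K:
                    totals[j, k] += _pairwise_sq(w, (j, k), (nj, nk))
                    counts[j, k] += 1
            for dj, dk in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
                nj, nk = j + dj, k + dk
                if 0 <= nj < J and 0 <= nk < K:
                    # diagonal component: half the diagonal distance plus
                    # half the cross-pair distance (both flanking units are
                    # in bounds whenever the diagonal neighbor is)
                    diag = _pairwise_sq(w, (j, k), (nj, nk))
                    cross = _pairwise_sq(w, (j, nk), (nj, k))
                    totals[j, k] += 0.5 * diag + 0.5 * cross
                    counts[j, k] += 1
    U = totals / counts
    return UMatrixField(values=U)


def segment_categories(
    field: UMatrixField,
    grid: SomGrid,
    threshold_quantile: float = 0.60,
    *,
    min_region: int = 0,
    merge_factor: float = 0.5,
) -> CategorySegmentation:
    """Partition the lattice into categories separated by high-U walls.

    Units whose U exceeds the ``threshold_quantile`` quantile are boundary
    units; the rest are grouped into 4-connected components. Components
    smaller than ``min_region`` units are demoted to boundary. Boundary
    units are then absorbed, breadth-first, into the adjacent component
    whose nearest member prototype is closest in weight space, so every
    unit ends up labeled.

    Finally, adjacent categories whose mean prototype vectors are closer
    than ``merge_factor`` times the median adjacent-pair centroid distance
    are merged (a spurious wall inside one data cluster leaves two
    near-identical categories); pass ``merge_factor=0`` to disable.
    """
    if not (0.0 < threshold_quantile < 1.0):
        raise UMatrixError(
            f"threshold_quantile must be in (0, 1), got {threshold_quantile}"
        )
    U = field.values
    if U.shape != (grid.J, grid.K):
        raise UMatrixError(
            f"field shape {U.shape} does not match grid ({grid.J}, {grid.K})"
        )
    threshold = np.quantile(U, threshold_quantile)
    interior = U <= threshold

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_components = ndimage.label(interior, structure=structure)

    if min_region > 0 and n_components > 0:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_components + 1))
        for comp_id, size in enumerate(sizes, start=1):
            if size < min_region:
                labels[labels == comp_id] = 0
        # compact ids
        kept = sorted(set(labels.ravel()) - {0})
        remap = {old: new for new, old in enumerate(kept, start=1)}
        labels = np.vectorize(lambda v: remap.get(v, 0))(labels) if kept else np.zeros_like(labels)
        n_components = len(kept)

    if n_components == 0:
        # everything was boundary: the whole map is one category
        labels = np.ones_like(labels)
        n_components = 1

    # absorb boundary units into the most similar adjacent component
    w = grid.weights
    while np.any(labels == 0):
        frontier = []
        for j, k in zip(*np.nonzero(labels == 0)):
            best: tuple[float, int] | None = None
            for dj, dk in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nj, nk = j + dj, k + dk
                if 0 <= nj < labels.shape[0] and 0 <= nk < labels.shape[1]:
                    lab = labels[nj, nk]
                    if lab > 0:
                        dist = _pairwise_sq(w, (j, k), (nj, nk))
                        if best is None or dist < best[0]:
                            best = (dist, int(lab))
            if best is not None:
                frontier.append(((j, k), best[1]))
        if not frontier:  # isolated region fully surrounded by unlabeled: cannot happen
            break
        for (j, k), lab in frontier:
            labels[j, k] = lab

    if merge_factor > 0:
        labels = _merge_similar_neighbors(labels, w, merge_factor)

    ids = sorted(int(v) for v in set(labels.ravel()))
    remap = {old: new for new, old in enumerate(ids, start=1)}
    labels = np.vectorize(remap.__getitem__)(labels).astype(int)
    categories = [
        Category(
            id=cid,
            units=[(int(j), int(k)) for j, k in np.argwhere(labels == cid)],
        )
        for cid in range(1, len(ids) + 1)
    ]
    return CategorySegmentation(label_map=labels, categories=categories)


def _merge_similar_neighbors(
    labels: np.ndarray, weights: np.ndarray, merge_factor: float
) -> np.ndarray:
    """Fuse adjacent categories whose prototype centroids nearly coincide.

    The merge threshold is relative: ``merge_factor`` times the median
    centroid distance over all currently adjacent category pairs, so the
    rule is scale-free. Merges repeat greedily (closest pair first) until
    no adjacent pair falls under the threshold.
    """
    labels = labels.copy()
    while True:
        ids = sorted(int(v) for v in set(labels.ravel()))
        if len(ids) < 3:
            return labels
        centroids = {
            cid: weights[labels == cid].mean(axis=0) for cid in ids
        }
        adjacent: set[tuple[int, int]] = set()
        J, K = labels.shape
        for j in range(J):
            for k in range(K):
                for dj, dk in ((1, 0), (0, 1)):
                    nj, nk = j + dj, k + dk
                    if nj < J and nk < K and labels[j, k] != labels[nj, nk]:
                        adjacent.add(tuple(sorted((int(labels[j, k]), int(labels[nj, nk])))))
        if not adjacent:
            return labels
        distances = {
            pair: float(np.linalg.norm(centroids[pair[0]] - centroids[pair[1]]))
            for pair in adjacent
        }
        threshold = merge_factor * float(np.median(list(distances.values())))
        closest = min(distances, key=distances.get)
        if distances[closest] >= threshold:
            return labels
        keep, drop = closest
        labels[labels == drop] = keep


def assign_semantic_labels(
    seg: CategorySegmentation,
    points: Sequence[MoodPoint],
    bmu_map: np.ndarray | Sequence[tuple[int, int]],
    tmd_ref: float = TMD_REF,
    f_ref: float = F_REF,
) -> CategorySegmentation:
    """Tag each category positive / neutral / negative from member means.

    ``bmu_map`` gives, per mood point, its best-matching unit (j, k); the
    point belongs to the category owning that unit. A category is tagged
    negative when mean member TMD exceeds ``tmd_ref``; otherwise positive
    when mean member F exceeds ``f_ref``, else neutral. Categories with no
    members get a neutral tag and a warning.
    """
    bmu_arr = np.asarray(bmu_map, dtype=int)
    if bmu_arr.shape != (len(points), 2):
        raise UMatrixError(
            f"bmu_map shape {bmu_arr.shape} does not match {len(points)} points"
        )
    membership: dict[int, list[MoodPoint]] = {c.id: [] for c in seg.categories}
    member_ids: dict[int, list[tuple[str, int]]] = {c.id: [] for c in seg.categories}
    for point, (j, k) in zip(points, bmu_arr):
        cid = int(seg.label_map[j, k])
        membership[cid].append(point)
        member_ids[cid].append((point.subject_id, point.session_index))

    for category in seg.categories:
        members = membership[category.id]
        category.members = member_ids[category.id]
        if not members:
            warnings.warn(
                f"category {category.id} has no member sessions; tagged neutral",
                stacklevel=2,
            )
            category.semantic = "neutral"
            category.mean_tmd = None
            category.mean_f = None
            continue
        category.mean_tmd = float(np.mean([p.TMD for p in members]))
        category.mean_f = float(np.mean([p.F for p in members]))
        if category.mean_tmd > tmd_ref:
            category.semantic = "negative"
        elif category.mean_f > f_ref:
            category.semantic = "positive"
        else:
            category.semantic = "neutral"
    return seg


def render_umatrix(
    field: UMatrixField,
    path: str | Path,
    *,
    dark_is_deep: bool = True,
    seg: CategorySegmentation | None = None,
) -> None:
    """Write the field as a grayscale PNG (optionally with category overlay).

    By default deeper boundaries render darker (brightness falls as U
    rises); pass ``dark_is_deep=False`` to invert.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    U = field.values
    span = U.max() - U.min()
    norm = (U - U.min()) / span if span > 0 else np.zeros_like(U)
    img = 1.0 - norm if dark_is_deep else norm
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, cmap="gray", vmin=0.0, vmax=1.0, interpolation="nearest")
    if seg is not None:
        ax.contour(seg.label_map, colors="red", linewidths=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
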