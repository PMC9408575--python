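"""Growing hierarchical SOM: a tree of small maps grown under a breadth
threshold.

The virtual root is a single unit whose weight is the mean of all inputs;
its deviation v0 anchors the growth test. Each map starts as a 2x2 lattice,
trains with the static-SOM rule on its assigned inputs, and grows laterally
(full row/column insertion between the error unit and its selected
neighbor) while its mean quantization deviation stays above the breadth
threshold times the parent deviation. Units whose own deviation still
exceeds the threshold spawn child 2x2 maps on their assigned inputs.
Leaves enumerate the final clusters; their count is the fusion feature G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import som as som_core
from .som import SomGrid, TrainConfig

__all__ = [
    "GhsomConfig",
    "GhsomNode",
    "GhsomTree",
    "mean_deviation",
    "unit_deviations",
    "should_grow",
    "grow_step",
    "build_tree",
]


class GhsomError(ValueError):
    pass


@dataclass(frozen=True)
class GhsomConfig:
    """Growth and training meta-parameters.

    ``t_m`` is the breadth threshold (default 0.08); ``max_per_layer``
    caps the number of occupied units (categories) a single map may reach
    before lateral growth stops (default 4). ``max_units`` and
    ``max_depth`` are hard termination bounds.
    """

    t_m: float = 0.08
    max_per_layer: int = 4
    max_depth: int = 5
    max_units: int = 16
    epochs: int = 200
    alpha0: float = 0.5  # node maps are tiny; a large step converges cleanly
    psi0: int = 1
    seed: int = 0
    dissimilar_rule: str = "min"  # "min" (literal rule) or "max" (standard variant)

    def __post_init__(self) -> None:
        if not (0.0 < self.t_m < 1.0):
            raise GhsomError(f"t_m must be in (0, 1), got {self.t_m}")
        if self.max_per_layer < 1 or self.max_depth < 1 or self.max_units < 4:
            raise GhsomError("invalid growth caps")
        if self.dissimilar_rule not in ("min", "max"):
            raise GhsomError(f"unknown dissimilar_rule {self.dissimilar_rule!r}")


@dataclass
class GhsomNode:
    """One map in the hierarchy with its assigned inputs and children."""

    grid: SomGrid
    depth: int
    input_indices: np.ndarray  # indices into the tree's input array
    assignments: np.ndarray  # per assigned input, flat unit index j*K + k
    parent_deviation: float
    children: dict[int, "GhsomNode"] = field(default_factory=dict)  # keyed by flat unit
    initial_shape: tuple[int, int] = (2, 2)  # every map is spawned as 2x2

    def unit_members(self, flat_unit: int) -> np.ndarray:
        return self.input_indices[self.assignments == flat_unit]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid.J, self.grid.K)


@dataclass
class GhsomTree:
    """Full hierarchy over an input set."""

    root_weight: np.ndarray  # w0: mean of all inputs
    root_deviation: float  # v0
    layer1: GhsomNode
    inputs: np.ndarray

    @property
    def G(self) -> int:
        """Number of leaf clusters."""
        return len(self.leaves())

    def leaves(self) -> list[tuple[GhsomNode, int]]:
        """All (node, flat unit) pairs that terminate a cluster.

        A leaf is a non-empty unit with no child map.
        """
        found: list[tuple[GhsomNode, int]] = []

        def walk(node: GhsomNode) -> None:
            for flat in range(node.grid.J * node.grid.K):
                members = node.unit_members(flat)
                if flat in node.children:
                    walk(node.children[flat])
                elif members.size > 0:
                    found.append((node, flat))

        walk(self.layer1)
        return found

    def leaf_memberships(self) -> list[list[int]]:
        """Input indices per leaf, in deterministic traversal order."""
        return [sorted(int(i) for i in node.unit_members(flat)) for node, flat in self.leaves()]

    def to_dict(self) -> dict:
        def node_dict(node: GhsomNode) -> dict:
            return {
                "shape": list(node.shape),
                "depth": node.depth,
                "weights": node.grid.weights.tolist(),
                "inputs": [int(i) for i in node.input_indices],
                "assignments": [int(a) for a in node.assignments],
                "children": {
                    str(flat): node_dict(child) for flat, child in node.children.items()
                },
            }

        return {
            "root_weight": self.root_weight.tolist(),
            "root_deviation": self.root_deviation,
            "G": self.G,
            "leaf_memberships": self.leaf_memberships(),
            "layer1": node_dict(self.layer1),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    def render_text(self) -> str:
        """Indented tree rendering: one line per map unit with member counts."""
        lines: list[str] = [
            f"root (v0={self.root_deviation:.4g}, G={self.G})",
        ]

        def walk(node: GhsomNode, indent: int) -> None:
            pad = "  " * indent
            lines.append(f"{pad}map {node.shape[0]}x{node.shape[1]} depth {node.depth}")
            for flat in range(node.grid.J * node.grid.K):
                members = node.unit_members(flat)
                j, k = divmod(flat, node.grid.K)
                tag = "leaf" if flat not in node.children else "branch"
                if members.size or flat in node.children:
                    lines.append(
                        f"{pad}  unit ({j},{k}) [{tag}] members={members.size}"
                    )
                if flat in node.children:
                    walk(node.children[flat], indent + 2)

        walk(self.layer1, 1)
        return "\n".join(lines)


def _assign(grid: SomGrid, data: np.ndarray) -> np.ndarray:
    """Flat BMU index per sample."""
    bmu = som_core.bmu_indices(grid, data)
    return bmu[:, 0] * grid.K + bmu[:, 1]


def mean_deviation(grid: SomGrid, data: np.ndarray) -> float:
    """Mean Euclidean distance of inputs to their BMU prototypes (>= 0)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise GhsomError("mean_deviation of an empty assignment")
    flat = grid.weights.reshape(-1, grid.I)
    d = np.linalg.norm(data[:, None, :] - flat[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def unit_deviations(grid: SomGrid, data: np.ndarray) -> np.ndarray:
    """Per-unit mean distance of assigned inputs (NaN for empty units)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    assignments = _assign(grid, data)
    n_units = grid.J * grid.K
    flat = grid.weights.reshape(-1, grid.I)
    out = np.full(n_units, np.nan)
    for u in range(n_units):
        members = data[assignments == u]
        if members.size:
            out[u] = float(np.linalg.norm(members - flat[u], axis=1).mean())
    return out


def should_grow(v_m: float, v_parent: float, t_m: float) -> bool:
    """Growth test: true iff v_m / v_parent exceeds the breadth threshold.

    A perfectly quantized parent (v_parent == 0) never grows.
    """
    if v_parent < 0 or v_m < 0:
        raise GhsomError("deviations must be non-negative")
    if v_parent == 0.0:
        return False
    return v_m / v_parent > t_m


def _neighbors(j: int, k: int, J: int, K: int) -> list[tuple[int, int]]:
    out = []
    for dj, dk in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nj, nk = j + dj, k + dk
        if 0 <= nj < J and 0 <= nk < K:
            out.append((nj, nk))
    return out


def grow_step(
    node: GhsomNode,
    data: np.ndarray,
    cfg: GhsomConfig,
    rng: np.random.Generator,
) -> GhsomNode:
    """One lateral growth: insert a row/column between the error unit and
    its selected neighbor, then retrain and reassign.

    The error unit u_e maximizes per-unit mean deviation; the companion u_d
    is the 4-neighbor with minimum deviation under the literal selection
    rule (``dissimilar_rule="min"``, default) or maximum weight distance
    under the standard variant. New weights interpolate the two flanking
    rows/columns. Ties break toward the smallest (j, k). A map already at
    the unit cap is returned unchanged with a warning.
    """
    import warnings

    grid = node.grid
    J, K = grid.J, grid.K
    if J * K >= cfg.max_units:
        warnings.warn("map already at max size; growth skipped", stacklevel=2)
        return node

    members = data[node.input_indices] if node.input_indices.size else data
    devs = unit_deviations(grid, members)
    if np.all(np.isnan(devs)):
        raise GhsomError("grow_step on a map with no assigned inputs")
    # error unit: max deviation, ties toward smallest flat index
    dev_filled = np.where(np.isnan(devs), -np.inf, devs)
    ue_flat = int(np.argmax(dev_filled))
    ue = divmod(ue_flat, K)

    neighbor_units = _neighbors(*ue, J, K)
    if cfg.dissimilar_rule == "min":
        # literal rule: neighbor with minimum deviation (empty units count 0)
        key = [
            (0.0 if np.isnan(devs[nj * K + nk]) else devs[nj * K + nk], nj, nk)
            for nj, nk in neighbor_units
        ]
        _, dj, dk = min(key)
    else:
        key = [
            (-float(np.linalg.norm(grid.weights[nj, nk] - grid.weights[ue])), nj, nk)
            for nj, nk in neighbor_units
        ]
        _, dj, dk = min(key)
    ud = (dj, dk)

    w = grid.weights
    if ue[0] != ud[0]:  # differ in row: insert a row between them
        if (J + 1) * K > cfg.max_units:
            warnings.warn("row insertion would exceed max size; growth skipped", stacklevel=2)
            return node
        lo = min(ue[0], ud[0])
        new_row = 0.5 * (w[lo] + w[lo + 1])
        new_w = np.insert(w, lo + 1, new_row, axis=0)
    else:  # differ in column
        if J * (K + 1) > cfg.max_units:
            warnings.warn("column insertion would exceed max size; growth skipped", stacklevel=2)
            return node
        lo = min(ue[1], ud[1])
        new_col = 0.5 * (w[:, lo] + w[:, lo + 1])
        new_w = np.insert(w, lo + 1, new_col[:, None], axis=1)

    refined = som_core.train(
        members,
        TrainConfig(alpha0=cfg.alpha0, psi0=cfg.psi0, epochs=cfg.epochs, seed=cfg.seed),
        initial_weights=new_w,
        rng=rng,
    )
    node.grid = refined
    node.assignments = _assign(refined, members)
    return node


def _build_node(
    inputs: np.ndarray,
    indices: np.ndarray,
    parent_deviation: float,
    depth: int,
    cfg: GhsomConfig,
    rng: np.random.Generator,
) -> GhsomNode:
    members = inputs[indices]
    grid = som_core.train(
        members,
        TrainConfig(alpha0=cfg.alpha0, psi0=cfg.psi0, epochs=cfg.epochs, seed=cfg.seed),
        shape=(2, 2),
        rng=rng,
    )
    node = GhsomNode(
        grid=grid,
        depth=depth,
        input_indices=indices,
        assignments=_assign(grid, members),
        parent_deviation=parent_deviation,
        initial_shape=(grid.J, grid.K),
    )

    # lateral growth: while the map quantizes too coarsely relative to the
    # parent and the occupied-unit (category) cap is not yet reached
    while True:
        v_m = mean_deviation(node.grid, members)
        occupied = len(set(node.assignments.tolist()))
        if (
            not should_grow(v_m, parent_deviation, cfg.t_m)
            or occupied >= cfg.max_per_layer
            or node.grid.J * node.grid.K >= cfg.max_units
        ):
            break
        before = node.grid.J * node.grid.K
        node = grow_step(node, inputs, cfg, rng)
        if node.grid.J * node.grid.K == before:  # cap hit inside grow_step
            break

    # hierarchical expansion: units whose own deviation ratio still exceeds
    # the threshold spawn child maps on their assigned inputs
    if depth < cfg.max_depth:
        devs = unit_deviations(node.grid, members)
        for flat in range(node.grid.J * node.grid.K):
            unit_idx = indices[node.assignments == flat]
            if unit_idx.size < 2 or np.isnan(devs[flat]):
                continue
            if should_grow(float(devs[flat]), parent_deviation, cfg.t_m):
                # child compares against this unit's own deviation
                node.children[flat] = _build_node(
                    inputs, unit_idx, float(devs[flat]), depth + 1, cfg, rng
                )
    return node


def build_tree(
    inputs: np.ndarray | Sequence[np.ndarray],
    cfg: GhsomConfig | None = None,
) -> GhsomTree:
    """Grow the full hierarchy over ``inputs``.

    The root deviation v0 is the mean distance of inputs to their global
    mean w0; the single layer-1 map grows against v0. Deterministic under
    a fixed seed: rerunning yields a byte-identical serialized tree.
    """
    cfg = cfg or GhsomConfig()
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.size == 0:
        raise GhsomError("no inputs")
    rng = np.random.default_rng(cfg.seed)
    w0 = inputs.mean(axis=0)
    v0 = float(np.linalg.norm(inputs - w0, axis=1).mean())
    layer1 = _build_node(
        inputs, np.arange(inputs.shape[0]), v0, depth=1, cfg=cfg, rng=rng
    )
    return GhsomTree(root_weight=w0, root_deviation=v0, layer1=layer1, inputs=inputs)
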