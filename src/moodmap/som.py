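"""From-scratch self-organizing map on a rectangular lattice.

Online (sample-at-a-time) training with best-matching-unit search, a square
Chebyshev neighborhood whose radius shrinks linearly to zero, and a linearly
decaying learning rate. No kernel weighting is applied inside the
neighborhood: every unit in the region takes the full step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TrainConfig",
    "SomGrid",
    "find_bmu",
    "neighborhood_extent",
    "update_weights",
    "train",
    "quantization_error",
    "save_grid",
    "load_grid",
]


class SomError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule: initial learning rate, neighborhood radius, epochs.

    Defaults follow the reference meta-parameter table: alpha0=0.1,
    psi0=40 on a 50x50 lattice, 200 epochs.
    """

    alpha0: float = 0.1
    psi0: int = 40
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha0 <= 1.0):
            raise SomError(f"alpha0 must be in (0, 1], got {self.alpha0}")
        if self.psi0 < 0 or int(self.psi0) != self.psi0:
            raise SomError(f"psi0 must be a non-negative integer, got {self.psi0}")
        if self.epochs < 1:
            raise SomError(f"epochs must be >= 1, got {self.epochs}")


@dataclass
class SomGrid:
    """A J x K lattice of I-dimensional prototype vectors.

    ``weights`` has shape (J, K, I). ``epoch`` tracks training progress.
    """

    weights: np.ndarray
    epoch: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise SomError(
                f"weights must have shape (J, K, I), got {self.weights.shape}"
            )
        if min(self.weights.shape) < 1:
            raise SomError(f"empty lattice: shape {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise SomError("weights contain non-finite values")

    @property
    def J(self) -> int:
        return self.weights.shape[0]

    @property
    def K(self) -> int:
        return self.weights.shape[1]

    @property
    def I(self) -> int:
        return self.weights.shape[2]


def init_weights(
    rng: np.random.Generator, data: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Uniform random init within the per-dimension [min, max] of ``data``."""
    low = data.min(axis=0)
    high = data.max(axis=0)
    return rng.uniform(low, high, size=(*shape, data.shape[1]))


def find_bmu(grid: SomGrid, x: np.ndarray) -> tuple[int, int]:
    """Best-matching unit: argmin of squared Euclidean distance to ``x``.

    Ties break toward the smallest j, then smallest k (row-major order).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.I,):
        raise SomError(f"input dimension {x.shape} != grid dimension ({grid.I},)")
    diff = grid.weights - x
    dist = np.einsum("jki,jki->jk", diff, diff)
    flat = int(np.argmin(dist))  # first minimum in row-major order
    return flat // grid.K, flat % grid.K


def neighborhood_extent(psi0: int, epochs: int, t: int) -> int:
    """Linearly shrinking square-neighborhood radius: floor(psi0*(1-t/O)+0.5)."""
    if not (0 <= t <= epochs):
        raise SomError(f"epoch t={t} outside [0, {epochs}]")
    return int(np.floor(psi0 * (1.0 - t / epochs) + 0.5))


def update_weights(
    grid: SomGrid,
    x: np.ndarray,
    bmu: tuple[int, int],
    alpha_t: float,
    psi_t: int,
) -> SomGrid:
    """Move every unit in the radius-``psi_t`` Chebyshev square toward ``x``.

    The square is clipped at the lattice edges; units inside move by
    ``w <- w + alpha_t * (x - w)``, all others are untouched. Updates the
    grid in place and returns it.
    """
    if not (0.0 < alpha_t <= 1.0):
        raise SomError(f"alpha_t must be in (0, 1], got {alpha_t}")
    if psi_t < 0:
        raise SomError(f"psi_t must be >= 0, got {psi_t}")
    x = np.asarray(x, dtype=float)
    j, k = bmu
    j0, j1 = max(0, j - psi_t), min(grid.J, j + psi_t + 1)
    k0, k1 = max(0, k - psi_t), min(grid.K, k + psi_t + 1)
    patch = grid.weights[j0:j1, k0:k1]
    patch += alpha_t * (x - patch)
    return grid


def train(
    data: Sequence[np.ndarray] | np.ndarray,
    cfg: TrainConfig,
    shape: tuple[int, int] = (50, 50),
    *,
    initial_weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    shuffle: bool = True,
) -> SomGrid:
    """Train a SOM for ``cfg.epochs`` epochs over ``data``.

    Each epoch presents every sample once (shuffled by the seeded RNG unless
    ``shuffle`` is False); the learning rate decays linearly,
    ``alpha_t = alpha0 * (1 - t/O)``, as does the neighborhood radius.
    Identical seed and data reproduce identical weights bit-for-bit.

    ``initial_weights``/``rng`` allow resuming or embedding in a larger
    seeded procedure (used by the hierarchical-map refinement step).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise SomError("training data is empty")
    if data.ndim != 2:
        raise SomError(f"data must be 2-D (n_samples, I), got shape {data.shape}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if initial_weights is None:
        weights = init_weights(rng, data, shape)
    else:
        weights = np.array(initial_weights, dtype=float)
    grid = SomGrid(weights=weights, seed=cfg.seed)
    if data.shape[1] != grid.I:
        raise SomError(
            f"data dimension {data.shape[1]} != weight dimension {grid.I}"
        )

    n = data.shape[0]
    for t in range(cfg.epochs):
        alpha_t = cfg.alpha0 * (1.0 - t / cfg.epochs)
        psi_t = neighborhood_extent(cfg.psi0, cfg.epochs, t)
        order = rng.permutation(n) if shuffle else np.arange(n)
        for idx in order:
            x = data[idx]
            bmu = find_bmu(grid, x)
            update_weights(grid, x, bmu, alpha_t, psi_t)
        grid.epoch = t + 1
    return grid


def quantization_error(grid: SomGrid, data: np.ndarray) -> float:
    """Mean squared distance between samples and their BMU prototypes."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    flat = grid.weights.reshape(-1, grid.I)
    d2 = ((data[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).mean())


def bmu_indices(grid: SomGrid, data: np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup; returns an (n, 2) array of (j, k) indices."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    flat = grid.weights.reshape(-1, grid.I)
    d2 = ((data[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return np.stack([idx // grid.K, idx % grid.K], axis=1)


def save_grid(grid: SomGrid, path: str | Path) -> None:
    """Serialize a grid as JSON metadata plus a CSV weight dump."""
    path = Path(path)
    meta = {"J": grid.J, "K": grid.K, "I": grid.I, "epoch": grid.epoch, "seed": grid.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))
    np.savetxt(path.with_suffix(".csv"), grid.weights.reshape(-1, grid.I), delimiter=",")


def load_grid(path: str | Path) -> SomGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    flat = np.loadtxt(path.with_suffix(".csv"), delimiter=",", ndmin=2)
    weights = flat.reshape(meta["J"], meta["K"], meta["I"])
    return SomGrid(weights=weights, epoch=meta["epoch"], seed=meta["seed"])
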