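"""Recurrent SOM for time-series feature vectors and smile-frame extraction.

Units carry a leaky difference activation with two-step memory:

    y(t) = beta1 * y(t-1) + beta2 * y(t-2) + beta3 * (x(t) - w)

The winner is the unit with the smallest activation norm, so recent history
biases the competition. Weight updates are gated by activation magnitude
(bounded gain ||y|| / (1 + ||y||)); with beta1 = beta2 = 0, beta3 = 1 and
the gate disabled the model degenerates exactly to the static SOM.

The mapping layer is a 1-D chain of 15 units by default, matching the fixed
expression-prototype count used downstream by the hierarchical stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import som as som_core

__all__ = [
    "RsomConfig",
    "RsomMap",
    "FaceSequence",
    "rsom_step",
    "rsom_update",
    "train_rsom",
    "extract_smiles",
    "SmileExtraction",
]

N_UNITS_DEFAULT = 15


class RsomError(ValueError):
    pass


@dataclass(frozen=True)
class RsomConfig:
    """RSOM meta-parameters (defaults from the reference parameter table)."""

    n_units: int = N_UNITS_DEFAULT
    betas: tuple[float, float, float] = (0.5, 0.2, 0.3)
    gamma0: float = 0.1
    psi0: int = 1
    epochs: int = 200
    seed: int = 0
    update_mode: str = "gated"  # "gated" (activation-magnitude gain) or "som"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise RsomError(f"n_units must be >= 1, got {self.n_units}")
        total = sum(self.betas)
        if not (0.0 < total <= 1.5):
            raise RsomError(f"sum of betas must be in (0, 1.5], got {total}")
        if not (0.0 < self.gamma0 <= 1.0):
            raise RsomError(f"gamma0 must be in (0, 1], got {self.gamma0}")
        if self.update_mode not in ("gated", "som"):
            raise RsomError(f"unknown update_mode {self.update_mode!r}")


@dataclass
class RsomMap:
    """Chain of units with weights and two-step activation history."""

    weights: np.ndarray  # (n_units, I)
    y1: np.ndarray  # y(t-1), (n_units, I)
    y2: np.ndarray  # y(t-2), (n_units, I)
    config: RsomConfig

    @classmethod
    def create(cls, weights: np.ndarray, config: RsomConfig) -> "RsomMap":
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2:
            raise RsomError(f"weights must be (n_units, I), got {weights.shape}")
        zeros = np.zeros_like(weights)
        return cls(weights=weights, y1=zeros.copy(), y2=zeros.copy(), config=config)

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    @property
    def I(self) -> int:
        return self.weights.shape[1]

    def reset_activations(self) -> None:
        """Zero the activation history (call at each sequence start)."""
        self.y1 = np.zeros_like(self.weights)
        self.y2 = np.zeros_like(self.weights)


@dataclass
class FaceSequence:
    """Ordered per-frame feature vectors with optional ground-truth flags."""

    frames: np.ndarray  # (n_frames, I)
    frame_rate: float = 30.0
    smile_flags: np.ndarray | None = None  # bool (n_frames,) when synthetic

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[0] < 3:
            raise RsomError(
                f"sequence needs >= 3 frames, got {self.frames.shape[0]}"
            )
        if self.smile_flags is not None:
            self.smile_flags = np.asarray(self.smile_flags, dtype=bool)
            if self.smile_flags.shape[0] != self.frames.shape[0]:
                raise RsomError("smile_flags length does not match frames")

    def __len__(self) -> int:
        return self.frames.shape[0]


def rsom_step(rsom: RsomMap, x_t: np.ndarray) -> tuple[int, np.ndarray]:
    """One recurrence step: update activations, return (BMU index, y_new).

    Shifts the two-step history after computing the new activations; the
    BMU is the unit minimizing the squared activation norm, ties breaking
    toward the smallest index.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (rsom.I,):
        raise RsomError(f"input shape {x_t.shape} != ({rsom.I},)")
    b1, b2, b3 = rsom.config.betas
    y_new = b1 * rsom.y1 + b2 * rsom.y2 + b3 * (x_t - rsom.weights)
    norms = np.einsum("ui,ui->u", y_new, y_new)
    bmu = int(np.argmin(norms))
    rsom.y2 = rsom.y1
    rsom.y1 = y_new
    return bmu, y_new


def rsom_update(rsom: RsomMap, x_t: np.ndarray, bmu: int, gamma_t: float, psi_t: int = 1) -> RsomMap:
    """Move the BMU and its chain neighbors within ``psi_t`` toward ``x_t``.

    In ``gated`` mode the step is scaled per unit by the bounded activation
    gain ||y|| / (1 + ||y||); in ``som`` mode the gain is 1 and the rule is
    the plain SOM update.
    """
    if not (0.0 < gamma_t <= 1.0):
        raise RsomError(f"gamma_t must be in (0, 1], got {gamma_t}")
    x_t = np.asarray(x_t, dtype=float)
    lo, hi = max(0, bmu - psi_t), min(rsom.n_units, bmu + psi_t + 1)
    patch = rsom.weights[lo:hi]
    if rsom.config.update_mode == "gated":
        mag = np.linalg.norm(rsom.y1[lo:hi], axis=1, keepdims=True)
        gain = mag / (1.0 + mag)
        patch += gamma_t * (x_t - patch) * gain
    else:
        patch += gamma_t * (x_t - patch)
    return rsom


def train_rsom(
    frames: np.ndarray | Sequence[np.ndarray],
    cfg: RsomConfig,
    *,
    shuffle: bool = False,
) -> RsomMap:
    """Train the recurrent map over a frame sequence for ``cfg.epochs`` epochs.

    Frames are presented in temporal order by default (the recurrence is
    order-sensitive); activation history resets at each epoch's sequence
    start. ``gamma`` and the neighborhood radius decay linearly, mirroring
    the static-SOM schedule so the degenerate configuration reproduces it.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.size == 0:
        raise RsomError("no training frames")
    rng = np.random.default_rng(cfg.seed)
    # same seeded init as the static SOM on an (n_units, 1) lattice
    weights = som_core.init_weights(rng, frames, (cfg.n_units, 1)).reshape(
        cfg.n_units, frames.shape[1]
    )
    rsom = RsomMap.create(weights, cfg)
    n = frames.shape[0]
    for t in range(cfg.epochs):
        gamma_t = cfg.gamma0 * (1.0 - t / cfg.epochs)
        psi_t = som_core.neighborhood_extent(cfg.psi0, cfg.epochs, t)
        rsom.reset_activations()
        order = rng.permutation(n) if shuffle else np.arange(n)
        for idx in order:
            bmu, _ = rsom_step(rsom, frames[idx])
            rsom_update(rsom, frames[idx], bmu, gamma_t, psi_t)
    return rsom


@dataclass
class SmileExtraction:
    """Result of smile-frame extraction over one sequence."""

    smile_frames: list[int]
    assignments: np.ndarray  # per-frame BMU index
    smile_units: list[int]
    R: int
    degenerate: bool = False


def assign_frames(seq: FaceSequence, rsom: RsomMap) -> np.ndarray:
    """Replay the recurrence over the sequence and record per-frame BMUs."""
    rsom.reset_activations()
    assignments = np.empty(len(seq), dtype=int)
    for i, frame in enumerate(seq.frames):
        assignments[i], _ = rsom_step(rsom, frame)
    return assignments


def extract_smiles(seq: FaceSequence, rsom: RsomMap) -> SmileExtraction:
    """Split the trained prototypes into smile / neutral groups and pick frames.

    Prototypes are partitioned by 2-means; the group farther (on average)
    from the sequence's median frame vector — the non-neutral pole — is the
    smile group. Frames assigned to smile-group units are returned, and R
    is their count. A sequence whose frames are all effectively identical
    is flagged degenerate (R is then 0 or the full length).
    """
    from sklearn.cluster import KMeans

    assignments = assign_frames(seq, rsom)
    median = np.median(seq.frames, axis=0)

    spread = np.ptp(seq.frames, axis=0).max()
    scale = max(spread, np.abs(seq.frames).max(), 1e-300)
    if spread <= 1e-12 * scale:
        # all frames identical: no smile/neutral contrast to exploit
        return SmileExtraction(
            smile_frames=[],
            assignments=assignments,
            smile_units=[],
            R=0,
            degenerate=True,
        )

    km = KMeans(n_clusters=2, n_init=10, random_state=0)
    groups = km.fit_predict(rsom.weights)
    dist_to_median = np.linalg.norm(rsom.weights - median, axis=1)
    mean_dist = [dist_to_median[groups == g].mean() for g in (0, 1)]
    smile_group = int(np.argmax(mean_dist))
    smile_units = [int(u) for u in np.nonzero(groups == smile_group)[0]]
    smile_frames = [int(i) for i in np.nonzero(np.isin(assignments, smile_units))[0]]
    return SmileExtraction(
        smile_frames=smile_frames,
        assignments=assignments,
        smile_units=smile_units,
        R=len(smile_frames),
    )


def extraction_accuracy(seq: FaceSequence, extraction: SmileExtraction) -> float:
    """Frame-level accuracy of extracted smile frames against ground truth."""
    if seq.smile_flags is None:
        raise RsomError("sequence has no ground-truth smile flags")
    predicted = np.zeros(len(seq), dtype=bool)
    predicted[extraction.smile_frames] = True
    return float(np.mean(predicted == seq.smile_flags))
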