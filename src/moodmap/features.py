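"""Behavioral feature extraction: saccades, gaze heatmaps/extent, Gabor
frame features.

Gaze processing stays in screen-pixel space throughout (the capture device
reports angular resolution, but all downstream quantities are comparative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GazeTrace",
    "GazeFeatures",
    "detect_saccades",
    "gaze_heatmap",
    "gaze_extent",
    "gabor_frame_features",
    "load_gaze_csv",
    "save_gaze_csv",
]

VELOCITY_THRESHOLD_DEFAULT = 1000.0  # px/s
HEATMAP_SIGMA_DEFAULT = 20.0  # px
DENSITY_QUANTILE_DEFAULT = 0.90
FACE_IMAGE_SIZE = 160


class FeatureError(ValueError):
    pass


@dataclass
class GazeTrace:
    """Time-stamped screen-coordinate gaze samples with validity flags."""

    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px
    valid: np.ndarray  # bool
    rate: float = 60.0
    screen: tuple[int, int] = (1280, 720)  # (width, height) px

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise FeatureError("trace arrays must have equal length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise FeatureError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class GazeFeatures:
    """Session-level gaze summary: heatmap extent E, saccade count S."""

    E: int
    S: int
    heatmap: np.ndarray


def detect_saccades(
    trace: GazeTrace, velocity_threshold: float = VELOCITY_THRESHOLD_DEFAULT
) -> tuple[int, list[tuple[int, int]]]:
    """Count saccades by velocity thresholding over valid samples.

    Point-to-point speeds are computed between consecutive valid samples;
    each maximal run of super-threshold speeds bounded by sub-threshold
    (fixation) movement on both sides counts as one saccade. Returns
    ``(S, intervals)`` where intervals are (start, end) indices into the
    valid-sample subsequence.
    """
    idx = np.nonzero(trace.valid)[0]
    if idx.size < 2:
        raise FeatureError("need at least 2 valid samples to detect saccades")
    t, x, y = trace.t[idx], trace.x[idx], trace.y[idx]
    dt = np.diff(t)
    speed = np.hypot(np.diff(x), np.diff(y)) / dt
    fast = speed > velocity_threshold

    intervals: list[tuple[int, int]] = []
    i = 0
    n = fast.size
    while i < n:
        if fast[i]:
            start = i
            while i < n and fast[i]:
                i += 1
            # a saccade must be bounded by fixation movement on both sides
            if start > 0 and i < n:
                intervals.append((start, i))
        else:
            i += 1
    return len(intervals), intervals


def gaze_heatmap(
    trace: GazeTrace,
    kernel_sigma: float = HEATMAP_SIGMA_DEFAULT,
    grid: tuple[int, int] | None = None,
) -> np.ndarray:
    """Gaze concentration density: a Gaussian kernel per valid sample.

    Returns an (h, w) array; ``grid`` defaults to the trace's screen size.
    Total mass equals the number of valid samples (up to edge truncation):
    each sample contributes a unit-mass discretized isotropic Gaussian.
    """
    if grid is None:
        grid = trace.screen
    w, h = grid
    if w < 1 or h < 1:
        raise FeatureError(f"zero-size heatmap grid {grid}")
    idx = np.nonzero(trace.valid)[0]
    if idx.size == 0:
        raise FeatureError("no valid samples in trace")
    xs = np.clip(np.round(trace.x[idx]).astype(int), 0, w - 1)
    ys = np.clip(np.round(trace.y[idx]).astype(int), 0, h - 1)
    counts = np.zeros((h, w))
    np.add.at(counts, (ys, xs), 1.0)
    if kernel_sigma <= 0:
        return counts
    return ndimage.gaussian_filter(counts, sigma=kernel_sigma, mode="constant", cval=0.0)


def gaze_extent(
    heatmap: np.ndarray, density_quantile: float = DENSITY_QUANTILE_DEFAULT
) -> int:
    """E: pixels whose density reaches the given quantile of nonzero values.

    Scale-invariant (depends only on density ranks), so comparable across
    sessions with different sample counts.
    """
    heatmap = np.asarray(heatmap, dtype=float)
    if heatmap.size == 0:
        raise FeatureError("empty heatmap")
    if not (0.0 < density_quantile < 1.0):
        raise FeatureError(f"density_quantile must be in (0, 1), got {density_quantile}")
    nonzero = heatmap[heatmap > 0]
    if nonzero.size == 0:
        return 0
    threshold = np.quantile(nonzero, density_quantile)
    return int(np.count_nonzero(heatmap >= threshold))


def gaze_features(
    trace: GazeTrace,
    *,
    velocity_threshold: float = VELOCITY_THRESHOLD_DEFAULT,
    kernel_sigma: float = HEATMAP_SIGMA_DEFAULT,
    density_quantile: float = DENSITY_QUANTILE_DEFAULT,
    grid: tuple[int, int] | None = None,
) -> GazeFeatures:
    """Convenience wrapper computing (E, S, heatmap) for one session."""
    s, _ = detect_saccades(trace, velocity_threshold)
    heatmap = gaze_heatmap(trace, kernel_sigma, grid)
    e = gaze_extent(heatmap, density_quantile)
    return GazeFeatures(E=e, S=s, heatmap=heatmap)


def gabor_frame_features(
    image: np.ndarray,
    *,
    frequencies: Sequence[float] = (0.1, 0.2),
    n_orientations: int = 4,
    block_grid: int = 8,
) -> np.ndarray:
    """Gabor-bank texture features for one 160x160 grayscale frame.

    The image is mean-centered (killing the DC response), filtered with
    ``len(frequencies) * n_orientations`` Gabor filters, and each response
    magnitude is averaged over a ``block_grid x block_grid`` tiling; the
    per-filter block means are concatenated. Deterministic.
    """
    from skimage.filters import gabor

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FeatureError(f"expected a single-channel image, got ndim={image.ndim}")
    if image.shape != (FACE_IMAGE_SIZE, FACE_IMAGE_SIZE):
        raise FeatureError(
            f"expected {FACE_IMAGE_SIZE}x{FACE_IMAGE_SIZE} image, got {image.shape}"
        )
    if image.shape[0] % block_grid:
        raise FeatureError("block_grid must divide the image size")
    centered = image - image.mean()
    block = image.shape[0] // block_grid

    features: list[np.ndarray] = []
    for frequency in frequencies:
        for o in range(n_orientations):
            theta = np.pi * o / n_orientations
            real, imag = gabor(centered, frequency=frequency, theta=theta)
            magnitude = np.hypot(real, imag)
            blocks = magnitude.reshape(block_grid, block, block_grid, block)
            features.append(blocks.mean(axis=(1, 3)).ravel())
    return np.concatenate(features)


def load_gaze_csv(path: str | Path, *, rate: float = 60.0, screen=(1280, 720)) -> GazeTrace:
    """Read a gaze CSV with columns t_s, x_px, y_px, valid (0/1)."""
    frame = pd.read_csv(path)
    required = ["t_s", "x_px", "y_px", "valid"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FeatureError(f"{path}: missing column(s) {', '.join(missing)}")
    return GazeTrace(
        t=frame["t_s"].to_numpy(float),
        x=frame["x_px"].to_numpy(float),
        y=frame["y_px"].to_numpy(float),
        valid=frame["valid"].to_numpy(int).astype(bool),
        rate=rate,
        screen=tuple(screen),
    )


def save_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": trace.t,
            "x_px": trace.x,
            "y_px": trace.y,
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, index=False)


def detect_face_roi(image: np.ndarray) -> tuple[int, int, int, int]:
    """Optional Viola-Jones face localization via OpenCV, if installed.

    Returns (x, y, w, h) of the largest detected face. The tested pipeline
    path consumes pre-cropped frames; this adapter exists for real camera
    input only.
    """
    try:
        import cv2
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "face detection requires opencv-python; install it or supply "
            "pre-cropped face frames"
        ) from exc
    cascade = cv2.CascadeClassifier(
        cv2.data.haarcascades + "haarcascade_frontalface_default.xml"
    )
    gray = image if image.ndim == 2 else cv2.cvtColor(image, cv2.COLOR_BGR2GRAY)
    faces = cascade.detectMultiScale(gray.astype(np.uint8), 1.1, 4)
    if len(faces) == 0:
        raise FeatureError("no face detected")
    areas = [w * h for (_, _, w, h) in faces]
    return tuple(int(v) for v in faces[int(np.argmax(areas))])
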