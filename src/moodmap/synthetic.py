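"""Seeded generators for cohort scores, gaze traces, and smile sequences.

Every generator is deterministic under its seed and ships ground truth, so
the whole pipeline is testable without any subject data. Default cluster
coordinates are synthetic stand-ins chosen to reproduce the qualitative
quadrant layout of the five mood categories (two positive, one neutral,
two negative); they are package constants, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import GazeTrace
from .psychometrics import COMPONENT_NAMES, ComponentScores
from .rsom import FaceSequence

__all__ = [
    "DEFAULT_SESSION_COUNTS",
    "DEFAULT_CLUSTERS",
    "CohortSpec",
    "GazeSpec",
    "SmileSpec",
    "generate_cohort",
    "generate_gaze",
    "generate_smile_sequence",
    "cohort_manifest_frame",
]


class SyntheticError(ValueError):
    pass


#: Per-subject measurement counts of the reference cohort: 20 subjects,
#: ten measured 4 times and ten measured 8 times (120 sessions total).
DEFAULT_SESSION_COUNTS: dict[str, int] = {
    "A": 4, "B": 4, "C": 4, "D": 4, "E": 4,
    "F": 8, "G": 8, "H": 8, "I": 8, "J": 8,
    "K": 4, "L": 4, "M": 4, "N": 4, "O": 4,
    "P": 8, "Q": 8, "R": 8, "S": 8, "T": 8,
}

#: Synthetic five-cluster layout in the (TMD, F) plane, T-score-like units:
#: A, B positive; C neutral; D, E negative quadrant positions.
DEFAULT_CLUSTERS: dict[str, dict] = {
    "A": {"mean": (30.0, 70.0), "semantic": "positive"},
    "B": {"mean": (40.0, 60.0), "semantic": "positive"},
    "C": {"mean": (50.0, 50.0), "semantic": "neutral"},
    "D": {"mean": (60.0, 40.0), "semantic": "negative"},
    "E": {"mean": (70.0, 30.0), "semantic": "negative"},
}

#: Behavior parameters per mood cluster used when simulating full sessions:
#: positive moods gaze more concentratedly with fewer saccades and smile in
#: regular tempo cycles; negative moods disperse and smile irregularly.
CLUSTER_BEHAVIOR: dict[str, dict] = {
    "A": {"dispersion": 30.0, "saccades": 4, "smile_cycles": 6},
    "B": {"dispersion": 60.0, "saccades": 8, "smile_cycles": 5},
    "C": {"dispersion": 110.0, "saccades": 14, "smile_cycles": 4},
    "D": {"dispersion": 170.0, "saccades": 20, "smile_cycles": 3},
    "E": {"dispersion": 240.0, "saccades": 28, "smile_cycles": 2},
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort shape plus mood-cluster geometry in the (TMD, F) plane."""

    session_counts: tuple[tuple[str, int], ...] = tuple(DEFAULT_SESSION_COUNTS.items())
    cluster_means: tuple[tuple[float, float], ...] = tuple(
        c["mean"] for c in DEFAULT_CLUSTERS.values()
    )
    cluster_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.session_counts:
            raise SyntheticError("need at least one subject")
        if self.cluster_sigma < 0:
            raise SyntheticError("cluster_sigma must be >= 0")


@dataclass(frozen=True)
class GazeSpec:
    """Fixation/saccade regime parameters for one synthetic session."""

    duration: float = 20.0
    rate: float = 60.0
    fixation_sigma: float = 2.0  # within-fixation jitter, px (keeps jitter
    # speeds well under the 1000 px/s saccade threshold at 60 Hz)
    n_saccades: int = 6
    amplitude_range: tuple[float, float] = (150.0, 400.0)
    dispersion: float = 80.0  # spread of fixation centers around screen center
    screen: tuple[int, int] = (1280, 720)
    ballistic_samples: int = 1  # 1 = instantaneous jumps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise SyntheticError("duration and rate must be positive")
        if self.n_saccades < 0:
            raise SyntheticError("n_saccades must be >= 0")


@dataclass(frozen=True)
class SmileSpec:
    """Trapezoidal neutral->smile->neutral tempo-cycle parameters."""

    n_cycles: int = 4
    frames_per_cycle: int = 40
    plateau_fraction: float = 0.8
    neutral_frames: int = 40  # expressionless gap between cycles
    noise_sigma: float = 0.05
    feature_mode: str = "vectors"  # "vectors" or "images"
    dim: int = 16  # vector-mode feature dimensionality
    smile_amplitude: float = 1.0
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise SyntheticError("n_cycles must be >= 0")
        if not (0.0 < self.plateau_fraction <= 1.0):
            raise SyntheticError("plateau_fraction must be in (0, 1]")
        if self.feature_mode not in ("vectors", "images"):
            raise SyntheticError(f"unknown feature_mode {self.feature_mode!r}")


def cohort_manifest_frame(spec: CohortSpec | None = None) -> pd.DataFrame:
    """The cohort manifest as a (subject, n_sessions) table."""
    spec = spec or CohortSpec()
    return pd.DataFrame(
        {"subject_id": [s for s, _ in spec.session_counts],
         "n_sessions": [n for _, n in spec.session_counts]}
    )


def _decompose_components(
    tmd_target: float, f_target: float, rng: np.random.Generator
) -> dict[str, float]:
    """Split a planted (TMD, F) pair into seven non-negative components.

    VA is drawn first, the five positive components share TMD + VA via a
    Dirichlet split, and F passes through directly; infeasible draws
    (negative forced score) are resampled.
    """
    if f_target < 0:
        raise SyntheticError(f"planted F must be >= 0, got {f_target}")
    for _ in range(100):
        va = rng.uniform(5.0, 15.0)
        positive_sum = tmd_target + va
        if positive_sum < 0:
            continue
        shares = rng.dirichlet(np.ones(5)) * positive_sum
        return {
            "AH": float(shares[0]),
            "CB": float(shares[1]),
            "DD": float(shares[2]),
            "FI": float(shares[3]),
            "TA": float(shares[4]),
            "VA": float(va),
            "F": float(f_target),
        }
    raise SyntheticError(
        f"cannot decompose TMD={tmd_target} into non-negative components"
    )


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[ComponentScores], dict[tuple[str, int], int]]:
    """Generate component scores for a full cohort with ground-truth clusters.

    Each subject is assigned a home cluster (round-robin over the cluster
    list); per-session (TMD, F) targets are drawn around the cluster mean
    and decomposed into seven component scores such that
    AH+CB+DD+FI+TA-VA reproduces the planted TMD exactly. Returns the
    score records and a {(subject, session): cluster index} ground truth.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    centers = np.asarray(spec.cluster_means, dtype=float)
    records: list[ComponentScores] = []
    gt: dict[tuple[str, int], int] = {}
    for subject_pos, (subject, n_sessions) in enumerate(spec.session_counts):
        cluster = subject_pos % len(centers)
        for session in range(1, n_sessions + 1):
            tmd_t, f_t = rng.normal(centers[cluster], spec.cluster_sigma)
            f_t = max(f_t, 0.0)
            components = _decompose_components(tmd_t, f_t, rng)
            records.append(
                ComponentScores(subject_id=subject, session_index=session, **components)
            )
            gt[(subject, session)] = cluster
    return records, gt


def save_cohort_csv(records: Sequence[ComponentScores], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "session": r.session_index,
                **{name: getattr(r, name) for name in COMPONENT_NAMES},
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False)


def generate_gaze(spec: GazeSpec | None = None) -> tuple[GazeTrace, dict]:
    """Generate a fixation/saccade gaze trace with planted ground truth.

    Fixation centers are drawn around the screen center with spread
    ``dispersion``; the trace alternates jittered fixations and (by
    default) one-sample saccadic jumps. Ground truth holds the planted
    saccade count and the fixation centers.
    """
    spec = spec or GazeSpec()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.rate))
    w, h = spec.screen
    center = np.array([w / 2.0, h / 2.0])

    k = spec.n_saccades
    # split samples into k+1 fixation segments, each at least 3 samples:
    # draw a uniform composition of the surplus over the segments
    n_segments = k + 1
    min_len = 3
    surplus = n_samples - min_len * n_segments
    if surplus < 0:
        raise SyntheticError("duration too short for requested saccade count")
    dividers = np.sort(rng.integers(0, surplus + 1, size=k)) if k else np.array([], dtype=int)
    gaps = np.diff(np.concatenate([[0], dividers, [surplus]]))
    lengths = min_len + gaps
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    cuts = bounds[1:-1]

    margin = 50.0
    fix_centers = []
    previous = None
    for _ in range(n_segments):
        for _ in range(200):
            candidate = rng.normal(center, spec.dispersion)
            candidate = np.clip(candidate, margin, [w - margin, h - margin])
            if previous is None:
                break
            amp = np.linalg.norm(candidate - previous)
            lo, hi = spec.amplitude_range
            if lo <= amp:
                break
        fix_centers.append(candidate)
        previous = candidate

    xs = np.empty(n_samples)
    ys = np.empty(n_samples)
    for seg, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:])):
        count = stop - start
        jitter = rng.normal(0.0, spec.fixation_sigma, size=(count, 2))
        pts = fix_centers[seg] + jitter
        xs[start:stop] = np.clip(pts[:, 0], 0, w - 1)
        ys[start:stop] = np.clip(pts[:, 1], 0, h - 1)

    t = np.arange(n_samples) / spec.rate
    trace = GazeTrace(
        t=t,
        x=xs,
        y=ys,
        valid=np.ones(n_samples, dtype=bool),
        rate=spec.rate,
        screen=spec.screen,
    )
    gt = {
        "saccade_count": k,
        "saccade_samples": [int(c) for c in cuts],
        "fixation_centers": [list(map(float, c)) for c in fix_centers],
    }
    return trace, gt


def _intensity_profile(spec: SmileSpec) -> np.ndarray:
    """Per-frame smile intensity: trapezoidal cycles separated by neutral gaps."""
    cycle = np.zeros(spec.frames_per_cycle)
    plateau = max(1, int(round(spec.plateau_fraction * spec.frames_per_cycle)))
    ramp = (spec.frames_per_cycle - plateau) // 2
    fall = spec.frames_per_cycle - plateau - ramp
    if ramp > 0:
        cycle[:ramp] = np.linspace(0.0, 1.0, ramp + 2)[1:-1]
    cycle[ramp : ramp + plateau] = 1.0
    if fall > 0:
        cycle[ramp + plateau :] = np.linspace(1.0, 0.0, fall + 2)[1:-1]
    gap = np.zeros(spec.neutral_frames)
    parts = [gap]
    for _ in range(spec.n_cycles):
        parts.extend([cycle, gap])
    profile = np.concatenate(parts) if spec.n_cycles else np.concatenate([gap, gap])
    return profile


def _render_face(intensity: float, size: int = 160) -> np.ndarray:
    """Parametric grayscale face: ellipse head, two eyes, mouth whose
    curvature tracks smile intensity."""
    from skimage.draw import disk, ellipse

    img = np.zeros((size, size))
    rr, cc = ellipse(size // 2, size // 2, size * 0.42, size * 0.34, shape=img.shape)
    img[rr, cc] = 0.55
    for cx in (size * 0.38, size * 0.62):
        rr, cc = disk((size * 0.40, cx), size * 0.035, shape=img.shape)
        img[rr, cc] = 0.05
    # mouth: parabola, corners rise and center drops as intensity grows
    xs = np.arange(int(size * 0.32), int(size * 0.68))
    rel = (xs - size / 2.0) / (size * 0.18)
    curve = size * 0.66 + size * 0.07 * intensity * (rel**2 - 0.5)
    width = 1 + int(round(2 * intensity))
    for x, yc in zip(xs, curve):
        y0 = int(round(yc))
        img[max(y0 - width, 0) : y0 + width + 1, x] = 0.05
    return img


def generate_smile_sequence(spec: SmileSpec | None = None) -> FaceSequence:
    """Generate a neutral->smile->neutral tempo-cycle face sequence.

    In vector mode each frame is ``base + intensity * amplitude * direction
    + noise``; in image mode a parametric 160x160 face is rendered per
    frame. Ground-truth smile flags mark frames with intensity > 0.5.
    """
    spec = spec or SmileSpec()
    rng = np.random.default_rng(spec.seed)
    intensity = _intensity_profile(spec)
    flags = intensity > 0.5

    if spec.feature_mode == "vectors":
        base = rng.normal(0.0, 1.0, size=spec.dim)
        direction = rng.normal(0.0, 1.0, size=spec.dim)
        direction /= np.linalg.norm(direction)
        noise = rng.normal(0.0, spec.noise_sigma, size=(intensity.size, spec.dim))
        frames = base + spec.smile_amplitude * intensity[:, None] * direction + noise
    else:
        from .features import gabor_frame_features

        images, _ = render_smile_images(spec)
        frames = np.stack([gabor_frame_features(img) for img in images])
    return FaceSequence(frames=frames, frame_rate=spec.frame_rate, smile_flags=flags)


def render_smile_images(spec: SmileSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw 160x160 face images for the tempo profile, plus smile flags."""
    rng = np.random.default_rng(spec.seed)
    intensity = _intensity_profile(spec)
    images = np.stack(
        [
            np.clip(
                _render_face(v) + rng.normal(0.0, spec.noise_sigma, size=(160, 160)),
                0.0,
                1.0,
            )
            for v in intensity
        ]
    )
    return images, intensity > 0.5
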