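"""Mood-score psychometrics: component scores, TMD/F indicators, T-scores.

The seven mood components (AH, CB, DD, FI, TA, VA, F) are combined into two
session-level indicators: TMD, the primary mood-disturbance composite, and F,
an independent friendliness component. Both are linearly standardized to
T-scores (mean 50, sd 10) before any downstream clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENT_NAMES",
    "ComponentScores",
    "MoodPoint",
    "compute_tmd",
    "t_score",
    "load_poms_csv",
    "mood_points",
    "save_mood_csv",
]

#: Canonical component order used in CSV files and validation messages.
COMPONENT_NAMES = ("AH", "CB", "DD", "FI", "TA", "VA", "F")

#: Normative axis-crossing constants for semantic labeling (configurable;
#: see :func:`moodmap.umatrix.assign_semantic_labels`).
TMD_NORM_MEAN = 55.0
F_NORM_MEAN = 49.0


class PsychometricsError(ValueError):
    """Raised for invalid component scores or malformed score files."""


@dataclass(frozen=True)
class ComponentScores:
    """One session's seven raw mood-component scores.

    All scores must be finite and non-negative; ``(subject_id,
    session_index)`` identifies the session.
    """

    subject_id: str
    session_index: int
    AH: float
    CB: float
    DD: float
    FI: float
    TA: float
    VA: float
    F: float

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise PsychometricsError(
                f"session_index must be a positive integer, got {self.session_index}"
            )
        for name in COMPONENT_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise PsychometricsError(
                    f"component {name} is not finite for subject "
                    f"{self.subject_id!r} session {self.session_index}: {value!r}"
                )
            if value < 0:
                raise PsychometricsError(
                    f"component {name} is negative for subject "
                    f"{self.subject_id!r} session {self.session_index}: {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COMPONENT_NAMES], dtype=float)


@dataclass(frozen=True)
class MoodPoint:
    """A session's (TMD, F) pair in T-score units."""

    subject_id: str
    session_index: int
    TMD: float
    F: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.TMD) and math.isfinite(self.F)):
            raise PsychometricsError(
                f"non-finite mood point for subject {self.subject_id!r} "
                f"session {self.session_index}: TMD={self.TMD!r} F={self.F!r}"
            )


def compute_tmd(scores: ComponentScores) -> float:
    """Total mood disturbance: AH + CB + DD + FI + TA - VA.

    VA enters with a negative sign (the vigor component is inverted).
    """
    return float(
        scores.AH + scores.CB + scores.DD + scores.FI + scores.TA - scores.VA
    )


def t_score(
    raw: Sequence[float] | np.ndarray,
    *,
    mean: float | None = None,
    sd: float | None = None,
) -> np.ndarray:
    """Linearly standardize ``raw`` to T-scores (mean 50, sd 10).

    By default the sample's own mean and standard deviation (``ddof=1``)
    are used, so the output has sample mean 50 and sample sd 10 exactly
    (to floating tolerance). Pass ``mean`` and ``sd`` together to
    standardize against external norms instead.

    Raises
    ------
    PsychometricsError
        If fewer than two values are given, the sample is constant, or
        only one of ``mean``/``sd`` is supplied.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise PsychometricsError(f"expected a 1-D sequence, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise PsychometricsError("t_score input contains non-finite values")
    if (mean is None) != (sd is None):
        raise PsychometricsError("external norms require both mean and sd")
    if mean is None:
        if x.size < 2:
            raise PsychometricsError(
                f"need at least 2 values for self-normalization, got {x.size}"
            )
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise PsychometricsError("cannot standardize a constant sample (sd = 0)")
    elif sd <= 0:
        raise PsychometricsError(f"external sd must be positive, got {sd}")
    return 50.0 + 10.0 * (x - mean) / sd


def load_poms_csv(path: str | Path) -> list[ComponentScores]:
    """Read a component-score CSV into a list of :class:`ComponentScores`.

    The file must have a header with columns ``subject_id, session, AH, CB,
    DD, FI, TA, VA, F``. Row order is preserved. Errors name the offending
    column or row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"subject_id": str})
    except Exception as exc:  # pragma: no cover - passthrough context
        raise PsychometricsError(f"cannot read {path}: {exc}") from exc

    required = ["subject_id", "session", *COMPONENT_NAMES]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PsychometricsError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )

    records: list[ComponentScores] = []
    seen: set[tuple[str, int]] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        try:
            session = int(data["session"])
            values = {name: float(data[name]) for name in COMPONENT_NAMES}
        except (TypeError, ValueError) as exc:
            raise PsychometricsError(
                f"{path} row {row_number}: non-numeric cell ({exc})"
            ) from exc
        key = (str(data["subject_id"]), session)
        if key in seen:
            raise PsychometricsError(
                f"{path} row {row_number}: duplicate (subject, session) {key}"
            )
        seen.add(key)
        try:
            records.append(
                ComponentScores(
                    subject_id=str(data["subject_id"]),
                    session_index=session,
                    **values,
                )
            )
        except PsychometricsError as exc:
            raise PsychometricsError(f"{path} row {row_number}: {exc}") from exc
    return records


def mood_points(
    scores: Iterable[ComponentScores],
    *,
    order: str = "raw-then-t",
    tmd_norms: tuple[float, float] | None = None,
    f_norms: tuple[float, float] | None = None,
) -> list[MoodPoint]:
    """Convert component scores into (TMD, F) mood points in T-score units.

    ``order`` selects the computation order:

    * ``"raw-then-t"`` (default): TMD is computed from raw components for
      every session, then the TMD and F columns are each T-scored across
      the dataset.
    * ``"t-then-raw"``: every component column is T-scored across the
      dataset first, then TMD is formed from the standardized components.

    ``tmd_norms`` / ``f_norms`` are optional external (mean, sd) pairs for
    norm-referenced standardization; by default the loaded sample
    self-normalizes.
    """
    records = list(scores)
    if not records:
        raise PsychometricsError("no component scores supplied")
    if order not in ("raw-then-t", "t-then-raw"):
        raise PsychometricsError(f"unknown order {order!r}")

    if order == "raw-then-t":
        tmd_raw = np.array([compute_tmd(r) for r in records])
        f_raw = np.array([r.F for r in records])
    else:
        columns = {
            name: np.array([getattr(r, name) for r in records])
            for name in COMPONENT_NAMES
        }
        standardized = {name: t_score(col) for name, col in columns.items()}
        tmd_raw = (
            standardized["AH"]
            + standardized["CB"]
            + standardized["DD"]
            + standardized["FI"]
            + standardized["TA"]
            - standardized["VA"]
        )
        f_raw = standardized["F"]

    tmd_kwargs = {} if tmd_norms is None else {"mean": tmd_norms[0], "sd": tmd_norms[1]}
    f_kwargs = {} if f_norms is None else {"mean": f_norms[0], "sd": f_norms[1]}
    tmd_t = t_score(tmd_raw, **tmd_kwargs)
    f_t = t_score(f_raw, **f_kwargs)
    return [
        MoodPoint(
            subject_id=r.subject_id,
            session_index=r.session_index,
            TMD=float(tmd),
            F=float(f),
        )
        for r, tmd, f in zip(records, tmd_t, f_t)
    ]


def save_mood_csv(points: Sequence[MoodPoint], path: str | Path) -> None:
    """Write mood points as CSV with columns subject_id, session, TMD, F."""
    frame = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in points],
            "session": [p.session_index for p in points],
            "TMD": [p.TMD for p in points],
            "F": [p.F for p in points],
        }
    )
    frame.to_csv(path, index=False)
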