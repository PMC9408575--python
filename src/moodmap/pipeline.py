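"""End-to-end orchestration: fusion inputs, SOM + U-Matrix maps, artifacts.

Fusion patterns combine the two psychometric indicators with behavioral
features:

* ``TMD_F`` — TMD, F only
* ``I``    — TMD, F, E (gaze extent), S (saccades)
* ``II``   — TMD, F, R (smile frames), G (expression-tree leaf count)
* ``III``  — TMD, F, E, S, R, G

Columns are z-scored over sessions before SOM input (switchable to
min-max), since raw scales differ by orders of magnitude.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as features_mod
from . import ghsom as ghsom_mod
from . import psychometrics as psych
from . import rsom as rsom_mod
from . import som as som_core
from . import synthetic as synth
from . import umatrix as umatrix_mod

__all__ = [
    "FusionRecord",
    "RunConfig",
    "assemble_features",
    "compute_behavior_features",
    "simulate_dataset",
    "run_pipeline",
    "PATTERN_COLUMNS",
]

logger = logging.getLogger("moodmap")

PATTERN_COLUMNS: dict[str, tuple[str, ...]] = {
    "TMD_F": ("TMD", "F"),
    "I": ("TMD", "F", "E", "S"),
    "II": ("TMD", "F", "R", "G"),
    "III": ("TMD", "F", "E", "S", "R", "G"),
}


class PipelineError(ValueError):
    pass


@dataclass
class FusionRecord:
    """One session's fused feature values (optional fields may be absent)."""

    subject_id: str
    session: int
    TMD: float
    F: float
    E: float | None = None
    S: float | None = None
    R: float | None = None
    G: float | None = None


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration with reference defaults.

    ``rsom_epochs`` / ``ghsom_epochs`` default lower than the map training
    schedule because they run once per session.
    """

    pattern: str = "TMD_F"
    map_shape: tuple[int, int] = (50, 50)
    alpha0: float = 0.1
    psi0: int = 40
    epochs: int = 200
    threshold_quantile: float = 0.60
    min_region: int = 25
    tmd_ref: float = umatrix_mod.TMD_REF
    f_ref: float = umatrix_mod.F_REF
    normalization: str = "zscore"  # or "minmax"
    rsom_epochs: int = 40
    ghsom_epochs: int = 30
    seed: int = 0
    out_dir: str = "moodmap_out"

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_COLUMNS:
            raise PipelineError(
                f"pattern must be one of {sorted(PATTERN_COLUMNS)}, got {self.pattern!r}"
            )
        if self.normalization not in ("zscore", "minmax"):
            raise PipelineError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "map_shape" in data:
            data["map_shape"] = tuple(data["map_shape"])
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["map_shape"] = list(self.map_shape)
        return data


def assemble_features(
    records: Sequence[FusionRecord],
    pattern: str,
    normalization: str = "zscore",
) -> tuple[np.ndarray, list[str]]:
    """Build the per-session feature matrix for a fusion pattern.

    Column order is fixed (TMD, F, E, S, R, G as applicable); each column
    is normalized over sessions. Missing required fields raise an error
    naming the affected sessions.
    """
    if pattern not in PATTERN_COLUMNS:
        raise PipelineError(f"unknown pattern {pattern!r}")
    columns = PATTERN_COLUMNS[pattern]
    missing: list[str] = []
    for record in records:
        absent = [c for c in columns if getattr(record, c) is None]
        if absent:
            missing.append(
                f"{record.subject_id}/{record.session} lacks {','.join(absent)}"
            )
    if missing:
        raise PipelineError(
            f"pattern {pattern} requires fields missing for: " + "; ".join(missing)
        )
    matrix = np.array(
        [[float(getattr(r, c)) for c in columns] for r in records], dtype=float
    )
    for col in range(matrix.shape[1]):
        v = matrix[:, col]
        if normalization == "zscore":
            sd = v.std()
            matrix[:, col] = (v - v.mean()) / sd if sd > 0 else 0.0
        else:
            span = v.max() - v.min()
            matrix[:, col] = (v - v.min()) / span if span > 0 else 0.0
    return matrix, list(columns)


def compute_behavior_features(
    record: FusionRecord,
    gaze: features_mod.GazeTrace | None,
    faces: rsom_mod.FaceSequence | None,
    cfg: RunConfig,
) -> FusionRecord:
    """Fill E, S from a gaze trace and R, G from a face sequence in place."""
    if gaze is not None:
        gf = features_mod.gaze_features(gaze)
        record.E = float(gf.E)
        record.S = float(gf.S)
    if faces is not None:
        rsom_cfg = rsom_mod.RsomConfig(epochs=cfg.rsom_epochs, seed=cfg.seed)
        rmap = rsom_mod.train_rsom(faces.frames, rsom_cfg)
        extraction = rsom_mod.extract_smiles(faces, rmap)
        record.R = float(extraction.R)
        tree = ghsom_mod.build_tree(
            rmap.weights,
            ghsom_mod.GhsomConfig(epochs=cfg.ghsom_epochs, seed=cfg.seed),
        )
        record.G = float(tree.G)
    return record


def simulate_dataset(
    out_dir: str | Path,
    cohort_spec: synth.CohortSpec | None = None,
    *,
    seed: int = 0,
    gaze_duration: float = 20.0,
    smile_template: synth.SmileSpec | None = None,
    write_face_images: bool = False,
) -> Path:
    """Write a full synthetic cohort directory tree.

    Layout: ``poms.csv``, ``gaze/<subject>_<session>.csv``,
    ``faces/<subject>_<session>.csv`` (per-frame feature vectors plus a
    ground-truth smile column), and ``gt.json``. Per-session behavioral
    parameters follow the session's ground-truth mood cluster so gaze and
    smile statistics correlate with mood, as the fusion analysis assumes.
    """
    out = Path(out_dir)
    (out / "gaze").mkdir(parents=True, exist_ok=True)
    (out / "faces").mkdir(parents=True, exist_ok=True)
    cohort_spec = cohort_spec or synth.CohortSpec(seed=seed)
    records, gt = synth.generate_cohort(cohort_spec)
    synth.save_cohort_csv(records, out / "poms.csv")

    cluster_names = list(synth.DEFAULT_CLUSTERS)
    seeds = np.random.SeedSequence(seed).spawn(2 * len(records))
    gt_out = {
        "clusters": {f"{s}/{i}": c for (s, i), c in gt.items()},
        "saccades": {},
        "smile_frames": {},
    }
    for pos, record in enumerate(records):
        key = (record.subject_id, record.session_index)
        cluster = gt[key]
        behavior = synth.CLUSTER_BEHAVIOR[cluster_names[cluster % len(cluster_names)]]
        gaze_seed = int(seeds[2 * pos].generate_state(1)[0])
        face_seed = int(seeds[2 * pos + 1].generate_state(1)[0])
        trace, trace_gt = synth.generate_gaze(
            synth.GazeSpec(
                duration=gaze_duration,
                n_saccades=behavior["saccades"],
                dispersion=behavior["dispersion"],
                seed=gaze_seed,
            )
        )
        stem = f"{record.subject_id}_{record.session_index}"
        features_mod.save_gaze_csv(trace, out / "gaze" / f"{stem}.csv")
        gt_out["saccades"][f"{key[0]}/{key[1]}"] = trace_gt["saccade_count"]

        template = smile_template or synth.SmileSpec()
        seq = synth.generate_smile_sequence(
            dataclasses.replace(
                template, n_cycles=behavior["smile_cycles"], seed=face_seed
            )
        )
        frame = pd.DataFrame(seq.frames)
        frame["smile_gt"] = seq.smile_flags.astype(int)
        frame.to_csv(out / "faces" / f"{stem}.csv", index=False)
        gt_out["smile_frames"][f"{key[0]}/{key[1]}"] = int(seq.smile_flags.sum())

        if write_face_images:
            from PIL import Image

            img_dir = out / "faces" / stem
            img_dir.mkdir(exist_ok=True)
            spec = synth.SmileSpec(
                n_cycles=behavior["smile_cycles"], seed=face_seed, feature_mode="images"
            )
            images, _ = synth.render_smile_images(spec)
            for i, img in enumerate(images):
                Image.fromarray((img * 255).astype(np.uint8)).save(
                    img_dir / f"frame_{i:04d}.png"
                )

    (out / "gt.json").write_text(json.dumps(gt_out, sort_keys=True, indent=1))
    return out


def load_face_csv(path: str | Path) -> rsom_mod.FaceSequence:
    frame = pd.read_csv(path)
    flags = None
    if "smile_gt" in frame.columns:
        flags = frame.pop("smile_gt").to_numpy(int).astype(bool)
    return rsom_mod.FaceSequence(frames=frame.to_numpy(float), smile_flags=flags)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, data_dir: str | Path) -> dict:
    """Run the full analysis over a dataset directory and write artifacts.

    Stages: psychometrics -> behavioral features (as the pattern requires)
    -> fusion assembly -> SOM -> U-Matrix -> segmentation -> semantic
    labels. Artifacts land in ``cfg.out_dir``: U-Matrix PNG + CSV,
    segmentation JSON, category membership report, fusion CSV, and a run
    manifest (config, seed, input hashes). Reruns with the same manifest
    reproduce identical JSON artifacts.
    """
    data_dir = Path(data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = round(time.perf_counter() - timings[name], 3)

    name = stage("psychometrics")
    poms_path = data_dir / "poms.csv"
    try:
        scores = psych.load_poms_csv(poms_path)
        points = psych.mood_points(scores)
    except Exception as exc:
        raise PipelineError(f"stage psychometrics failed on {poms_path}: {exc}") from exc
    records = [
        FusionRecord(
            subject_id=p.subject_id, session=p.session_index, TMD=p.TMD, F=p.F
        )
        for p in points
    ]
    done(name)

    columns = PATTERN_COLUMNS[cfg.pattern]
    need_gaze = "E" in columns or "S" in columns
    need_faces = "R" in columns or "G" in columns
    if need_gaze or need_faces:
        name = stage("behavior")
        for record in records:
            stem = f"{record.subject_id}_{record.session}"
            gaze = None
            faces = None
            try:
                if need_gaze:
                    gaze = features_mod.load_gaze_csv(data_dir / "gaze" / f"{stem}.csv")
                if need_faces:
                    faces = load_face_csv(data_dir / "faces" / f"{stem}.csv")
                compute_behavior_features(record, gaze, faces, cfg)
            except Exception as exc:
                raise PipelineError(
                    f"stage behavior failed for session {stem}: {exc}"
                ) from exc
        done(name)

    name = stage("fusion")
    matrix, column_names = assemble_features(records, cfg.pattern, cfg.normalization)
    fusion_frame = pd.DataFrame(matrix, columns=column_names)
    fusion_frame.insert(0, "subject_id", [r.subject_id for r in records])
    fusion_frame.insert(1, "session", [r.session for r in records])
    fusion_frame.to_csv(out / "fusion.csv", index=False)
    done(name)

    name = stage("som")
    grid = som_core.train(
        matrix,
        som_core.TrainConfig(
            alpha0=cfg.alpha0, psi0=cfg.psi0, epochs=cfg.epochs, seed=cfg.seed
        ),
        shape=cfg.map_shape,
    )
    done(name)

    name = stage("umatrix")
    field = umatrix_mod.compute_umatrix(grid)
    np.savetxt(out / "umatrix.csv", field.values, delimiter=",")
    seg = umatrix_mod.segment_categories(
        field, grid, cfg.threshold_quantile, min_region=cfg.min_region
    )
    bmus = som_core.bmu_indices(grid, matrix)
    umatrix_mod.assign_semantic_labels(
        seg, points, bmus, tmd_ref=cfg.tmd_ref, f_ref=cfg.f_ref
    )
    seg.save_json(out / "segmentation.json")
    umatrix_mod.render_umatrix(field, out / "umatrix.png", seg=seg)
    done(name)

    name = stage("report")
    boundary_threshold = float(np.quantile(field.values, cfg.threshold_quantile))
    boundary_mask = field.values > boundary_threshold
    report = {
        "pattern": cfg.pattern,
        "n_sessions": len(records),
        "n_categories": len(seg.categories),
        "mean_boundary_u": float(field.values[boundary_mask].mean())
        if boundary_mask.any()
        else 0.0,
        "mean_u": float(field.values.mean()),
        "categories": [
            {
                "id": c.id,
                "semantic": c.semantic,
                "mean_tmd": c.mean_tmd,
                "mean_f": c.mean_f,
                "n_units": len(c.units),
                "members": [f"{s}/{i}" for s, i in c.members],
            }
            for c in seg.categories
        ],
    }
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))

    inputs_hashed = {
        str(p.relative_to(data_dir)): _sha256(p)
        for p in sorted(data_dir.rglob("*.csv"))
    }
    manifest = {
        "config": cfg.to_dict(),
        "input_hashes": inputs_hashed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    # timings are diagnostics, not part of the reproducible artifact set
    (out / "timings.log").write_text(
        "".join(f"{k}\t{v}\n" for k, v in timings.items())
    )
    done(name)
    report["out_dir"] = str(out)
    return report
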