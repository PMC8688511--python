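"""End-to-end study orchestration.

Three stages mirror a complete in vivo measurement session:

1. *Model accuracy* (:func:`run_validation`) — register an independently
   reconstructed copy of each vertebra onto its reference model and report
   per-level surface-deviation statistics.
2. *Registration accuracy* (:func:`run_kinematics`, accuracy table) — after
   registering each neutral model onto each end-position model, report the
   residual deviation per level and posture.
3. *6-DOF kinematics* (:func:`run_kinematics`, kinematics table) — carry the
   neutral anatomic frames through the registration transforms and decompose
   each upper-in-lower pose into translations and joint angles.

:func:`simulate` writes a complete synthetic study (meshes, landmarks and a
ground-truth manifest) that the two run functions can consume, so the whole
chain is exercisable without any imaging data.

File layout convention: ``<dir>/<level>_<posture>.stl`` for posture models,
``<level>_ct.stl`` for the independent validation copy, and
``<level>_landmarks.json``; a ``manifest.json`` records settings, seeds and
(for synthetic studies) ground-truth transforms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .frames import build_frame, read_landmarks, write_landmarks
from .kinematics import LEVEL_PAIRS, intervertebral_6dof
from .mesh_core import (
    POSTURES,
    DeviationReport,
    TriangleMesh,
    deviation_report,
    read_mesh,
    signed_distances,
    write_mesh,
)
from .registration import RigidTransform, apply_transform, icp_register, initial_align
from .synthetic import (
    MotionScenario,
    VertebraSpec,
    default_stack_frames,
    generate_vertebra,
    make_scenario,
    perturb_mesh,
    vertebra_landmarks,
)

__all__ = ["StudyConfig", "simulate", "run_validation", "run_kinematics"]

logger = logging.getLogger("cervkin")

_END_POSTURES = tuple(p for p in POSTURES if p != "neutral")


@dataclass
class StudyConfig:
    """Settings for one study run; echoed verbatim into the output manifest."""

    input_dir: str
    output_dir: str
    levels: Sequence[str] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")
    postures: Sequence[str] = _END_POSTURES
    file_format: str = "stl"
    init_mode: str = "centroid+principal_axes"
    tolerance: float = 1e-6
    max_iterations: int = 200
    euler_sequence: str = "yxz"
    kinematics_mode: str = "motion_from_neutral"
    log_level: str = "INFO"
    seed: int = 0

    @staticmethod
    def from_json(path) -> "StudyConfig":
        with open(path) as fh:
            return StudyConfig(**json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["postures"] = list(self.postures)
        return d

    def check_inputs(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory {self.input_dir} not found")


def _write_manifest(out_dir: Path, payload: dict) -> None:
    payload = {"cervkin_version": __version__, **payload}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# synthetic study generation
# ---------------------------------------------------------------------------

def simulate(
    output_dir,
    scenario: str | MotionScenario = "ar",
    levels: Sequence[str] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7"),
    postures: Sequence[str] = _END_POSTURES,
    seed: int = 0,
    noise_sigma: float = 0.2,
    remesh_factor: float = 1.0,
    pitch: float = 0.9,
    file_format: str = "stl",
) -> MotionScenario:
    """Write a synthetic multi-posture study with known ground truth.

    Per level: a clean reference model (``<level>_ct``), an independently
    perturbed neutral model (``<level>_neutral``), perturbed-and-moved
    models for the requested end postures, and the analytic landmark file.
    Each model variant uses its own perturbation seed, so no two share
    vertex correspondence — as two scans of the same bone would not.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = default_stack_frames(levels)
    if isinstance(scenario, str):
        scenario = make_scenario(scenario, frames=stack)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xce]))
    gt: dict = {"levels": {}, "scenario": scenario.description}
    for li, level in enumerate(levels):
        spec = VertebraSpec.for_level(level, pitch=pitch)
        mesh = generate_vertebra(spec)
        lms = vertebra_landmarks(spec)
        frame_local = build_frame(lms)
        # place the vertebra so its landmark frame coincides with the stack
        place = stack[level].as_transform().compose(
            frame_local.as_transform().inverse()
        )
        mesh = apply_transform(mesh, place)
        lms = lms.transformed(place)
        sub = int(rng.integers(0, 2**31 - 1))

        write_mesh(dataclasses.replace(mesh, posture="neutral"),
                   out / f"{level}_ct.{file_format}")
        neutral = perturb_mesh(mesh, noise_sigma, remesh_factor,
                               seed=sub)
        write_mesh(neutral, out / f"{level}_neutral.{file_format}")
        write_landmarks(lms, out / f"{level}_landmarks.json")
        gt["levels"][level] = {"postures": {}, "seed": sub}
        for posture in postures:
            t = scenario.transforms[posture][level]
            variant = perturb_mesh(mesh, noise_sigma, remesh_factor,
                                   seed=int(rng.integers(0, 2**31 - 1)))
            moved = apply_transform(variant, t)
            moved = dataclasses.replace(moved, posture=posture)
            write_mesh(moved, out / f"{level}_{posture}.{file_format}")
            gt["levels"][level]["postures"][posture] = t.to_dict()
    _write_manifest(out, {
        "kind": "synthetic_study",
        "settings": {
            "levels": list(levels), "postures": list(postures), "seed": seed,
            "noise_sigma": noise_sigma, "remesh_factor": remesh_factor,
            "pitch": pitch, "file_format": file_format,
        },
        "ground_truth": gt,
        "joints": scenario.joints,
    })
    return scenario


# ---------------------------------------------------------------------------
# phase 1: model accuracy
# ---------------------------------------------------------------------------

def run_validation(config: StudyConfig) -> pd.DataFrame:
    """Register each level's independent copy onto its reference model and
    tabulate the surface-deviation statistics (one row per level)."""
    config.check_inputs()
    logging.basicConfig(level=config.log_level)
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for level in config.levels:
        moving_path = in_dir / f"{level}_ct.{config.file_format}"
        target_path = in_dir / f"{level}_neutral.{config.file_format}"
        if not moving_path.is_file() or not target_path.is_file():
            logger.warning("level %s: model pair missing, row skipped", level)
            continue
        moving = read_mesh(moving_path, label=level, posture="neutral")
        target = read_mesh(target_path, label=level, posture="neutral")
        result = icp_register(
            moving, target,
            init=initial_align(moving, target, config.init_mode),
            max_iterations=config.max_iterations, tolerance=config.tolerance,
        )
        row = result.final_report.to_row()
        row["converged"] = result.converged
        rows.append(row)
        logger.info("level %s: mean |d| = %.3f mm", level,
                    result.final_report.mean_absolute_deviation)
    table = pd.DataFrame(rows, columns=[*DeviationReport.COLUMNS, "converged"])
    table.to_csv(out_dir / "model_accuracy.csv", index=False)
    _write_manifest(out_dir, {"kind": "validation",
                              "settings": config.to_dict()})
    return table


# ---------------------------------------------------------------------------
# phases 2 + 3: registration accuracy and 6-DOF kinematics
# ---------------------------------------------------------------------------

def run_kinematics(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Register neutral models to each end posture, then extract 6-DOF rows.

    Returns ``(kinematics_table, accuracy_table)`` and writes both CSVs, the
    per-level/per-posture transforms JSON and the run manifest to the output
    directory.  A registration that fails to converge is flagged in its data
    row; a missing neutral model is fatal.
    """
    config.check_inputs()
    logging.basicConfig(level=config.log_level)
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    neutral_meshes: dict[str, TriangleMesh] = {}
    neutral_frames = {}
    for level in config.levels:
        path = in_dir / f"{level}_neutral.{config.file_format}"
        if not path.is_file():
            raise FileNotFoundError(f"missing neutral model for {level}: {path}")
        neutral_meshes[level] = read_mesh(path, label=level, posture="neutral")
        neutral_frames[level] = build_frame(
            read_landmarks(in_dir / f"{level}_landmarks.json", level=level)
        )

    acc_rows = []
    transforms: dict[str, dict[str, RigidTransform]] = {}
    converged_flags: dict[tuple[str, str], bool] = {}
    for posture in config.postures:
        transforms[posture] = {}
        for level in config.levels:
            path = in_dir / f"{level}_{posture}.{config.file_format}"
            if not path.is_file():
                logger.warning("%s %s: model missing, skipped", level, posture)
                continue
            target = read_mesh(path, label=level, posture=posture)
            moving = neutral_meshes[level]
            result = icp_register(
                moving, target,
                init=initial_align(moving, target, config.init_mode),
                max_iterations=config.max_iterations,
                tolerance=config.tolerance,
            )
            if not result.converged:
                logger.warning("%s %s: registration did not converge",
                               level, posture)
            transforms[posture][level] = result.transform
            converged_flags[(posture, level)] = result.converged
            row = {"posture": posture, **result.final_report.to_row(),
                   "converged": result.converged}
            acc_rows.append(row)
    accuracy = pd.DataFrame(
        acc_rows, columns=["posture", *DeviationReport.COLUMNS, "converged"]
    )
    accuracy.to_csv(out_dir / "registration_accuracy.csv", index=False)

    kin_rows = []
    for posture in config.postures:
        for upper, lower in LEVEL_PAIRS:
            if upper not in transforms.get(posture, {}) or \
               lower not in transforms.get(posture, {}):
                continue
            res = intervertebral_6dof(
                neutral_frames, transforms, (upper, lower), posture,
                mode=config.kinematics_mode, sequence=config.euler_sequence,
            )
            row = res.as_row()
            row["converged"] = (converged_flags[(posture, upper)]
                                and converged_flags[(posture, lower)])
            kin_rows.append(row)
    kinematics = pd.DataFrame(kin_rows, columns=[
        "level_pair", "posture", "tx", "ty", "tz",
        "alpha", "gamma", "beta", "mode", "converged",
    ])
    kinematics.to_csv(out_dir / "kinematics.csv", index=False)

    with open(out_dir / "transforms.json", "w") as fh:
        json.dump(
            {p: {lvl: t.to_dict() for lvl, t in by_level.items()}
             for p, by_level in transforms.items()},
            fh, indent=2, sort_keys=True,
        )
    _write_manifest(out_dir, {"kind": "kinematics",
                              "settings": config.to_dict()})
    return kinematics, accuracy
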