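"""Per-vertebra anatomic coordinate frames built from bony landmarks.

Each vertebra carries a right-handed orthonormal frame: origin at the most
posterior-inferior point of the vertebral body in the mid-sagittal plane,
x axis positive to the patient's left, y axis positive superiorly, z axis
positive anteriorly.  The frame is constructed once on the neutral-position
model from four explicit landmarks and carried to end positions through the
registration transforms, so landmarking noise cancels within a subject.

Landmark files are JSON or CSV with named 3D points in the mesh's mm
coordinate system.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .registration import RigidTransform

__all__ = [
    "LandmarkSet",
    "AnatomicalFrame",
    "build_frame",
    "transform_frame",
    "read_landmarks",
    "write_landmarks",
]

_COLLINEAR_TOL = 1e-9

_LANDMARK_NAMES = (
    "origin_candidate",
    "superior_reference",
    "left_reference",
    "right_reference",
)


@dataclass
class LandmarkSet:
    """Four landmarks defining one vertebra's anatomic frame (mm).

    origin_candidate
        Most posterior-inferior point of the vertebral body, at or near the
        mid-sagittal plane.
    superior_reference
        Point defining, with the origin, the superior direction.
    left_reference / right_reference
        Bilaterally symmetric pair (e.g. the transverse-process tips); their
        difference defines the left axis and their midpoint the mid-sagittal
        plane.
    """

    origin_candidate: np.ndarray
    superior_reference: np.ndarray
    left_reference: np.ndarray
    right_reference: np.ndarray
    level: str | None = None

    def __post_init__(self) -> None:
        for name in _LANDMARK_NAMES:
            v = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            if not np.isfinite(v).all():
                raise ValueError(f"landmark {name} has non-finite coordinates")
            setattr(self, name, v)

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            *(t.apply(getattr(self, n)) for n in _LANDMARK_NAMES),
            level=self.level,
        )


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes (x left, y superior,
    z anterior), each checked to 1e-10."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        axes = [
            np.asarray(a, dtype=np.float64).reshape(3)
            for a in (self.x_axis, self.y_axis, self.z_axis)
        ]
        R = np.column_stack(axes)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if not np.allclose(np.cross(axes[0], axes[1]), axes[2], atol=1e-8):
            raise ValueError("frame is not right-handed (x cross y != z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", axes[0])
        object.__setattr__(self, "y_axis", axes[1])
        object.__setattr__(self, "z_axis", axes[2])

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as columns (frame -> world)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def as_transform(self) -> RigidTransform:
        """Rigid transform mapping frame-local coordinates to world."""
        return RigidTransform(self.rotation, self.origin)

    def to_dict(self) -> dict:
        return {
            "origin_mm": [float(v) for v in self.origin],
            "x_axis_left": [float(v) for v in self.x_axis],
            "y_axis_superior": [float(v) for v in self.y_axis],
            "z_axis_anterior": [float(v) for v in self.z_axis],
        }

    @staticmethod
    def from_dict(d: dict) -> "AnatomicalFrame":
        return AnatomicalFrame(
            np.array(d["origin_mm"]), np.array(d["x_axis_left"]),
            np.array(d["y_axis_superior"]), np.array(d["z_axis_anterior"]),
        )


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COLLINEAR_TOL:
        raise ValueError(f"degenerate landmarks: {what}")
    return v / n


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Construct the anatomic frame from four landmarks.

    x is the unit left-right axis (left minus right reference); y is the
    superior direction with its x component removed (Gram-Schmidt, x
    primary); z completes the right-handed triad.  The origin is the origin
    candidate projected onto the mid-sagittal plane (through the midpoint of
    the left/right references, normal x).
    """
    x = _unit(
        landmarks.left_reference - landmarks.right_reference,
        "left_reference equals right_reference",
    )
    y_raw = landmarks.superior_reference - landmarks.origin_candidate
    y = y_raw - np.dot(y_raw, x) * x
    y = _unit(
        y, "superior_reference collinear with the left-right axis through origin"
    )
    z = np.cross(x, y)
    mid = 0.5 * (landmarks.left_reference + landmarks.right_reference)
    oc = landmarks.origin_candidate
    origin = oc - np.dot(oc - mid, x) * x
    return AnatomicalFrame(origin, x, y, z)


def transform_frame(frame: AnatomicalFrame, t: RigidTransform) -> AnatomicalFrame:
    """Carry a frame through a rigid transform (axes rotate, origin maps)."""
    R = t.rotation
    return AnatomicalFrame(
        t.apply(frame.origin), R @ frame.x_axis, R @ frame.y_axis, R @ frame.z_axis
    )


# ---------------------------------------------------------------------------
# landmark file I/O
# ---------------------------------------------------------------------------

def read_landmarks(path, level: str | None = None) -> LandmarkSet:
    """Read a landmark file (JSON mapping name -> [x, y, z], or CSV with
    columns name,x,y,z)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        points = {k: data[k] for k in data if k in _LANDMARK_NAMES}
        level = level or data.get("level")
    else:
        points = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                points[row["name"]] = [row["x"], row["y"], row["z"]]
    missing = [n for n in _LANDMARK_NAMES if n not in points]
    if missing:
        raise ValueError(f"{path}: missing landmarks {missing}")
    return LandmarkSet(
        *(np.asarray(points[n], dtype=float) for n in _LANDMARK_NAMES),
        level=level,
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    data = {
        n: [float(v) for v in getattr(landmarks, n)] for n in _LANDMARK_NAMES
    }
    if landmarks.level:
        data["level"] = landmarks.level
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z"])
            for n in _LANDMARK_NAMES:
                writer.writerow([n, *data[n]])
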