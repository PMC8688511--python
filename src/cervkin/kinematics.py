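"""Six degree-of-freedom intervertebral kinematics.

Motion at each level is the pose of the upper vertebra's anatomic frame
expressed in the frame of the subjacent (lower) vertebra: three origin
translations (mm) and three joint rotations (degrees) from an Euler
decomposition.  Sign conventions follow the anatomic frame (x left,
y superior, z anterior):

===========  ======================================  ==========
quantity     meaning                                  sign
===========  ======================================  ==========
tx           left-right translation                  right (-) / left (+)
ty           inferior-superior translation           inferior (-) / superior (+)
tz           posterior-anterior translation          posterior (-) / anterior (+)
alpha        flexion-extension (about x)             flexion (-) / extension (+)
gamma        lateral bending (about z)               left (-) / right (+)
beta         axial rotation (about y)                right (-) / left (+)
===========  ======================================  ==========

The default Euler sequence is intrinsic y-x-z (axial rotation, then
flexion-extension, then lateral bending); physiological cervical angles are
far from the gimbal singularity and, below ~5 deg, all sequences agree to
within a few hundredths of a degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .frames import AnatomicalFrame, transform_frame
from .registration import RigidTransform, compose, invert

__all__ = [
    "SixDofResult",
    "relative_pose",
    "decompose_rotation",
    "compose_rotation",
    "intervertebral_6dof",
    "LEVEL_PAIRS",
]

#: Adjacent level pairs, upper vertebra first.
LEVEL_PAIRS = (
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"),
    ("C4", "C5"), ("C5", "C6"), ("C6", "C7"),
)

_VALID_SEQUENCES = {"xyz", "xzy", "yxz", "yzx", "zxy", "zyx"}
_GIMBAL_TOL_DEG = 1e-6


@dataclass(frozen=True)
class SixDofResult:
    """Translations (mm) and rotations (deg) of one level at one posture.

    ``mode`` is ``"absolute_pose"`` (the upper-in-lower pose itself) or
    ``"motion_from_neutral"`` (displacement of that pose from its neutral
    value; zero by construction at the neutral posture).
    """

    level_pair: str
    posture: str
    tx: float
    ty: float
    tz: float
    alpha: float
    gamma: float
    beta: float
    mode: str = "motion_from_neutral"

    def __post_init__(self) -> None:
        vals = (self.tx, self.ty, self.tz, self.alpha, self.gamma, self.beta)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite 6-DOF value")

    def as_row(self) -> dict:
        return {
            "level_pair": self.level_pair, "posture": self.posture,
            "tx": self.tx, "ty": self.ty, "tz": self.tz,
            "alpha": self.alpha, "gamma": self.gamma, "beta": self.beta,
            "mode": self.mode,
        }


def relative_pose(upper: AnatomicalFrame, lower: AnatomicalFrame) -> RigidTransform:
    """Pose of the upper frame expressed in the lower frame's coordinates.

    With R the axis-column matrices and o the origins:
    rotation = Rl.T @ Ru, translation = Rl.T @ (ou - ol).
    """
    Rl, Ru = lower.rotation, upper.rotation
    return RigidTransform(Rl.T @ Ru, Rl.T @ (upper.origin - lower.origin))


def _axis_angles(rotmat: np.ndarray, sequence: str) -> dict[str, float]:
    """Intrinsic Euler angles (deg) keyed by axis letter, gimbal-checked."""
    if sequence not in _VALID_SEQUENCES:
        raise ValueError(f"unsupported Euler sequence {sequence!r}")
    with warnings.catch_warnings():
        # scipy warns at the singularity; we raise a hard error below instead
        warnings.simplefilter("ignore")
        angles = Rotation.from_matrix(rotmat).as_euler(
            sequence.upper(), degrees=True
        )
    middle = angles[1]
    if abs(abs(middle) - 90.0) < _GIMBAL_TOL_DEG:
        raise ValueError(
            f"gimbal lock: middle angle of sequence {sequence} is {middle:.8f} deg"
        )
    return dict(zip(sequence, angles))


def decompose_rotation(
    rotmat: np.ndarray, sequence: str = "yxz"
) -> tuple[float, float, float]:
    """Decompose a joint rotation into (alpha, gamma, beta) degrees.

    alpha is flexion(-)/extension(+) about x, gamma lateral bending
    left(-)/right(+) about z, beta axial rotation right(-)/left(+) about y.
    A right-hand-rule rotation about +x tips the head forward (flexion), so
    alpha negates the raw x angle; the raw z and y angles already carry the
    documented signs.
    """
    rotmat = np.asarray(rotmat, dtype=np.float64)
    if rotmat.shape != (3, 3) or not np.allclose(
        rotmat @ rotmat.T, np.eye(3), atol=1e-6
    ):
        raise ValueError("input is not an orthonormal rotation matrix")
    ang = _axis_angles(rotmat, sequence)
    return (-ang["x"], ang["z"], ang["y"])


def compose_rotation(
    alpha: float, gamma: float, beta: float, sequence: str = "yxz"
) -> np.ndarray:
    """Inverse of :func:`decompose_rotation`: rebuild the rotation matrix."""
    if sequence not in _VALID_SEQUENCES:
        raise ValueError(f"unsupported Euler sequence {sequence!r}")
    per_axis = {"x": -alpha, "z": gamma, "y": beta}
    angles = [per_axis[axis] for axis in sequence]
    return Rotation.from_euler(sequence.upper(), angles, degrees=True).as_matrix()


def _normalize_pair(level_pair) -> tuple[str, str]:
    if isinstance(level_pair, str):
        upper, lower = level_pair.replace("–", "-").split("-")
    else:
        upper, lower = level_pair
    return upper, lower


def intervertebral_6dof(
    neutral_frames: Mapping[str, AnatomicalFrame],
    level_transforms: Mapping[str, Mapping[str, RigidTransform]],
    level_pair,
    posture: str,
    mode: str = "motion_from_neutral",
    sequence: str = "yxz",
) -> SixDofResult:
    """6-DOF of one level pair at one posture.

    ``neutral_frames`` maps level -> anatomic frame on the neutral model;
    ``level_transforms`` maps posture -> level -> rigid transform carrying
    the neutral model of that level to the posture (world coordinates).
    Each neutral frame is carried to the posture through its transform, the
    upper-in-lower relative pose is formed, and, in ``motion_from_neutral``
    mode, referenced to the neutral relative pose:
    ``D = P_neutral^-1 ∘ P_posture``.
    """
    if mode not in ("absolute_pose", "motion_from_neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    upper_lvl, lower_lvl = _normalize_pair(level_pair)
    neutral_is_implicit = posture == "neutral" and posture not in level_transforms
    for lvl in (upper_lvl, lower_lvl):
        if lvl not in neutral_frames:
            raise KeyError(f"no neutral frame for level {lvl}")
        if not neutral_is_implicit and (
            posture not in level_transforms
            or lvl not in level_transforms[posture]
        ):
            raise KeyError(f"no transform for level {lvl} at posture {posture!r}")
    if posture == "neutral" and mode == "motion_from_neutral":
        # the neutral posture is its own reference: identically zero motion
        return SixDofResult(
            level_pair=f"{upper_lvl}-{lower_lvl}", posture=posture,
            tx=0.0, ty=0.0, tz=0.0, alpha=0.0, gamma=0.0, beta=0.0, mode=mode,
        )
    if neutral_is_implicit:
        ident = RigidTransform.identity()
        fu = transform_frame(neutral_frames[upper_lvl], ident)
        fl = transform_frame(neutral_frames[lower_lvl], ident)
    else:
        fu = transform_frame(neutral_frames[upper_lvl],
                             level_transforms[posture][upper_lvl])
        fl = transform_frame(neutral_frames[lower_lvl],
                             level_transforms[posture][lower_lvl])
    pose = relative_pose(fu, fl)
    if mode == "motion_from_neutral":
        p0 = relative_pose(neutral_frames[upper_lvl], neutral_frames[lower_lvl])
        pose = compose(invert(p0), pose)
    alpha, gamma, beta = decompose_rotation(pose.rotation, sequence=sequence)
    tx, ty, tz = pose.translation
    return SixDofResult(
        level_pair=f"{upper_lvl}-{lower_lvl}", posture=posture,
        tx=float(tx), ty=float(ty), tz=float(tz),
        alpha=float(alpha), gamma=float(gamma), beta=float(beta), mode=mode,
    )
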