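"""Rigid 3D-3D registration of vertebra surface models.

One segmental model (the *moving* model, typically the neutral-position
vertebra) is translated and rotated iteratively in space until it aligns
with its *target* model (the same vertebra imaged in another posture or by
another modality).  Registration is iterative closest point (ICP) with
point-to-surface correspondences: each iteration finds, for every moving
vertex, the closest point on the target surface, then solves the
least-squares rigid update in closed form (Kabsch / orthogonal Procrustes).
The objective reported per iteration is the root-mean-square correspondence
distance; with least-squares updates it is non-increasing.

Minimising summed *squared* distances (rather than the plain sum of
distances) is what admits the closed-form update; see docs/methods.md.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import svd

from .mesh_core import (
    VERTEBRA_DIMENSIONS_MM,
    DeviationReport,
    SurfaceIndex,
    TriangleMesh,
    deviation_report,
    signed_distances,
)

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "initial_align",
    "icp_register",
    "apply_transform",
    "compose",
    "invert",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """An SE(3) pose: ``x -> rotation @ x + translation`` (mm).

    ``rotation`` is orthonormal with determinant +1 (checked to 1e-10 at
    construction).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=np.float64)
        return RigidTransform(matrix[:3, :3], matrix[:3, 3])

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation_row_major": [float(v) for v in self.rotation.ravel()],
            "translation_mm": [float(v) for v in self.translation],
            "convention": "x_target = R @ x_moving + t; rotation row-major",
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        R = np.array(d["rotation_row_major"], dtype=float).reshape(3, 3)
        t = np.array(d["translation_mm"], dtype=float)
        return RigidTransform(R, t)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_json(path) -> "RigidTransform":
        with open(path) as fh:
            return RigidTransform.from_dict(json.load(fh))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform mapping ``x -> a(b(x))``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Return the mesh with every vertex mapped through ``t`` (faces kept)."""
    return mesh.with_vertices(t.apply(mesh.vertices))


@dataclass
class RegistrationResult:
    """Outcome of one ICP run.

    ``transform`` maps moving-model coordinates into target-model
    coordinates.  ``objective_trace`` holds the RMS correspondence distance
    at the start of each iteration and is non-increasing.
    """

    transform: RigidTransform
    objective_trace: list[float]
    iterations: int
    converged: bool
    final_report: Optional[DeviationReport] = None

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "objective_trace_mm": [float(v) for v in self.objective_trace],
            "iterations": self.iterations,
            "converged": self.converged,
        }


def _kabsch(source: np.ndarray, dest: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``dest``.

    Closed-form orthogonal-Procrustes solution via SVD; the fresh SVD per
    update keeps the accumulated rotation orthonormal to machine precision.
    """
    cs = source.mean(axis=0)
    cd = dest.mean(axis=0)
    H = (source - cs).T @ (dest - cd)
    U, _, Vt = svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and covariance eigenvectors (columns, ascending eigenvalue)."""
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, V = np.linalg.eigh(cov)
    if np.linalg.det(V) < 0:  # make the basis right-handed
        V = V.copy()
        V[:, 2] = -V[:, 2]
    return c, V


def initial_align(
    moving: TriangleMesh,
    target: TriangleMesh,
    mode: str = "centroid+principal_axes",
    index: Optional[SurfaceIndex] = None,
) -> RigidTransform:
    """Coarse alignment used to seed ICP.

    ``centroid`` translates the moving centroid onto the target centroid;
    ``centroid+principal_axes`` additionally aligns the vertex-covariance
    principal axes, resolving the four-fold axis-sign ambiguity by scoring
    each proper-rotation candidate with the RMS surface distance on a
    deterministic vertex subsample and keeping the best.  ``identity``
    returns the identity transform.
    """
    if mode == "identity":
        return RigidTransform.identity()
    cm = moving.centroid
    ct = target.centroid
    if mode == "centroid":
        return RigidTransform(np.eye(3), ct - cm)
    if mode != "centroid+principal_axes":
        raise ValueError(f"unknown initialization mode {mode!r}")

    _, Vm = _principal_axes(moving.vertices)
    _, Vt = _principal_axes(target.vertices)
    wm = np.sort(np.linalg.eigvalsh(np.cov((moving.vertices - cm).T)))
    # rank-deficient (e.g. coplanar vertices) or repeated-eigenvalue inertia
    # leaves the principal directions ill-defined
    if wm[0] < 1e-12 * max(wm[-1], 1.0) or np.min(np.diff(wm)) < 1e-6 * wm[-1]:
        warnings.warn(
            "degenerate inertia tensor; falling back to centroid alignment",
            RuntimeWarning,
        )
        return RigidTransform(np.eye(3), ct - cm)

    if index is None:
        index = SurfaceIndex(target)
    step = max(1, len(moving.vertices) // 400)
    probe = moving.vertices[::step]
    best: Optional[RigidTransform] = None
    best_obj = np.inf
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            S = np.diag([sx, sy, sx * sy])  # keeps det(R) = +1
            R = Vt @ S @ Vm.T
            cand = RigidTransform(R, ct - R @ cm)
            _, dist, _ = index.query(cand.apply(probe))
            obj = float(np.sqrt(np.mean(dist ** 2)))
            if obj < best_obj:
                best_obj, best = obj, cand
    assert best is not None
    return best


def icp_register(
    moving: TriangleMesh,
    target: TriangleMesh,
    init: Optional[RigidTransform] = None,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
    min_objective: float = 1e-9,
    trim_percentile: Optional[float] = None,
    index: Optional[SurfaceIndex] = None,
    compute_report: bool = True,
) -> RegistrationResult:
    """Register ``moving`` onto ``target`` by point-to-surface ICP.

    Iterates closest-point correspondence against the target surface and the
    closed-form least-squares rigid update, stopping when the relative
    decrease of the RMS correspondence distance falls below ``tolerance``,
    the objective falls below the ``min_objective`` floor (1e-9 mm, i.e.
    exact alignment up to round-off), or ``max_iterations`` is reached (then
    ``converged`` is False, not an exception).  ``trim_percentile``, if given (e.g. 90), drops the farthest
    correspondences above that percentile from each update for robustness;
    it is off by default.  The algorithm is fully deterministic.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not np.isfinite(moving.vertices).all() or not np.isfinite(target.vertices).all():
        raise ValueError("non-finite vertex coordinates")
    if index is None:
        index = SurfaceIndex(target)
    T = init if init is not None else initial_align(moving, target, index=index)

    src = moving.vertices
    trace: list[float] = []
    converged = False
    prev: Optional[float] = None
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        pts = T.apply(src)
        cp, dist, _ = index.query(pts)
        obj = float(np.sqrt(np.mean(dist ** 2)))
        trace.append(obj)
        if obj <= min_objective or (
            prev is not None and prev - obj <= tolerance * max(prev, 1e-12)
        ):
            converged = True
            break
        prev = obj
        if trim_percentile is not None:
            keep = dist <= np.percentile(dist, trim_percentile)
            T = _kabsch(src[keep], cp[keep])
        else:
            T = _kabsch(src, cp)

    report = None
    if compute_report:
        fld = signed_distances(apply_transform(moving, T), target, index=index)
        if moving.label in VERTEBRA_DIMENSIONS_MM:
            report = deviation_report(fld, level=moving.label)
        else:
            span = float(np.max(target.extents()))
            report = deviation_report(fld, characteristic_dimension=span)
    return RegistrationResult(
        transform=T,
        objective_trace=trace,
        iterations=iterations,
        converged=converged,
        final_report=report,
    )
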