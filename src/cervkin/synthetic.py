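"""Synthetic vertebra meshes and ground-truth motion scenarios.

The generator produces *stylized* vertebra-like surfaces — an elliptical
vertebral body, posterior arch, two transverse processes and a spinous
process — sized to a built-in table of typical per-level cervical dimensions.
They are deliberately not anatomically faithful: what the rest of the
package needs from a fixture is realistic size, enough surface complexity to
make rigid registration well-posed, and broken symmetry so the registration
optimum is unique.  Every mesh is closed, connected and deterministic.

:func:`perturb_mesh` emulates the difference between two independent
segmentations of the same bone (e.g. CT- versus CBCT-derived models): the
surface is remeshed so that no output vertex coincides with an input vertex
(no trivial point correspondence survives), then vertices are displaced
along local normals by zero-mean Gaussian noise, mimicking segmentation
boundary error.

:func:`make_scenario` builds per-level ground-truth rigid transforms for the
six end postures from per-joint 6-DOF motions, so the full measurement chain
(registration -> frames -> kinematics) can be checked against injected
truth.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

from .frames import AnatomicalFrame, LandmarkSet
from .kinematics import LEVEL_PAIRS, compose_rotation
from .mesh_core import (
    POSTURES,
    VERTEBRA_DIMENSIONS_MM,
    SurfaceIndex,
    TriangleMesh,
)
from .registration import RigidTransform

__all__ = [
    "VertebraSpec",
    "MotionScenario",
    "generate_vertebra",
    "vertebra_landmarks",
    "perturb_mesh",
    "remesh",
    "add_surface_noise",
    "default_stack_frames",
    "make_scenario",
]

_DOF_NAMES = ("tx", "ty", "tz", "alpha", "gamma", "beta")


@dataclass(frozen=True)
class VertebraSpec:
    """Size and perturbation parameters for one synthetic vertebra.

    ``height``/``width``/``length`` are the target bounding-box extents in
    mm (superior-inferior, left-right, anterior-posterior); defaults for a
    named level come from the built-in dimension table via
    :meth:`for_level`.  ``pitch`` is the marching-cubes voxel size in mm and
    sets mesh resolution.
    """

    level: str
    height: float
    width: float
    length: float
    noise_sigma: float = 0.0
    remesh_factor: float = 1.0
    seed: int = 0
    pitch: float = 0.9

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.length) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 < self.remesh_factor <= 4:
            raise ValueError("remesh_factor must be in (0, 4]")

    @classmethod
    def for_level(cls, level: str, **overrides) -> "VertebraSpec":
        """Spec with the tabulated typical dimensions of a cervical level."""
        if level not in VERTEBRA_DIMENSIONS_MM:
            raise ValueError(f"unknown vertebra level {level!r}")
        h, w, l = VERTEBRA_DIMENSIONS_MM[level]
        params = dict(level=level, height=h, width=w, length=l)
        params.update(overrides)
        return cls(**params)


# ---------------------------------------------------------------------------
# implicit-surface vertebra template
# ---------------------------------------------------------------------------

def _primitives(h: float, w: float, l: float):
    """Capsule segments (a, b, radius) plus body-cylinder parameters.

    Anatomic orientation: +x left, +y superior, +z anterior.  The vertebral
    body sits anteriorly, the arch and spinous process posteriorly; the two
    transverse processes reach the full lateral width.  Deliberate
    asymmetries (radii, tip heights, spinous tip offset) remove rotational
    and mirror near-symmetries.
    """
    zb = 0.30 * l                      # body centre, anterior
    rp = 0.20 * h                      # pedicle radius
    rl = 0.17 * h                      # lamina radius
    rt = 0.17 * h                      # transverse-process radius
    rs = 0.20 * h                      # spinous radius
    caps = [
        # pedicles: body to arch roots
        ((+0.16 * w, -0.08 * h, zb - 0.10 * l), (+0.21 * w, 0.00, -0.04 * l), rp),
        ((-0.16 * w, -0.08 * h, zb - 0.10 * l), (-0.21 * w, 0.00, -0.04 * l), rp),
        # laminae: arch roots to posterior midline
        ((+0.21 * w, 0.00, -0.04 * l), (0.0, 0.06 * h, -0.30 * l), rl),
        ((-0.21 * w, 0.00, -0.04 * l), (0.0, 0.06 * h, -0.30 * l), rl),
        # transverse processes (left thicker, tips at different heights)
        ((+0.18 * w, 0.00, zb - 0.12 * l), (+0.50 * w, -0.05 * h, 0.02 * l),
         1.15 * rt),
        ((-0.18 * w, 0.00, zb - 0.12 * l), (-0.50 * w, +0.07 * h, 0.06 * l), rt),
        # spinous process, sloping inferiorly, tip nudged off midline
        ((0.0, 0.05 * h, -0.26 * l), (0.035 * w, -0.14 * h, -0.50 * l), rs),
    ]
    body = dict(center=(0.0, -0.06 * h, zb), semi_x=0.22 * w, semi_z=0.18 * l,
                y_half=0.42 * h)
    return caps, body


def _implicit_field(points: np.ndarray, h: float, w: float, l: float) -> np.ndarray:
    caps, body = _primitives(h, w, l)
    d = np.full(len(points), np.inf)
    for a, b, r in caps:
        a = np.asarray(a)
        ba = np.asarray(b) - a
        pa = points - a
        t = np.clip(pa @ ba / (ba @ ba), 0.0, 1.0)
        d = np.minimum(d, np.linalg.norm(pa - t[:, None] * ba, axis=1) - r)
    cx, cy, cz = body["center"]
    q = np.sqrt(
        ((points[:, 0] - cx) / body["semi_x"]) ** 2
        + ((points[:, 2] - cz) / body["semi_z"]) ** 2
    )
    d_ell = (q - 1.0) * min(body["semi_x"], body["semi_z"])
    d_body = np.maximum(d_ell, np.abs(points[:, 1] - cy) - body["y_half"])
    d = np.minimum(d, d_body)
    # gentle deterministic surface texture: breaks residual symmetry and
    # gives the registration cost function sharp, well-separated optima
    tex = 0.30 * (
        np.sin(0.55 * points[:, 0] + 1.0)
        * np.sin(0.75 * points[:, 1] + 0.5)
        * np.sin(0.40 * points[:, 2] + 2.0)
    )
    return d + tex


def _raw_landmarks(h: float, w: float, l: float) -> dict[str, np.ndarray]:
    caps, body = _primitives(h, w, l)
    cx, cy, cz = body["center"]
    return {
        # most posterior-inferior point of the body, mid-sagittal
        "origin_candidate": np.array([0.0, cy - body["y_half"],
                                      cz - body["semi_z"]]),
        # posterior-superior body point: directly above the origin, so the
        # superior direction is not biased anteriorly
        "superior_reference": np.array([0.0, cy + body["y_half"],
                                        cz - body["semi_z"]]),
        "left_reference": np.array(caps[4][1]),   # left TP tip
        "right_reference": np.array(caps[5][1]),  # right TP tip
    }


@lru_cache(maxsize=32)
def _generate_clean(level: str, h: float, w: float, l: float, pitch: float):
    margin = 3.0 * pitch
    caps, body = _primitives(h, w, l)
    pts = [np.asarray(p) for a, b, _ in caps for p in (a, b)]
    rad = max(c[2] for c in caps)
    lo = np.min(pts, axis=0) - rad - margin
    hi = np.max(pts, axis=0) + rad + margin
    lo = np.minimum(lo, [-0.25 * w, -0.55 * h, -0.05 * l])
    hi = np.maximum(hi, [0.25 * w, 0.45 * h, 0.52 * l])
    axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    flat = np.column_stack([g.ravel() for g in grid])
    fld = _implicit_field(flat, h, w, l).reshape([len(a) for a in axes])
    verts, faces, _, _ = measure.marching_cubes(fld, level=0.0,
                                                spacing=(pitch, pitch, pitch))
    verts = verts + lo
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.update_faces(tm.nondegenerate_faces(height=1e-9))
    tm.remove_unreferenced_vertices()
    if tm.body_count > 1:  # keep the main body if stray voxels split off
        tm = max(tm.split(only_watertight=False), key=lambda m: len(m.faces))
    tm.fix_normals()
    # rescale anisotropically so the bounding box matches the spec exactly,
    # and centre the box on the origin
    ext = tm.bounds[1] - tm.bounds[0]
    scale = np.array([w, h, l]) / ext
    center = tm.bounds.mean(axis=0)
    v = (np.asarray(tm.vertices) - center) * scale
    lm = {k: (p - center) * scale for k, p in _raw_landmarks(h, w, l).items()}
    return v, np.asarray(tm.faces), lm


def generate_vertebra(spec: VertebraSpec) -> TriangleMesh:
    """Generate one synthetic vertebra mesh (closed, connected, mm).

    The axis-aligned bounding box matches (width, height, length) on
    (x, y, z) exactly after rescaling.  If the spec carries ``noise_sigma``
    or a non-unit ``remesh_factor`` the perturbation of
    :func:`perturb_mesh` is applied with the spec's seed.
    """
    v, f, _ = _generate_clean(spec.level, spec.height, spec.width,
                              spec.length, spec.pitch)
    mesh = TriangleMesh(v.copy(), f.copy(), label=spec.level, posture="neutral")
    if spec.noise_sigma > 0 or spec.remesh_factor != 1.0:
        mesh = perturb_mesh(mesh, spec.noise_sigma, spec.remesh_factor,
                            spec.seed)
    return mesh


def vertebra_landmarks(spec: VertebraSpec) -> LandmarkSet:
    """Analytic anatomic landmarks of the generated vertebra.

    The generator knows its own primitive anchors (body corner, body top,
    transverse-process tips), so the landmark coordinates are exact rather
    than estimated from the discretized surface.
    """
    _, _, lm = _generate_clean(spec.level, spec.height, spec.width,
                               spec.length, spec.pitch)
    return LandmarkSet(
        lm["origin_candidate"].copy(), lm["superior_reference"].copy(),
        lm["left_reference"].copy(), lm["right_reference"].copy(),
        level=spec.level,
    )


# ---------------------------------------------------------------------------
# perturbation: remesh + surface noise
# ---------------------------------------------------------------------------

def _decimate(vertices: np.ndarray, faces: np.ndarray, target_faces: int):
    """Shortest-edge midpoint collapse on a closed manifold mesh."""
    V = [v for v in vertices]
    F = {i: list(f) for i, f in enumerate(faces)}
    vert_faces: dict[int, set[int]] = {}
    for fi, f in F.items():
        for vi in f:
            vert_faces.setdefault(vi, set()).add(fi)
    alive = set(range(len(V)))

    def neighbors(v):
        out = set()
        for fi in vert_faces.get(v, ()):
            out.update(F[fi])
        out.discard(v)
        return out

    heap = []
    for fi, f in F.items():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if a < b:
                heapq.heappush(
                    heap, (float(np.linalg.norm(V[a] - V[b])), a, b)
                )
    n_faces = len(F)
    while n_faces > target_faces and heap:
        _, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        shared = vert_faces[a] & vert_faces[b]
        if len(shared) != 2:
            continue
        opposite = {v for fi in shared for v in F[fi]} - {a, b}
        if neighbors(a) & neighbors(b) != opposite:
            continue  # link condition: collapse would pinch the surface
        m = 0.5 * (V[a] + V[b])
        touched = (vert_faces[a] | vert_faces[b]) - shared
        ok = True
        for fi in touched:
            f = [m if v in (a, b) else V[v] for v in F[fi]]
            n_new = np.cross(f[1] - f[0], f[2] - f[0])
            g = [V[v] for v in F[fi]]
            n_old = np.cross(g[1] - g[0], g[2] - g[0])
            if np.linalg.norm(n_new) < 1e-12 or np.dot(n_new, n_old) <= 0:
                ok = False
                break
        if not ok:
            continue
        mi = len(V)
        V.append(m)
        alive.add(mi)
        alive.discard(a)
        alive.discard(b)
        vert_faces[mi] = set()
        for fi in shared:
            for v in F[fi]:
                vert_faces[v].discard(fi)
            del F[fi]
            n_faces -= 1
        for fi in touched:
            F[fi] = [mi if v in (a, b) else v for v in F[fi]]
            vert_faces[mi].add(fi)
        for nb in neighbors(mi):
            lo, hi2 = (mi, nb) if mi < nb else (nb, mi)
            heapq.heappush(heap, (float(np.linalg.norm(V[lo] - V[hi2])), lo, hi2))
    remap = {old: new for new, old in enumerate(sorted(alive))}
    out_v = np.array([V[old] for old in sorted(alive)])
    out_f = np.array([[remap[v] for v in f] for f in F.values()], dtype=np.int64)
    return out_v, out_f


def remesh(mesh: TriangleMesh, factor: float = 1.0, seed: int = 0) -> TriangleMesh:
    """Re-tessellate a surface so no output vertex coincides with an input
    vertex, keeping the geometry on the input surface exactly.

    Vertices are redistributed by one seeded, asymmetrically weighted
    Laplacian step and re-projected onto the input surface (so the remeshed
    vertices lie *on* the original triangulated surface, not near it).  For
    ``factor > 1`` the mesh is midpoint-subdivided first; other target
    face-count ratios are reached by shortest-edge collapse decimation.
    """
    if not 0 < factor <= 4:
        raise ValueError("remesh factor must be in (0, 4]")
    n0 = len(mesh.faces)
    target = max(4, int(round(factor * n0)))
    work_v, work_f = mesh.vertices, mesh.faces
    if factor > 1.0:
        tm = trimesh.Trimesh(work_v, work_f, process=False).subdivide()
        work_v, work_f = np.asarray(tm.vertices), np.asarray(tm.faces)
    if len(work_f) > target and abs(len(work_f) - target) > 0.05 * target:
        work_v, work_f = _decimate(work_v, work_f, target)

    index = SurfaceIndex(mesh)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5e]))
    n = len(work_v)
    rows = np.concatenate([work_f[:, [0, 1, 2]].ravel(), work_f[:, [1, 2, 0]].ravel()])
    cols = np.concatenate([work_f[:, [1, 2, 0]].ravel(), work_f[:, [0, 1, 2]].ravel()])
    from scipy.sparse import coo_matrix
    weights = 1.0 + 0.6 * rng.random(len(rows))
    A = coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()
    wsum = np.asarray(A.sum(axis=1)).ravel()
    avg = A @ work_v / wsum[:, None]
    moved = work_v + 0.5 * (avg - work_v)
    proj, _, _ = index.query(moved)

    # no output vertex may coincide with an input vertex
    tree = cKDTree(mesh.vertices)
    for _ in range(8):
        d, _ = tree.query(proj)
        stuck = d < 1e-9
        if not stuck.any():
            break
        jitter = moved[stuck] + 0.25 * (
            avg[stuck] - work_v[stuck]
        ) * rng.random((int(stuck.sum()), 1))
        proj_stuck, _, _ = index.query(jitter)
        proj[stuck] = proj_stuck
    out = TriangleMesh(proj, work_f, label=mesh.label, posture=mesh.posture)
    return out


def add_surface_noise(
    mesh: TriangleMesh, sigma: float, seed: int = 0
) -> TriangleMesh:
    """Displace vertices along vertex normals by N(0, sigma^2) mm."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return mesh
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0a]))
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    normals = np.asarray(tm.vertex_normals)
    offsets = rng.normal(0.0, sigma, size=len(mesh.vertices))
    return mesh.with_vertices(mesh.vertices + offsets[:, None] * normals)


def perturb_mesh(
    mesh: TriangleMesh,
    noise_sigma: float,
    remesh_factor: float = 1.0,
    seed: int = 0,
) -> TriangleMesh:
    """Emulate an independent re-segmentation of the same bone surface.

    Remeshes (breaking all vertex correspondence with the input) and then
    adds zero-mean Gaussian displacement along local normals.  Deterministic
    per seed.
    """
    out = remesh(mesh, factor=remesh_factor, seed=seed)
    return add_surface_noise(out, noise_sigma, seed=seed)


# ---------------------------------------------------------------------------
# motion scenarios
# ---------------------------------------------------------------------------

_LEVELS = tuple(VERTEBRA_DIMENSIONS_MM)
_DISC_GAP_MM = 4.0

#: Template joint motions per preset: posture -> level pair -> partial DOF
#: dict (degrees / mm).  Signs follow the kinematics conventions; the
#: patterns are qualitative templates of in vivo findings: axial rotation
#: concentrated at C1-C2 (~30 deg) with opposite-direction coupled lateral
#: bending there and same-direction coupled bending subaxially; bending
#: distributed roughly evenly; flexion-extension spread across levels.
_PRESETS: dict[str, dict[str, dict[str, dict[str, float]]]] = {
    "fe": {
        "flexion": {
            "C1-C2": {"alpha": -4.0, "tz": 0.4},
            "C2-C3": {"alpha": -5.0, "tz": 0.5},
            "C3-C4": {"alpha": -7.0, "tz": 0.6},
            "C4-C5": {"alpha": -8.0, "tz": 0.6},
            "C5-C6": {"alpha": -7.0, "tz": 0.5},
            "C6-C7": {"alpha": -5.0, "tz": 0.3},
        },
        "extension": {
            "C1-C2": {"alpha": 7.9, "tz": -0.3},
            "C2-C3": {"alpha": 5.0, "tz": -0.4},
            "C3-C4": {"alpha": 6.0, "tz": -0.5},
            "C4-C5": {"alpha": 7.0, "tz": -0.5},
            "C5-C6": {"alpha": 6.0, "tz": -0.4},
            "C6-C7": {"alpha": 4.0, "tz": -0.2},
        },
    },
    "lb": {
        "left_bend": {
            "C1-C2": {"gamma": -8.0, "beta": -3.0},
            "C2-C3": {"gamma": -4.0, "beta": -0.5},
            "C3-C4": {"gamma": -4.0, "beta": -0.5},
            "C4-C5": {"gamma": -4.0, "beta": -0.5},
            "C5-C6": {"gamma": -4.0, "beta": -0.5},
            "C6-C7": {"gamma": -3.0, "beta": -0.5},
        },
        "right_bend": {
            "C1-C2": {"gamma": 8.0, "beta": 3.0},
            "C2-C3": {"gamma": 4.0, "beta": 0.5},
            "C3-C4": {"gamma": 4.0, "beta": 0.5},
            "C4-C5": {"gamma": 4.0, "beta": 0.5},
            "C5-C6": {"gamma": 4.0, "beta": 0.5},
            "C6-C7": {"gamma": 3.0, "beta": 0.5},
        },
    },
    "ar": {
        "left_rotation": {
            # ~30 deg of head axial rotation carried by C1-C2, bending
            # coupled opposite (rightward) there, same-direction subaxially
            "C1-C2": {"beta": 30.0, "gamma": 2.0, "alpha": 1.0},
            "C2-C3": {"beta": 1.5, "gamma": -1.0},
            "C3-C4": {"beta": 1.5, "gamma": -1.0},
            "C4-C5": {"beta": 1.5, "gamma": -1.0},
            "C5-C6": {"beta": 1.5, "gamma": -1.0},
            "C6-C7": {"beta": 1.0, "gamma": -0.5},
        },
        "right_rotation": {
            "C1-C2": {"beta": -30.0, "gamma": -2.0, "alpha": 1.0},
            "C2-C3": {"beta": -1.5, "gamma": 1.0},
            "C3-C4": {"beta": -1.5, "gamma": 1.0},
            "C4-C5": {"beta": -1.5, "gamma": 1.0},
            "C5-C6": {"beta": -1.5, "gamma": 1.0},
            "C6-C7": {"beta": -1.0, "gamma": 0.5},
        },
    },
}


@dataclass
class MotionScenario:
    """Ground truth for one simulated multi-posture study.

    ``transforms[posture][level]`` carries the neutral model of ``level`` to
    ``posture`` in world coordinates (identity for the neutral posture);
    ``joints[posture][pair]`` holds the injected per-joint 6-DOF values;
    ``frames[level]`` are the neutral anatomic frames the scenario was built
    on.
    """

    description: str
    transforms: dict[str, dict[str, RigidTransform]]
    joints: dict[str, dict[str, dict[str, float]]]
    frames: dict[str, AnatomicalFrame]

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.frames)

    @property
    def postures(self) -> tuple[str, ...]:
        return tuple(self.transforms)


def default_stack_frames(
    levels: Sequence[str] = _LEVELS, disc_gap: float = _DISC_GAP_MM
) -> dict[str, AnatomicalFrame]:
    """Neutral anatomic frames of a vertically stacked cervical column.

    Levels are stacked along +y (superior) at their tabulated heights plus a
    disc gap, C7 at the bottom, axes identity.
    """
    levels = list(levels)
    frames = {}
    y = 0.0
    for lvl in reversed(levels):  # bottom-up; origin at the inferior point
        frames[lvl] = AnatomicalFrame(
            np.array([0.0, y, 0.0]),
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([0.0, 0.0, 1.0]),
        )
        y += VERTEBRA_DIMENSIONS_MM[lvl][0] + disc_gap
    return {lvl: frames[lvl] for lvl in levels}


def _joint_transform(dof: Mapping[str, float]) -> RigidTransform:
    R = compose_rotation(
        dof.get("alpha", 0.0), dof.get("gamma", 0.0), dof.get("beta", 0.0)
    )
    t = np.array([dof.get("tx", 0.0), dof.get("ty", 0.0), dof.get("tz", 0.0)])
    return RigidTransform(R, t)


def make_scenario(
    name: str = "ar",
    magnitudes: Optional[Mapping[str, Mapping[str, Mapping[str, float]]]] = None,
    seed: int = 0,
    frames: Optional[dict[str, AnatomicalFrame]] = None,
) -> MotionScenario:
    """Build ground-truth per-level posture transforms from joint motions.

    ``name`` selects a preset ("fe", "lb", "ar") or "custom" (then
    ``magnitudes`` is required).  ``magnitudes`` maps
    posture -> level pair -> DOF overrides and is merged over the preset.
    All postures absent from the template get identity transforms; the
    neutral posture is always identity.  Angles beyond +-60 deg or
    translations beyond +-20 mm are rejected.
    """
    if name not in (*_PRESETS, "custom"):
        raise ValueError(f"unknown scenario preset {name!r}")
    if name == "custom" and magnitudes is None:
        raise ValueError("custom scenarios require explicit magnitudes")
    template: dict[str, dict[str, dict[str, float]]] = {
        p: {pair: dict(dofs) for pair, dofs in table.items()}
        for p, table in _PRESETS.get(name, {}).items()
    }
    for posture, table in (magnitudes or {}).items():
        if posture not in POSTURES or posture == "neutral":
            raise ValueError(f"invalid posture {posture!r} in magnitudes")
        dst = template.setdefault(posture, {})
        for pair, dofs in table.items():
            dst.setdefault(pair, {}).update(dofs)

    frames = frames if frames is not None else default_stack_frames()
    levels = list(frames)
    pair_names = [f"{u}-{lo}" for u, lo in LEVEL_PAIRS
                  if u in levels and lo in levels]
    joints: dict[str, dict[str, dict[str, float]]] = {}
    transforms: dict[str, dict[str, RigidTransform]] = {
        "neutral": {lvl: RigidTransform.identity() for lvl in levels}
    }
    for posture in POSTURES:
        if posture == "neutral":
            continue
        all_pairs = {f"{u}-{lo}" for u, lo in LEVEL_PAIRS}
        for pair, dofs in template.get(posture, {}).items():
            if pair not in all_pairs:
                raise ValueError(f"unknown level pair {pair!r}")
            for k, v in dofs.items():
                if k not in _DOF_NAMES:
                    raise ValueError(f"unknown DOF {k!r}")
                limit = 20.0 if k.startswith("t") else 60.0
                if abs(v) > limit:
                    raise ValueError(
                        f"{posture} {pair} {k}={v} exceeds +-{limit}"
                    )
        # pairs outside the requested level span are dropped
        table = {p: d for p, d in template.get(posture, {}).items()
                 if p in pair_names}
        joints[posture] = {
            pair: {k: float(table.get(pair, {}).get(k, 0.0))
                   for k in _DOF_NAMES}
            for pair in pair_names
        }
        # chain poses bottom-up: the lowest level stays put, each upper
        # vertebra's frame is its neutral pose in the lower frame composed
        # with the injected joint displacement
        world: dict[str, RigidTransform] = {}
        base = levels[-1]
        world[base] = frames[base].as_transform()
        for upper, lower in reversed(LEVEL_PAIRS):
            if upper not in levels or lower not in levels:
                continue
            p0 = frames[lower].as_transform().inverse().compose(
                frames[upper].as_transform()
            )
            j = _joint_transform(joints[posture][f"{upper}-{lower}"])
            world[upper] = world[lower].compose(p0).compose(j)
        transforms[posture] = {
            lvl: world[lvl].compose(frames[lvl].as_transform().inverse())
            for lvl in levels
        }
    return MotionScenario(
        description=f"{name} scenario", transforms=transforms,
        joints=joints, frames=dict(frames),
    )
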