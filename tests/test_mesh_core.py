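"""Mesh I/O, signed point-to-surface distances and deviation statistics."""

import numpy as np
import pytest
import trimesh

from cervkin import (
    DeviationReport,
    MeshIOError,
    MeshValidationError,
    RigidTransform,
    SignedDistanceField,
    SurfaceIndex,
    TriangleMesh,
    apply_transform,
    deviation_report,
    estimate_angular_deviation,
    read_mesh,
    signed_distances,
    write_mesh,
)

TET_VERTS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


def square_patch():
    """Unit square in the z=0 plane, winding normal +z."""
    return TriangleMesh(
        np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
        np.array([[0, 1, 2], [0, 2, 3]]),
    )


def point_mesh(*points):
    """Single-triangle carrier so arbitrary query points form a mesh."""
    pts = np.asarray(points, float)
    assert len(pts) == 3
    return TriangleMesh(pts, np.array([[0, 1, 2]]))


# ---------------------------------------------------------------------------
# construction and I/O
# ---------------------------------------------------------------------------

class TestMeshModel:
    def test_invalid_meshes_rejected(self):
        with pytest.raises(MeshValidationError, match="empty"):
            TriangleMesh(np.empty((0, 3)), np.empty((0, 3), int))
        with pytest.raises(MeshValidationError, match="missing vertices"):
            TriangleMesh(TET_VERTS, np.array([[0, 1, 9]]))
        with pytest.raises(MeshValidationError, match="degenerate"):
            TriangleMesh(TET_VERTS, np.array([[0, 1, 1]]))
        with pytest.raises(MeshValidationError, match="connected"):
            TriangleMesh(
                np.vstack([TET_VERTS, TET_VERTS + 10.0]),
                np.vstack([TET_FACES, TET_FACES + 4]),
            )
        with pytest.raises(MeshValidationError, match="posture"):
            TriangleMesh(TET_VERTS, TET_FACES, posture="sideways")

    @pytest.mark.parametrize("fmt", ["stl", "ply"])
    def test_roundtrip(self, tmp_path, fmt):
        mesh = TriangleMesh(TET_VERTS, TET_FACES)
        path = tmp_path / f"tet.{fmt}"
        write_mesh(mesh, path)
        back = read_mesh(path, label="C3", posture="neutral")
        assert len(back.vertices) == 4
        assert back.label == "C3"
        # vertex sets equal within float round-trip (order may differ)
        a = mesh.vertices[np.lexsort(mesh.vertices.T)]
        b = back.vertices[np.lexsort(back.vertices.T)]
        assert np.allclose(a, b, atol=1e-6)

    def test_read_errors(self, tmp_path):
        with pytest.raises(MeshIOError):
            read_mesh(tmp_path / "nope.stl")
        trunc = tmp_path / "trunc.stl"
        write_mesh(TriangleMesh(TET_VERTS, TET_FACES), trunc)
        data = trunc.read_bytes()
        trunc.write_bytes(data[: len(data) // 2])
        with pytest.raises((MeshIOError, MeshValidationError)):
            read_mesh(trunc)
        open_path = tmp_path / "open.stl"
        sq = square_patch()
        sq.to_trimesh().export(open_path)
        with pytest.raises(MeshValidationError, match="watertight"):
            read_mesh(open_path)
        assert read_mesh(open_path, require_closed=False).faces.shape == (2, 3)


# ---------------------------------------------------------------------------
# signed distances
# ---------------------------------------------------------------------------

class TestSignedDistances:
    def test_plane_patch_cases(self):
        target = square_patch()
        moving = point_mesh([0.5, 0.5, 0.7], [2.0, 0.5, 0.0], [0.5, 0.5, 0.0])
        d = signed_distances(moving, target).distances
        assert d[0] == pytest.approx(0.7, abs=1e-12)   # above the plane
        assert d[1] == pytest.approx(1.0, abs=1e-12)   # beyond the edge
        assert d[2] == pytest.approx(0.0, abs=1e-12)   # on the surface
        below = point_mesh([0.5, 0.5, -0.3], [0.25, 0.25, -0.1], [0.7, 0.2, -0.2])
        assert (signed_distances(below, target).distances < 0).all()

    def test_indexed_equals_bruteforce_exactly(self, c5_mesh, c5_index, rng):
        pts = rng.normal(scale=25.0, size=(500, 3))
        ci, di, fi = c5_index.query(pts)
        cb, db, fb = c5_index.query(pts, method="bruteforce")
        assert np.array_equal(di, db)
        assert np.array_equal(fi, fb)
        assert np.array_equal(ci, cb)

    def test_rigid_invariance_of_magnitude(self, c5_mesh, c5_remeshed):
        base = signed_distances(c5_remeshed, c5_mesh).distances
        R = trimesh.transformations.rotation_matrix(0.9, [1, 2, 3])[:3, :3]
        t = RigidTransform(R, np.array([12.0, -7.0, 4.0]))
        moved = signed_distances(
            apply_transform(c5_remeshed, t), apply_transform(c5_mesh, t)
        ).distances
        assert np.allclose(np.abs(moved), np.abs(base), rtol=1e-9, atol=1e-9)

    def test_self_distance_zero(self, c5_mesh, c5_index):
        field = signed_distances(c5_mesh, c5_mesh, index=c5_index)
        report = deviation_report(field, level="C5")
        assert report.average_distance == 0.0
        assert report.mean_deviation == 0.0
        assert report.max_positive == 0.0 and report.max_negative == 0.0


# ---------------------------------------------------------------------------
# deviation statistics
# ---------------------------------------------------------------------------

def make_field(distances):
    d = np.asarray(distances, float)
    return SignedDistanceField(d, np.zeros((len(d), 3)), np.zeros(len(d), int))


class TestDeviationReport:
    def test_hand_computed_symmetric_pair(self):
        rep = deviation_report(make_field([0.3, -0.3]), 10.0)
        assert rep.average_distance == pytest.approx(0.0, abs=1e-15)
        assert rep.mean_absolute_deviation == pytest.approx(0.3)
        assert rep.mean_deviation == pytest.approx(0.3)
        assert rep.max_positive == pytest.approx(0.3)
        assert rep.max_negative == pytest.approx(-0.3)
        assert rep.std_positive == 0.0 and rep.std_negative == 0.0

    def test_uniform_plane_offset(self):
        lower = square_patch()
        upper = TriangleMesh(lower.vertices + [0, 0, 0.5], lower.faces)
        rep = deviation_report(signed_distances(upper, lower), 10.0)
        assert rep.average_distance == pytest.approx(0.5, abs=1e-12)
        assert rep.mean_absolute_deviation == pytest.approx(0.5, abs=1e-12)
        assert rep.std_positive == pytest.approx(0.0, abs=1e-12)

    def test_concentric_spheres_offset(self):
        inner = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        outer = trimesh.creation.icosphere(subdivisions=3, radius=10.5)
        rep = deviation_report(
            signed_distances(
                TriangleMesh(outer.vertices, outer.faces),
                TriangleMesh(inner.vertices, inner.faces),
            ),
            10.0,
        )
        assert rep.average_distance == pytest.approx(0.5, abs=0.02)
        assert rep.max_negative >= -1e-9  # outer sphere lies fully outside

    def test_report_invariants_on_random_fields(self, rng):
        for _ in range(20):
            d = rng.normal(scale=rng.uniform(0.01, 2.0), size=50)
            rep = deviation_report(make_field(d), 11.9)
            assert rep.max_negative <= rep.average_distance <= rep.max_positive
            max_mag = max(abs(rep.max_positive), abs(rep.max_negative))
            assert rep.mean_absolute_deviation <= rep.mean_deviation + 1e-12
            assert rep.mean_deviation <= max_mag + 1e-12
            assert np.isfinite(list(rep.to_row().values())[1:]).all()

    def test_all_zero_field_is_valid(self):
        rep = deviation_report(make_field([0.0, 0.0, 0.0]), 11.9)
        assert rep.mean_deviation == 0.0 and rep.angular_prediction_pos == 0.0

    def test_default_dimension_from_level(self):
        rep = deviation_report(make_field([0.1]), level="C5")
        assert rep.characteristic_dimension == 11.9
        with pytest.raises(ValueError):
            deviation_report(make_field([0.1]))


class TestAngularDeviation:
    def test_worked_examples(self):
        assert estimate_angular_deviation(0.06, 11.9) == pytest.approx(
            0.289, abs=5e-4
        )
        assert estimate_angular_deviation(0.02, 11.9) == pytest.approx(
            0.096, abs=5e-4
        )
        assert estimate_angular_deviation(0.0, 7.7) == 0.0

    def test_linearity(self, rng):
        e = rng.uniform(0.01, 1.0)
        d = rng.uniform(5.0, 60.0)
        base = estimate_angular_deviation(e, d)
        assert estimate_angular_deviation(3 * e, d) == pytest.approx(3 * base)
        assert estimate_angular_deviation(e, 2 * d) == pytest.approx(base / 2)

    def test_rejects_nonpositive_dimension(self):
        with pytest.raises(ValueError):
            estimate_angular_deviation(0.1, 0.0)
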