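"""Rigid-transform algebra and ICP surface registration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cervkin import (
    RigidTransform,
    TriangleMesh,
    apply_transform,
    compose,
    icp_register,
    initial_align,
    invert,
)
from cervkin.evaluation import random_rigid_transform


def rot(deg, axis):
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.deg2rad(deg) * axis / np.linalg.norm(axis)
                                ).as_matrix()


class TestTransformAlgebra:
    def test_identity_and_inverse(self, rng):
        t = random_rigid_transform(rng, 170.0, 40.0)
        ident = compose(t, invert(t))
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(ident.translation, 0.0, atol=1e-10)
        same = compose(RigidTransform.identity(), t)
        assert np.allclose(same.rotation, t.rotation)
        assert np.allclose(same.translation, t.translation)

    def test_compose_matches_sequential_application(self, rng):
        a = random_rigid_transform(rng, 100.0, 20.0)
        b = random_rigid_transform(rng, 100.0, 20.0)
        pts = rng.normal(scale=30, size=(100, 3))
        assert np.allclose(compose(a, b).apply(pts), a.apply(b.apply(pts)),
                           atol=1e-9)

    def test_textbook_rotation(self):
        t = RigidTransform(rot(90, [0, 0, 1]), np.zeros(3))
        assert np.allclose(t.apply(np.array([1.0, 0, 0])), [0, 1, 0],
                           atol=1e-12)

    def test_apply_then_inverse_restores_mesh(self, c5_mesh, rng):
        t = random_rigid_transform(rng)
        back = apply_transform(apply_transform(c5_mesh, t), invert(t))
        assert np.allclose(back.vertices, c5_mesh.vertices, atol=1e-9)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))

    def test_json_roundtrip(self, tmp_path, rng):
        t = random_rigid_transform(rng)
        t.to_json(tmp_path / "t.json")
        back = RigidTransform.from_json(tmp_path / "t.json")
        assert np.allclose(back.matrix, t.matrix, atol=1e-15)


class TestInitialAlign:
    def test_centroid_modes(self, c5_mesh):
        t = initial_align(c5_mesh, c5_mesh, mode="centroid")
        assert np.allclose(t.translation, 0.0, atol=1e-12)
        shifted = apply_transform(
            c5_mesh, RigidTransform(np.eye(3), np.array([5.0, -3.0, 2.0]))
        )
        t = initial_align(c5_mesh, shifted, mode="centroid")
        assert np.allclose(t.translation, [5, -3, 2], atol=1e-9)
        assert np.allclose(
            initial_align(c5_mesh, c5_mesh, mode="identity").matrix, np.eye(4)
        )

    def test_principal_axes_recover_pure_rotation(self, c5_mesh):
        truth = RigidTransform(rot(90, [0, 1, 0]), np.array([4.0, 0.0, -6.0]))
        target = apply_transform(c5_mesh, truth)
        t = initial_align(c5_mesh, target, mode="centroid+principal_axes")
        err = compose(invert(truth), t)
        assert err.rotation_angle_deg() < 1e-6
        assert np.linalg.norm(err.translation) < 1e-6

    def test_degenerate_inertia_falls_back_to_centroid(self):
        flat = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        with pytest.warns(RuntimeWarning, match="degenerate inertia"):
            t = initial_align(flat, flat, mode="centroid+principal_axes")
        assert np.allclose(t.rotation, np.eye(3))


class TestICP:
    def test_self_registration_is_identity(self, c5_mesh):
        res = icp_register(c5_mesh, c5_mesh, init=RigidTransform.identity())
        assert res.converged
        assert res.final_objective <= 1e-9
        assert np.allclose(res.transform.matrix, np.eye(4), atol=1e-9)

    def test_recovers_known_transform(self, c5_mesh, c5_remeshed):
        truth = RigidTransform(rot(25, [0, 1, 0]), np.array([3.0, 1.0, -2.0]))
        moving = apply_transform(c5_remeshed, truth)
        res = icp_register(moving, c5_mesh)
        assert res.converged
        err = compose(res.transform, truth)
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(err.translation) < 0.1
        # objective trace must never increase
        trace = np.array(res.objective_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_mutual_registrations_are_inverse(self, c5_mesh, c5_remeshed):
        ab = icp_register(c5_remeshed, c5_mesh).transform
        ba = icp_register(c5_mesh, c5_remeshed).transform
        err = compose(ab, ba)
        assert err.rotation_angle_deg() < 0.2
        assert np.linalg.norm(err.translation) < 0.2

    def test_far_displacement_never_silently_wrong(self, c5_mesh, c5_remeshed):
        truth = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        moving = apply_transform(c5_remeshed, truth)
        res = icp_register(moving, c5_mesh, init=RigidTransform.identity(),
                           max_iterations=50)
        err = compose(res.transform, truth)
        genuinely_recovered = (
            err.rotation_angle_deg() < 0.5
            and np.linalg.norm(err.translation) < 0.5
        )
        # either it honestly failed (flag or large residual) or it recovered
        assert (not res.converged) or res.final_objective > 0.5 \
            or genuinely_recovered

    def test_nonfinite_vertices_rejected(self, c5_mesh):
        bad = c5_mesh.with_vertices(c5_mesh.vertices.copy())
        bad.vertices[0, 0] = np.nan
        with pytest.raises(ValueError):
            icp_register(bad, c5_mesh, init=RigidTransform.identity())

    def test_iteration_cap_reports_nonconvergence(self, c5_mesh, c5_remeshed):
        truth = random_rigid_transform(np.random.default_rng(5))
        moving = apply_transform(c5_remeshed, truth)
        res = icp_register(moving, c5_mesh, max_iterations=2)
        assert not res.converged
        assert res.iterations == 2
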