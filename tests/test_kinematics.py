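"""Relative poses, Euler decomposition and intervertebral 6-DOF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cervkin import (
    RigidTransform,
    build_frame,
    compose_rotation,
    decompose_rotation,
    default_stack_frames,
    intervertebral_6dof,
    make_scenario,
    relative_pose,
    transform_frame,
)
from cervkin import LandmarkSet
from cervkin.evaluation import euler_roundtrip_max_error

CANONICAL = LandmarkSet(
    origin_candidate=[0, 0, 0],
    superior_reference=[0, 10, 0],
    left_reference=[20, 0, 0],
    right_reference=[-20, 0, 0],
)


def frame_at(origin):
    f = build_frame(CANONICAL)
    return transform_frame(f, RigidTransform(np.eye(3), np.asarray(origin,
                                                                   float)))


class TestRelativePose:
    def test_identical_frames_give_identity(self):
        f = frame_at([1, 2, 3])
        p = relative_pose(f, f)
        assert np.allclose(p.matrix, np.eye(4), atol=1e-12)

    def test_superior_offset(self):
        lower = frame_at([0, 0, 0])
        upper = frame_at([0, 1, 0])
        p = relative_pose(upper, lower)
        assert np.allclose(p.translation, [0, 1, 0], atol=1e-12)
        assert np.allclose(p.rotation, np.eye(3), atol=1e-12)

    def test_known_relative_rotation_about_lower_y(self, rng):
        lower = frame_at(rng.normal(size=3))
        Ry = Rotation.from_euler("y", 15, degrees=True).as_matrix()
        world_rot = lower.rotation @ Ry @ lower.rotation.T
        upper = transform_frame(lower, RigidTransform(
            world_rot, lower.origin - world_rot @ lower.origin))
        p = relative_pose(upper, lower)
        assert np.allclose(p.rotation, Ry, atol=1e-9)

    def test_antisymmetry(self, rng):
        from cervkin.evaluation import random_rigid_transform
        a = transform_frame(frame_at([0, 0, 0]),
                            random_rigid_transform(rng, 40, 10))
        b = transform_frame(frame_at([0, 9, 0]),
                            random_rigid_transform(rng, 40, 10))
        ab = relative_pose(a, b)
        ba = relative_pose(b, a)
        assert np.allclose(ab.compose(ba).matrix, np.eye(4), atol=1e-10)


class TestEulerDecomposition:
    def test_identity(self):
        assert decompose_rotation(np.eye(3)) == pytest.approx((0, 0, 0))

    def test_single_axis_conventions(self):
        # +20 deg right-hand about the superior axis: left axial rotation
        Ry = Rotation.from_euler("y", 20, degrees=True).as_matrix()
        alpha, gamma, beta = decompose_rotation(Ry)
        assert beta == pytest.approx(20.0, abs=1e-9)
        assert alpha == pytest.approx(0.0, abs=1e-9)
        assert gamma == pytest.approx(0.0, abs=1e-9)
        # +10 deg right-hand about the left axis tips the head forward:
        # flexion, reported negative
        Rx = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        assert decompose_rotation(Rx)[0] == pytest.approx(-10.0, abs=1e-9)
        # +10 deg right-hand about the anterior axis raises the left side:
        # right bending, reported positive
        Rz = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        assert decompose_rotation(Rz)[1] == pytest.approx(10.0, abs=1e-9)

    def test_roundtrip_over_physiological_range(self):
        assert euler_roundtrip_max_error(n=1000, seed=0) < 1e-9

    def test_composed_rotation_reconstructs(self, rng):
        for _ in range(50):
            R = (Rotation.from_euler("x", rng.uniform(-30, 30), degrees=True)
                 * Rotation.from_euler("y", rng.uniform(-30, 30),
                                       degrees=True)).as_matrix()
            rebuilt = compose_rotation(*decompose_rotation(R))
            assert np.allclose(rebuilt, R, atol=1e-9)

    def test_small_angles_sequence_independent(self, rng):
        # cross-sequence differences are second order in the angles
        # (~ theta^2 rad), so the agreement bound scales with the range
        for limit, bound in ((1.5, 0.05), (5.0, 0.5)):
            for _ in range(50):
                angles = rng.uniform(-limit, limit, 3)
                R = compose_rotation(*angles)
                results = [decompose_rotation(R, sequence=s)
                           for s in ("xyz", "xzy", "yxz", "yzx", "zxy", "zyx")]
                spread = np.ptp(np.array(results), axis=0)
                assert (spread < bound).all()

    def test_gimbal_lock_raises(self):
        Rx = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        with pytest.raises(ValueError, match="gimbal"):
            decompose_rotation(Rx, sequence="yxz")

    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            decompose_rotation(np.diag([2.0, 1.0, 1.0]))


class TestIntervertebral6Dof:
    def test_neutral_posture_is_exactly_zero(self):
        sc = make_scenario("ar")
        res = intervertebral_6dof(sc.frames, sc.transforms, "C1-C2", "neutral")
        assert (res.tx, res.ty, res.tz) == (0.0, 0.0, 0.0)
        assert (res.alpha, res.gamma, res.beta) == (0.0, 0.0, 0.0)

    def test_injected_axial_rotation_recovered_exactly(self):
        sc = make_scenario("ar")
        res = intervertebral_6dof(sc.frames, sc.transforms, "C1-C2",
                                  "left_rotation")
        truth = sc.joints["left_rotation"]["C1-C2"]
        assert res.beta == pytest.approx(truth["beta"], abs=1e-9)
        assert res.gamma == pytest.approx(truth["gamma"], abs=1e-9)
        assert res.alpha == pytest.approx(truth["alpha"], abs=1e-9)
        assert abs(res.tx) < 1e-9 and abs(res.ty) < 1e-9 and abs(res.tz) < 1e-9

    def test_pure_anterior_slide(self):
        sc = make_scenario(
            "custom", magnitudes={"flexion": {"C3-C4": {"tz": 1.0}}}
        )
        res = intervertebral_6dof(sc.frames, sc.transforms, "C3-C4", "flexion")
        assert res.tz == pytest.approx(1.0, abs=1e-9)
        assert abs(res.tx) < 1e-9 and abs(res.ty) < 1e-9
        assert abs(res.alpha) < 1e-9 and abs(res.beta) < 1e-9

    def test_absolute_pose_mode_reports_stack_offset(self):
        frames = default_stack_frames(["C3", "C4"])
        sc = make_scenario("custom", magnitudes={}, frames=frames)
        res = intervertebral_6dof(sc.frames, sc.transforms, "C3-C4",
                                  "neutral", mode="absolute_pose")
        # C3's origin sits one C4 height plus one disc gap above C4's
        assert res.ty == pytest.approx(13.5 + 4.0)

    def test_missing_transform_is_named(self):
        sc = make_scenario("ar", frames=default_stack_frames(["C1", "C2"]))
        with pytest.raises(KeyError, match="C2.*flexion"):
            intervertebral_6dof(
                sc.frames, {"flexion": {"C1": RigidTransform.identity()}},
                "C1-C2", "flexion",
            )
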