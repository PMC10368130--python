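import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabmotion.kinematics import (ANGLE_NAMES, DEFAULT_LIMITS_DEG, ArmModel, JointAngles,
                                    JointLimitError, SegmentLengths,
                                    estimate_segment_lengths,
                                    forward_kinematics,
                                    forward_kinematics_batch, hom, rot,
                                    scapulohumeral_rhythm)

RIGHT_CHAIN = [("TOR", "RSHO"), ("RSHO", "RELB"), ("RELB", "RWRI"),
               ("RWRI", "RHAN"), ("RHAN", "RTIP")]
SEGS = ["LSCAP", "LUA", "LLA", "LH", "LT"]


class TestElementaryTransforms:
    def test_zero_angle_is_identity(self):
        for ax in "xyz":
            assert np.allclose(rot(ax, 0.0), np.eye(3))

    def test_rz_quarter_turn_maps_x_to_y(self):
        assert np.allclose(rot("z", np.pi / 2) @ [1, 0, 0], [0, 1, 0],
                           atol=1e-12)

    def test_translation_composition(self):
        t = hom(np.eye(3), [1, 2, 3]) @ hom(np.eye(3), [4, 5, 6])
        assert np.allclose(t, hom(np.eye(3), [5, 7, 9]))

    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=50, deadline=None)
    def test_rotations_orthonormal_det_one(self, angle):
        for ax in "xyz":
            r = rot(ax, angle)
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(r), 1.0)


class TestForwardKinematics:
    def test_rest_pose_segment_gaps(self, arm_models):
        right, left = arm_models
        f = forward_kinematics(JointAngles(), right, left)
        L = right.lengths
        for (a, b), seg in zip(RIGHT_CHAIN, SEGS):
            gap = np.linalg.norm(f.position(a) - f.position(b))
            assert np.isclose(gap, getattr(L, seg))
        # distal chain hangs straight down below the shoulder
        for n in ("RELB", "RWRI", "RHAN", "RTIP"):
            p = f.position(n)
            assert np.isclose(p[0], L.LSCAP) and np.isclose(p[2], 0.0)

    def test_elbow_flexion_right_triangle(self, arm_models):
        right, left = arm_models
        ja = JointAngles()
        ja.right[ANGLE_NAMES.index("elb_x")] = np.pi / 2
        f = forward_kinematics(ja, right, left)
        d = np.linalg.norm(f.position("RWRI") - f.position("RSHO"))
        assert np.isclose(d, np.sqrt(0.30**2 + 0.25**2))
        assert np.isclose(d, 0.3905, atol=5e-5)

    def test_output_has_11_markers(self, arm_models):
        f = forward_kinematics(JointAngles(), *arm_models)
        assert len(f.joints) == 11

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bone_length_conservation_any_angles(self, arm_models, seed):
        right, left = arm_models
        r = np.random.default_rng(seed)
        ja = JointAngles(r.uniform(-1, 1, 9), r.uniform(-1, 1, 9),
                        r.uniform(-1, 1, 3), r.uniform(-0.5, 0.5, 3))
        f = forward_kinematics(ja, right, left)
        L = right.lengths
        for (a, b), seg in zip(RIGHT_CHAIN, SEGS):
            gap = np.linalg.norm(f.position(a) - f.position(b))
            assert abs(gap - getattr(L, seg)) <= 1e-9 * getattr(L, seg)

    def test_mirror_symmetry(self, arm_models, rng):
        right, left = arm_models
        ja = JointAngles(rng.uniform(-0.4, 0.4, 9), np.zeros(9))
        ja.left = ja.right.copy()
        f = forward_kinematics(ja, right, left)
        m = np.diag([-1.0, 1.0, 1.0])
        for s in ("SHO", "ELB", "WRI", "HAN", "TIP"):
            assert np.allclose(m @ f.position("R" + s), f.position("L" + s),
                               atol=1e-12)

    def test_batch_matches_scalar_path(self, arm_models, rng):
        right, left = arm_models
        x = rng.uniform(-0.5, 0.5, (6, 9))
        batch = forward_kinematics_batch(x, right)
        ref = forward_kinematics(JointAngles(right=x[4]), right, left)
        names = ("RSHO", "RELB", "RWRI", "RHAN", "RTIP")
        assert np.allclose(batch[4],
                           np.stack([ref.position(n) for n in names]))

    def test_limit_violation_names_angle(self, arm_models):
        right, left = arm_models
        ja = JointAngles()
        ja.right[ANGLE_NAMES.index("elb_x")] = np.radians(170)
        with pytest.raises(JointLimitError, match="elb_x"):
            forward_kinematics(ja, right, left, check_limits=True)

    def test_dof_count_is_nine_per_arm(self):
        assert len(ANGLE_NAMES) == 9


class TestScapulohumeralRhythm:
    @pytest.mark.parametrize("beta,fb,ud", [
        (70.0, 0.0, 14.4),       # fb: middle and upper branches agree
        (90.0, -4.4, 21.6),
        (-10.0, 3.5, 3.0),
        (0.0, 0.0, 0.0),
        (30.0, 0.0, 0.0),
    ])
    def test_printed_piecewise_values(self, beta, fb, ud):
        got_fb, got_ud = scapulohumeral_rhythm(beta)
        assert np.isclose(got_fb, fb, atol=1e-12)
        assert np.isclose(got_ud, ud, atol=1e-12)

    @pytest.mark.parametrize("bp,which", [(0.0, "fb"), (70.0, "fb"),
                                          (0.0, "ud"), (30.0, "ud")])
    def test_continuity_at_breakpoints(self, bp, which):
        # steepest branch slope is 0.36 deg/deg, so the two-sided gap
        # must shrink like 2 * slope * eps
        i = 0 if which == "fb" else 1
        for eps in (1e-3, 1e-6, 1e-9):
            lo = scapulohumeral_rhythm(bp - eps)[i]
            hi = scapulohumeral_rhythm(bp + eps)[i]
            assert abs(hi - lo) <= 2 * 0.36 * eps + 1e-12

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            scapulohumeral_rhythm(float("nan"))


class TestModelConfig:
    def test_yaml_round_trip_with_overrides(self, tmp_path):
        (tmp_path / "m.yaml").write_text(
            "lengths: {LUA: 0.32, LLA: 0.26}\n"
            "limits_deg: {elb_x: [0, 145]}\n")
        right = ArmModel.from_config(tmp_path / "m.yaml", side="right")
        left = ArmModel.from_config(tmp_path / "m.yaml", side="left")
        assert right.lengths.LUA == 0.32
        assert right.limits_deg["elb_x"] == (0.0, 145.0)
        assert right.limits_deg["sh_y"] == DEFAULT_LIMITS_DEG["sh_y"]
        assert left.side == "left"
        again = ArmModel.from_config(right.to_config())
        assert again.lengths == right.lengths

    def test_unknown_limit_name_rejected(self):
        with pytest.raises(KeyError):
            ArmModel.from_config({"limits_deg": {"knee": [0, 1]}})


class TestSegmentLengthEstimation:
    def test_noise_free_recovery(self, sweep_sim, arm_models):
        right, _ = arm_models
        est = estimate_segment_lengths(sweep_sim.frames)
        for seg in SEGS:
            assert abs(getattr(est, seg)
                       - getattr(right.lengths, seg)) < 1e-9

    def test_noisy_recovery_within_2mm(self, sweep_sim, rng):
        from rehabmotion.skeleton import SkeletonFrame
        frames = []
        for f in sweep_sim.frames * 8:        # n = 320
            joints = {n: p + rng.normal(0, 0.005, 3)
                      for n, p in f.joints.items()}
            frames.append(SkeletonFrame(f.timestamp, joints))
        est = estimate_segment_lengths(frames)
        truth = SegmentLengths()
        for seg in SEGS:
            assert abs(getattr(est, seg) - getattr(truth, seg)) < 2e-3

    def test_too_few_frames_rejected(self, sweep_sim):
        with pytest.raises(ValueError):
            estimate_segment_lengths(sweep_sim.frames[:5])
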