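import numpy as np
import pytest

from rehabmotion.calibration import RigidTransform
from rehabmotion.kinematics import ArmModel
from rehabmotion.simulate import (PROTOCOL, CameraSpec, ImpairmentSpec,
                                  default_camera_pair, generate_trajectory,
                                  get_action, make_assessment_dataset,
                                  render_views)


def _peak_elevation_deg(frames):
    out = []
    for f in frames:
        d = f.position("RTIP") - f.position("RSHO")
        d = d / np.linalg.norm(d)
        out.append(np.degrees(np.arccos(np.clip(-d[1], -1, 1))))
    return max(out)


class TestProtocol:
    def test_catalogue_has_16_actions(self):
        assert len(PROTOCOL) == 16
        ids = [a.id for a in PROTOCOL]
        assert len(set(ids)) == 16
        assert sum(a.kind == "reachable" for a in PROTOCOL) == 8
        assert sum(a.kind == "proximal" for a in PROTOCOL) == 8

    def test_vertical_sweeps_use_printed_azimuths(self):
        azs = sorted(a.azimuth_deg for a in PROTOCOL
                     if a.id.startswith("RW-V"))
        assert azs == [0.0, 45.0, 90.0, 135.0]

    def test_unknown_action_rejected(self):
        with pytest.raises(KeyError, match="unknown action"):
            get_action("RW-V999")


class TestGenerateTrajectory:
    def test_identity_impairment_full_amplitude(self, sweep_sim):
        assert _peak_elevation_deg(sweep_sim.frames) == pytest.approx(
            180.0, abs=1e-6)

    def test_half_rom_halves_peak_elevation(self):
        sim = generate_trajectory("RW-V90", ImpairmentSpec(rom_scale=0.5),
                                  fps=10, seed=1)
        assert _peak_elevation_deg(sim.frames) == pytest.approx(90.0,
                                                                abs=1e-6)

    def test_frames_are_fk_images_of_angles(self, sweep_sim, arm_models):
        from rehabmotion.kinematics import forward_kinematics
        right, left = arm_models
        for ja, f in zip(sweep_sim.angles[::7], sweep_sim.frames[::7]):
            ref = forward_kinematics(ja, right, left)
            for n in f.joints:
                assert np.allclose(f.position(n), ref.position(n),
                                   atol=1e-12)

    def test_seed_determinism(self):
        imp = ImpairmentSpec(rom_scale=0.7, tremor_amp_deg=2.0)
        a = generate_trajectory("Nose", imp, fps=30, seed=9)
        b = generate_trajectory("Nose", imp, fps=30, seed=9)
        for fa, fb in zip(a.frames, b.frames):
            for n in fa.joints:
                assert np.array_equal(fa.position(n), fb.position(n))

    def test_slowness_dilates_duration(self):
        fast = generate_trajectory("Stomach", ImpairmentSpec(), fps=10,
                                   seed=0)
        slow = generate_trajectory("Stomach", ImpairmentSpec(slowness=2.0),
                                   fps=10, seed=0)
        assert len(slow.frames) == 2 * len(fast.frames)


class TestScoreLabel:
    def test_formula_and_clamping(self):
        assert ImpairmentSpec(rom_scale=1.0).score == 100.0
        assert ImpairmentSpec(rom_scale=0.5,
                              tremor_amp_deg=2.0).score == pytest.approx(42.0)
        assert ImpairmentSpec(rom_scale=0.3,
                              tremor_amp_deg=10.0).score == 0.0

    def test_monotone_in_rom_and_tremor(self):
        roms = np.linspace(0.3, 1.0, 8)
        scores = [ImpairmentSpec(rom_scale=r, tremor_amp_deg=2.0).score
                  for r in roms]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        trem = [ImpairmentSpec(rom_scale=0.9, tremor_amp_deg=t).score
                for t in np.linspace(0, 5, 6)]
        assert all(b <= a for a, b in zip(trem, trem[1:]))


class TestRenderViews:
    def test_noiseless_rendering_is_exact_rigid_transform(self, sweep_sim):
        cam_a, cam_b = default_camera_pair()
        cam_a = CameraSpec(pose=cam_a.pose, occlusion_enabled=False)
        cam_b = CameraSpec(pose=cam_b.pose, occlusion_enabled=False)
        sa, sb = render_views(sweep_sim.frames[:5], cam_a, cam_b, seed=0)
        for f_true, fa in zip(sweep_sim.frames[:5], sa):
            back = cam_a.pose.apply(fa.position("HANDTIP_RIGHT"))
            assert np.allclose(back, f_true.position("RTIP"), atol=1e-12)

    def test_each_device_frame_has_32_joints(self, sweep_sim):
        cam_a, cam_b = default_camera_pair()
        sa, sb = render_views(sweep_sim.frames[:3], cam_a, cam_b, seed=0)
        assert all(len(f.joints) == 32 for f in sa + sb)

    def test_dropout_rate_binomial(self, sweep_sim):
        cam = CameraSpec(pose=default_camera_pair()[0].pose,
                         dropout_prob=0.2, occlusion_enabled=False)
        sim = generate_trajectory("RW-V90",
                                  ImpairmentSpec(slowness=3.0), fps=30,
                                  seed=2)
        sa, _ = render_views(sim.frames, cam, cam, seed=5)
        flags = [c == 0.0 for f in sa for c in f.confidence.values()]
        assert len(flags) >= 10000
        assert abs(np.mean(flags) - 0.2) < 0.01

    def test_seeded_streams_bit_identical(self, sweep_sim):
        cam_a, cam_b = default_camera_pair(noise_sd_m=0.01,
                                           dropout_prob=0.1)
        a1, b1 = render_views(sweep_sim.frames[:10], cam_a, cam_b, seed=3)
        a2, b2 = render_views(sweep_sim.frames[:10], cam_a, cam_b, seed=3)
        for s1, s2 in ((a1, a2), (b1, b2)):
            for f1, f2 in zip(s1, s2):
                assert all(np.array_equal(f1.position(n), f2.position(n))
                           for n in f1.joints)

    def test_occluded_joint_gets_sentinel_and_zero_confidence(self):
        sim = generate_trajectory("LumbarSpine", ImpairmentSpec(), fps=15,
                                  seed=1)
        cam_a, cam_b = default_camera_pair()
        sa, _ = render_views(sim.frames, cam_a, cam_b, seed=0)
        occluded = [(f, n) for f in sa for n in f.joints
                    if f.confidence[n] == 0.0]
        assert occluded, "reach behind the back must occlude something"
        f, n = occluded[0]
        assert np.allclose(f.position(n), 0.0)

    def test_default_pair_geometry(self):
        cam_a, cam_b = default_camera_pair()
        spacing = np.linalg.norm(cam_a.pose.translation
                                 - cam_b.pose.translation)
        assert spacing == pytest.approx(2.0)
        za = cam_a.pose.rotation[:, 2]
        zb = cam_b.pose.rotation[:, 2]
        angle = np.degrees(np.arccos(np.clip(np.dot(za, zb), -1, 1)))
        assert angle == pytest.approx(90.0)


class TestAssessmentDataset:
    def test_shapes_and_normalization(self):
        x, y, labels = make_assessment_dataset(6, seed=0, n_frames=24)
        assert x.shape == (6, 24, 11, 3)
        assert y.shape == (6,) and len(labels) == 6
        assert np.all((y >= 0) & (y <= 100))
        # TOR-centered: node 0 stays near the origin (noise only)
        assert np.abs(x[:, :, 0, :]).max() < 0.05
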