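import numpy as np
import pytest

from rehabmotion.ik import (FitnessTarget, Swarm, SwarmConfig,
                            UnderdeterminedError, crossbreed, fitness,
                            pso_step, solve_frame, solve_sequence)
from rehabmotion.kinematics import ArmModel, JointAngles, forward_kinematics
from rehabmotion.simulate import ImpairmentSpec, generate_trajectory


def _sphere(x):
    return np.sum(np.asarray(x) ** 2, axis=-1)


def _make_swarm(cfg, rng, bounds=None):
    bounds = bounds if bounds is not None else np.array([[-5.0, 5.0]] * cfg.D)
    return Swarm.initialize(cfg, bounds, _sphere, rng)


class TestPsoStep:
    def test_all_zero_coefficients_freeze_positions(self, rng):
        cfg = SwarmConfig(N=10, D=3, omega=0.0, c1=0.0, c2=0.0)
        sw = _make_swarm(cfg, rng)
        x_before = sw.X.copy()
        pso_step(sw, cfg, _sphere, rng)
        assert np.array_equal(sw.X, x_before)

    def test_particle_at_both_bests_with_zero_velocity_stays(self, rng):
        cfg = SwarmConfig(N=4, D=2)
        sw = _make_swarm(cfg, rng)
        sw.X[0] = sw.pbest[0] = sw.gbest.copy()
        sw.pbest_fit[0] = sw.gbest_fit
        sw.V[0] = 0.0
        x0 = sw.X[0].copy()
        pso_step(sw, cfg, _sphere, rng)
        assert np.allclose(sw.X[0], x0)

    def test_gbest_monotone_nonincreasing(self, rng):
        cfg = SwarmConfig(N=20, D=4)
        sw = _make_swarm(cfg, rng)
        last = sw.gbest_fit
        for _ in range(50):
            pso_step(sw, cfg, _sphere, rng)
            assert sw.gbest_fit <= last + 1e-15
            last = sw.gbest_fit

    def test_positions_clamped_to_bounds(self, rng):
        cfg = SwarmConfig(N=15, D=3)
        b = np.array([[-1.0, 1.0]] * 3)
        sw = Swarm.initialize(cfg, b, _sphere, rng)
        for _ in range(20):
            pso_step(sw, cfg, _sphere, rng)
            assert np.all(sw.X >= -1.0) and np.all(sw.X <= 1.0)


class TestCrossbreed:
    def test_pc_one_child_equals_parent1(self, rng):
        cfg = SwarmConfig(N=2, D=3, Pc=1.0, pool_frac=1.0)
        sw = _make_swarm(cfg, rng)
        x = sw.X.copy()
        crossbreed(sw, cfg, _sphere, rng)
        # with Pc=1 each child keeps its own parent's position
        assert np.allclose(np.sort(sw.X, axis=0), np.sort(x, axis=0))

    def test_child_velocity_normalized_sum(self):
        cfg = SwarmConfig(N=2, D=2, Pc=0.5, pool_frac=1.0)
        rng = np.random.default_rng(0)
        sw = Swarm.initialize(cfg, np.array([[-5.0, 5.0]] * 2), _sphere,
                              rng)
        sw.V[0] = np.array([1.0, 0.0])
        sw.V[1] = np.array([0.0, 1.0])
        crossbreed(sw, cfg, _sphere, rng)
        expect = np.array([1.0, 1.0]) / np.sqrt(2.0)
        # both parents had unit speed: both children get the same velocity
        assert np.allclose(sw.V[0], expect)
        assert np.allclose(sw.V[1], expect)

    def test_small_pool_is_noop(self, rng):
        cfg = SwarmConfig(N=10, D=2, pool_frac=0.05)   # pool rounds to 0
        sw = _make_swarm(cfg, rng)
        x, v = sw.X.copy(), sw.V.copy()
        crossbreed(sw, cfg, _sphere, rng)
        assert np.array_equal(sw.X, x) and np.array_equal(sw.V, v)


class TestFitness:
    def test_zero_at_generating_angles(self, sweep_sim):
        i = 12
        target = FitnessTarget.from_model_frame(sweep_sim.frames[i],
                                                "right")
        val = fitness(sweep_sim.angles[i].right, target, ArmModel("right"))
        assert val < 1e-18

    def test_perturbation_strictly_increases(self, sweep_sim):
        i = 12
        target = FitnessTarget.from_model_frame(sweep_sim.frames[i],
                                                "right")
        base = fitness(sweep_sim.angles[i].right, target,
                       ArmModel("right"))
        for j in (2, 3, 5):
            pert = sweep_sim.angles[i].right.copy()
            pert[j] += 0.05
            assert fitness(pert, target, ArmModel("right")) > base

    def test_underdetermined_target_rejected(self, sweep_sim):
        f = sweep_sim.frames[0]
        for n in ("RELB", "RWRI", "RHAN", "RTIP"):
            f.confidence[n] = 0.0
        with pytest.raises(UnderdeterminedError):
            FitnessTarget.from_model_frame(f, "right")


class TestSolveFrame:
    def test_warm_start_at_truth_returns_immediately(self, sweep_sim):
        i = 10
        target = FitnessTarget.from_model_frame(sweep_sim.frames[i],
                                                "right")
        res = solve_frame(target, SwarmConfig(seed=3), ArmModel("right"),
                          warm_start=sweep_sim.angles[i].right)
        assert res.fitness < 1e-12
        assert res.iterations <= 2

    def test_cold_start_reconstructs_markers(self, sweep_sim, arm_models):
        right, left = arm_models
        i = 10
        frame = sweep_sim.frames[i]
        target = FitnessTarget.from_model_frame(frame, "right")
        res = solve_frame(target, SwarmConfig(seed=1), right)
        rec = forward_kinematics(JointAngles(right=res.angles), right, left)
        rms = np.sqrt(np.mean([
            np.sum((rec.position(n) - frame.position(n)) ** 2)
            for n in ("RSHO", "RELB", "RWRI", "RHAN", "RTIP")]))
        assert rms < 1e-3


class TestSolveSequence:
    def test_constant_pose_gives_constant_angles(self, arm_models):
        right, left = arm_models
        ja = JointAngles()
        ja.right[2], ja.right[5] = 0.4, 0.8
        frame = forward_kinematics(ja, right, left)
        frames = []
        from rehabmotion.skeleton import SkeletonFrame
        for i in range(6):
            frames.append(SkeletonFrame(i * 0.1, dict(frame.joints)))
        sol = solve_sequence(frames, SwarmConfig(seed=2), sides=("right",))
        drift = np.abs(np.diff(
            np.stack([a.right for a in sol.angles]), axis=0))
        assert drift.max() < 1e-6

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            solve_sequence([], SwarmConfig())

    def test_reconstruction_is_bone_length_exact(self, sweep_sim,
                                                 arm_models):
        right, _ = arm_models
        sol = solve_sequence(sweep_sim.frames[5:8], SwarmConfig(seed=4),
                             sides=("right",))
        L = right.lengths
        chain = [("TOR", "RSHO", L.LSCAP), ("RSHO", "RELB", L.LUA),
                 ("RELB", "RWRI", L.LLA), ("RWRI", "RHAN", L.LH),
                 ("RHAN", "RTIP", L.LT)]
        for f in sol.frames:
            for a, b, ell in chain:
                gap = np.linalg.norm(f.position(a) - f.position(b))
                assert abs(gap - ell) <= 1e-9 * ell

    def test_occluded_tip_still_reconstructed_nearby(self, sweep_sim):
        # hide the two distal markers mid-sequence; the warm-started
        # chain must still place RTIP within a few centimetres
        from rehabmotion.skeleton import SkeletonFrame
        frames = []
        for k, f in enumerate(sweep_sim.frames[8:12]):
            g = SkeletonFrame(f.timestamp, dict(f.joints),
                              dict(f.confidence))
            if k in (1, 2):
                g.confidence["RTIP"] = 0.0
                g.confidence["RHAN"] = 0.0
            frames.append(g)
        sol = solve_sequence(frames, SwarmConfig(seed=6), sides=("right",))
        for rec, truth in zip(sol.frames, sweep_sim.frames[8:12]):
            err = np.linalg.norm(rec.position("RTIP")
                                 - truth.position("RTIP"))
            assert err < 0.03
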