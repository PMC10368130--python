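"""Inverse kinematics by crossbreed particle swarm optimization (CBPSO).

Per frame, the 9 joint angles of one arm are recovered by minimizing the
confidence-weighted squared distance between observed markers and the
forward-kinematic image of a candidate angle vector, optionally plus a
soft scapulohumeral-rhythm prior that regularizes how girdle and humeral
elevation share the lift.  The swarm uses the classical inertia-weight
velocity/position update extended with a crossbreed operator: selected
parent pairs are replaced by children whose position is a Pc-blend of
the parents and whose velocity is the normalized parent-velocity sum
rescaled to the first parent's speed — a genetic-style mixing that lets
particles escape local minima of the redundant chain.

Sequences are solved frame by frame with warm starts: each frame's
swarm seeds one particle at the previous solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import RigidTransform
from .kinematics import (ANGLE_NAMES, ArmModel, JointAngles,
                         forward_kinematics, forward_kinematics_batch)
from .skeleton import SkeletonFrame

__all__ = [
    "SwarmConfig", "Swarm", "FitnessTarget", "UnderdeterminedError",
    "fitness", "pso_step", "crossbreed", "solve_frame", "solve_sequence",
    "IKResult", "SequenceResult",
]

_ARM_MARKERS = {"right": ("RSHO", "RELB", "RWRI", "RHAN", "RTIP"),
                "left": ("LSHO", "LELB", "LWRI", "LHAN", "LTIP")}


class UnderdeterminedError(ValueError):
    """Fewer than 3 confident markers: the arm pose is unconstrained."""


@dataclass(frozen=True)
class SwarmConfig:
    """CBPSO hyper-parameters.

    N particles in D dimensions; omega is the inertia weight, c1/c2 the
    cognitive/social learning factors, Pc the crossbreed blend weight.
    Each iteration the crossbreed operator fires with probability
    ``crossbreed_prob`` on a pool of ``pool_frac`` of the swarm.
    """

    N: int = 60
    D: int = 9
    omega: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    Pc: float = 0.6
    pool_frac: float = 0.2
    crossbreed_prob: float = 0.5
    max_iter: int = 300
    tol: float = 1e-8
    seed: int = 0
    rhythm_weight: float = 1e-5
    attempts: int = 3       # fresh cold re-runs while fitness stays poor
    refine: bool = True     # narrowing-box polish after each attempt

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need at least 2 particles")
        if not 0 <= self.Pc <= 1:
            raise ValueError("Pc must be in [0, 1]")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("learning factors must be >= 0")


@dataclass
class Swarm:
    """Particle positions/velocities plus personal and global bests."""

    X: np.ndarray          # (N, D)
    V: np.ndarray          # (N, D)
    pbest: np.ndarray      # (N, D)
    pbest_fit: np.ndarray  # (N,)
    gbest: np.ndarray      # (D,)
    gbest_fit: float
    bounds: np.ndarray     # (D, 2)

    @classmethod
    def initialize(cls, config: SwarmConfig, bounds: np.ndarray,
                   fitness_fn: Callable[[np.ndarray], np.ndarray],
                   rng: np.random.Generator,
                   warm_start: Optional[np.ndarray] = None) -> "Swarm":
        lo, hi = bounds[:, 0], bounds[:, 1]
        x = rng.uniform(lo, hi, size=(config.N, config.D))
        if warm_start is not None:
            # seed a local cluster around the warm start: one particle on
            # it exactly, a third of the swarm perturbed around it
            w = np.clip(np.asarray(warm_start, float), lo, hi)
            k = max(config.N // 3, 1)
            x[:k] = np.clip(w + rng.normal(0.0, 0.05, size=(k, config.D)),
                            lo, hi)
            x[0] = w
        v = rng.uniform(-0.1, 0.1, size=(config.N, config.D)) * (hi - lo)
        fit = fitness_fn(x)
        g = int(np.argmin(fit))
        return cls(X=x, V=v, pbest=x.copy(), pbest_fit=fit.copy(),
                   gbest=x[g].copy(), gbest_fit=float(fit[g]),
                   bounds=bounds)

    def _absorb(self, fit: np.ndarray) -> None:
        better = fit < self.pbest_fit
        self.pbest[better] = self.X[better]
        self.pbest_fit[better] = fit[better]
        g = int(np.argmin(self.pbest_fit))
        if self.pbest_fit[g] < self.gbest_fit:
            self.gbest = self.pbest[g].copy()
            self.gbest_fit = float(self.pbest_fit[g])


def pso_step(swarm: Swarm, config: SwarmConfig,
             fitness_fn: Callable[[np.ndarray], np.ndarray],
             rng: np.random.Generator) -> Swarm:
    """One classical PSO iteration (in place; returns the swarm).

    Velocity mixes inertia, the pull toward each particle's personal
    best and the pull toward the global best, with fresh uniform random
    factors per particle per dimension; positions are clamped to bounds
    with velocity zeroed on clamped dimensions.  The global best is
    non-increasing.
    """
    n, d = swarm.X.shape
    r1 = rng.uniform(size=(n, d))
    r2 = rng.uniform(size=(n, d))
    swarm.V = (config.omega * swarm.V
               + config.c1 * r1 * (swarm.pbest - swarm.X)
               + config.c2 * r2 * (swarm.gbest[None, :] - swarm.X))
    vmax = 0.25 * (swarm.bounds[:, 1] - swarm.bounds[:, 0])
    swarm.V = np.clip(swarm.V, -vmax, vmax)
    swarm.X = swarm.X + swarm.V
    lo, hi = swarm.bounds[:, 0], swarm.bounds[:, 1]
    clamped = (swarm.X < lo) | (swarm.X > hi)
    swarm.X = np.clip(swarm.X, lo, hi)
    swarm.V[clamped] = 0.0
    swarm._absorb(fitness_fn(swarm.X))
    return swarm


def crossbreed(swarm: Swarm, config: SwarmConfig,
               fitness_fn: Callable[[np.ndarray], np.ndarray],
               rng: np.random.Generator) -> Swarm:
    """Crossbreed (hybridization) operator.

    A pool of ``pool_frac`` of the swarm is drawn uniformly and paired at
    random.  Each parent is replaced by a child: the child position
    blends the pair's positions with weight Pc, the child velocity is
    the normalized parent-velocity sum rescaled to the replaced parent's
    speed (falling back to that parent's velocity when the sum
    vanishes).  Personal-best memories stay with the slots; the global
    best is untouched, so its fitness remains non-increasing.
    """
    n = swarm.X.shape[0]
    pool_size = int(round(config.pool_frac * n))
    pool_size -= pool_size % 2
    if pool_size < 2:
        return swarm
    idx = rng.choice(n, size=pool_size, replace=False)
    for a, b in idx.reshape(-1, 2):
        x1, x2 = swarm.X[a].copy(), swarm.X[b].copy()
        v1, v2 = swarm.V[a].copy(), swarm.V[b].copy()
        child_a = config.Pc * x1 + (1.0 - config.Pc) * x2
        child_b = config.Pc * x2 + (1.0 - config.Pc) * x1
        vsum = v1 + v2
        norm = np.linalg.norm(vsum)
        if norm < 1e-300:
            cva, cvb = v1, v2
        else:
            unit = vsum / norm
            cva = unit * np.linalg.norm(v1)
            cvb = unit * np.linalg.norm(v2)
        swarm.X[a], swarm.X[b] = child_a, child_b
        swarm.V[a], swarm.V[b] = cva, cvb
    lo, hi = swarm.bounds[:, 0], swarm.bounds[:, 1]
    swarm.X = np.clip(swarm.X, lo, hi)
    swarm._absorb(fitness_fn(swarm.X))
    return swarm


# --- the IK fitness ------------------------------------------------------

@dataclass
class FitnessTarget:
    """Observed markers of one arm in the torso's parent (world) frame.

    ``positions``/``weights`` follow the shoulder..tip order; weight 0
    marks an occluded marker, excluded from the sum.  ``torso`` is the
    world-from-torso transform under which candidate angles are imaged.
    """

    positions: np.ndarray                 # (5, 3)
    weights: np.ndarray                   # (5,)
    torso: RigidTransform = field(default_factory=RigidTransform.identity)
    rhythm_weight: float = 1e-5
    # weak temporal-continuity prior: pins DOF the visible markers do not
    # constrain (e.g. wrist angles while the hand is occluded) to the
    # previous frame's solution without measurably biasing observed DOF
    continuity_ref: Optional[np.ndarray] = None
    continuity_weight: float = 1e-6

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(5, 3)
        self.weights = np.asarray(self.weights, float).reshape(5)
        if int(np.sum(self.weights > 0)) < 3:
            raise UnderdeterminedError(
                "fewer than 3 confident markers for this arm")

    @classmethod
    def from_model_frame(cls, frame: SkeletonFrame, side: str,
                         torso: Optional[RigidTransform] = None,
                         rhythm_weight: float = 1e-5) -> "FitnessTarget":
        names = _ARM_MARKERS[side]
        pos = np.stack([frame.position(n) for n in names])
        w = np.array([frame.confidence.get(n, 0.0) for n in names])
        if torso is None:
            tor = frame.position("TOR")
            torso = RigidTransform(np.eye(3), tor) \
                if frame.confidence.get("TOR", 0) > 0 \
                else RigidTransform.identity()
        return cls(positions=pos, weights=w, torso=torso,
                   rhythm_weight=rhythm_weight)


def _rhythm_deg_vec(beta_deg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized piecewise rhythm functions, degrees in/out."""
    b = np.asarray(beta_deg, float)
    fb = np.where(b < 0, -0.35 * b, np.where(b <= 70, 0.0,
                                             -0.22 * b + 15.4))
    ud = np.where(b < 0, -0.3 * b, np.where(b <= 30, 0.0,
                                            0.36 * b - 10.8))
    return fb, ud


def fitness(x: np.ndarray, target: FitnessTarget,
            model: ArmModel) -> np.ndarray:
    """Weighted squared marker distance (+ rhythm prior), vectorized.

    ``x`` is (..., 9); the return drops the angle axis.  The rhythm
    prior penalizes the squared deviation (radians) of the candidate
    girdle angles from the rhythm-predicted values at the candidate's
    own humeral elevation.
    """
    x = np.asarray(x, float)
    t44 = np.eye(4)
    t44[:3, :3] = target.torso.rotation
    t44[:3, 3] = target.torso.translation
    markers = forward_kinematics_batch(x, model, t44)   # (..., 5, 3)
    d2 = np.sum((markers - target.positions) ** 2, axis=-1)  # (..., 5)
    cost = np.sum(target.weights * d2, axis=-1)
    if target.rhythm_weight > 0:
        ua = markers[..., 1, :] - markers[..., 0, :]   # elbow - shoulder
        ua = target.torso.rotation.T @ ua[..., None]
        ua = ua[..., 0]
        nrm = np.linalg.norm(ua, axis=-1)
        cos_el = np.clip(-ua[..., 1] / np.maximum(nrm, 1e-12), -1, 1)
        beta = np.degrees(np.arccos(cos_el))
        fb, ud = _rhythm_deg_vec(beta)
        dev = ((x[..., 0] - np.radians(fb)) ** 2
               + (x[..., 1] - np.radians(ud)) ** 2)
        cost = cost + target.rhythm_weight * dev
    if target.continuity_ref is not None and target.continuity_weight > 0:
        cost = cost + target.continuity_weight * np.sum(
            (x - target.continuity_ref) ** 2, axis=-1)
    return cost


@dataclass
class IKResult:
    angles: np.ndarray
    fitness: float
    iterations: int


def solve_frame(target: FitnessTarget, config: SwarmConfig,
                model: ArmModel,
                warm_start: Optional[np.ndarray] = None,
                rng: Optional[np.random.Generator] = None) -> IKResult:
    """Solve one arm's 9 angles for one frame by CBPSO."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bounds = model.bounds_rad()
    cfg = replace(config, D=9)

    def f(x):
        return fitness(x, target, model)

    def run(box: np.ndarray, warm: Optional[np.ndarray],
            n_iter: int) -> Tuple[np.ndarray, float, int]:
        swarm = Swarm.initialize(cfg, box, f, rng, warm_start=warm)
        it = 0
        while it < n_iter and swarm.gbest_fit > cfg.tol:
            pso_step(swarm, cfg, f, rng)
            if (cfg.crossbreed_prob > 0
                    and rng.random() < cfg.crossbreed_prob):
                crossbreed(swarm, cfg, f, rng)
            it += 1
        return swarm.gbest.copy(), swarm.gbest_fit, it

    # Up to three attempts: the first from the warm start, later ones
    # cold with fresh randomness (escapes a wrong basin).  Each attempt
    # is followed by narrowing restarts — plain CBPSO re-seeded inside a
    # shrinking box around the incumbent best, which polishes off the
    # last millimetres of a stall.
    accept = max(cfg.tol * 100.0, cfg.tol)
    best, best_fit, total_it = None, np.inf, 0
    for attempt in range(max(cfg.attempts, 1)):
        warm = warm_start if attempt == 0 else None
        cand, cand_fit, it = run(bounds, warm, cfg.max_iter)
        total_it += it
        for half_width in ((0.3, 0.1, 0.03) if cfg.refine else ()):
            if cand_fit <= cfg.tol:
                break
            box = np.column_stack([
                np.maximum(cand - half_width, bounds[:, 0]),
                np.minimum(cand + half_width, bounds[:, 1])])
            c2, f2, it = run(box, cand, cfg.max_iter // 2)
            total_it += it
            if f2 < cand_fit:
                cand, cand_fit = c2, f2
        if cand_fit < best_fit:
            best, best_fit = cand, cand_fit
        if best_fit <= accept:
            break
    return IKResult(angles=best, fitness=best_fit, iterations=total_it)


@dataclass
class SequenceResult:
    """Angle trajectories and FK-reconstructed markers for a stream."""

    angles: List[JointAngles]
    frames: List[SkeletonFrame]
    fitness_right: np.ndarray
    fitness_left: np.ndarray
    failures: List[int]


def estimate_torso_pose(frame: SkeletonFrame,
                        previous: Optional[RigidTransform] = None
                        ) -> RigidTransform:
    """Torso pose from the TOR marker (identity orientation).

    The subject faces the master camera and does not rotate the trunk,
    so orientation is held at identity; translation tracks the neck
    marker, carrying the previous estimate through TOR occlusions.
    """
    if frame.confidence.get("TOR", 0.0) > 0:
        return RigidTransform(np.eye(3), frame.position("TOR"))
    return previous if previous is not None else RigidTransform.identity()


def solve_sequence(frames: Sequence[SkeletonFrame], config: SwarmConfig,
                   right: Optional[ArmModel] = None,
                   left: Optional[ArmModel] = None,
                   sides: Tuple[str, ...] = ("right", "left")
                   ) -> SequenceResult:
    """Frame-by-frame CBPSO IK with warm starts along the sequence.

    Underdetermined frames (too few confident markers) keep the previous
    solution and are listed in ``failures``.  The reconstructed marker
    stream is the forward-kinematic image of the solved angles, so it is
    bone-length exact by construction.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty sequence")
    right = right or ArmModel("right")
    left = left or ArmModel("left")
    models = {"right": right, "left": left}
    rng = np.random.default_rng(config.seed)
    warm = {"right": None, "left": None}
    torso_prev: Optional[RigidTransform] = None
    out_angles: List[JointAngles] = []
    out_frames: List[SkeletonFrame] = []
    fit = {"right": np.full(len(frames), np.nan),
           "left": np.full(len(frames), np.nan)}
    failures: List[int] = []
    for i, frame in enumerate(frames):
        torso = estimate_torso_pose(frame, torso_prev)
        torso_prev = torso
        ja = JointAngles(torso_t=torso.translation)
        failed = False
        for side in sides:
            try:
                target = FitnessTarget.from_model_frame(
                    frame, side, torso=torso,
                    rhythm_weight=config.rhythm_weight)
                target.continuity_ref = warm[side]
                res = solve_frame(target, config, models[side],
                                  warm_start=warm[side], rng=rng)
                warm[side] = res.angles
                fit[side][i] = res.fitness
            except UnderdeterminedError:
                failed = True
            if warm[side] is not None:
                setattr(ja, side, warm[side].copy())
        if failed:
            failures.append(i)
        out_angles.append(ja)
        out_frames.append(forward_kinematics(ja, right, left,
                                             timestamp=frame.timestamp))
    return SequenceResult(angles=out_angles, frames=out_frames,
                          fitness_right=fit["right"],
                          fitness_left=fit["left"], failures=failures)
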