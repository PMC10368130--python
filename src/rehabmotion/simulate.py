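"""Synthetic motion and sensor simulator.

Emulates the 16-action assessment protocol — eight reachable-workspace
sweeps with the arm straight (four vertical-plane sweeps at azimuths
0/45/90/135 deg traversing elevation 0-180 deg, four horizontal sweeps
at fixed elevations) and eight proximal touch targets (side, lumbar
spine, stomach, contralateral shoulder, ipsilateral shoulder, nose, ear,
head top) — as ground-truth joint-angle trajectories of the 9-DOF arm
model, then renders them to two noisy, occlusion-corrupted camera views
in the 32-joint device format.

Impairment is explicit: a range-of-motion scale in (0, 1] multiplying
angular amplitude, band-limited tremor added in joint-angle space
(default 4-8 Hz, so corrupted motion stays biologically connected), and
a slowness time-dilation factor.  The ground-truth quality label is the
documented deterministic formula

    score = clip(100 * rom_scale - c_t * tremor_amp_deg, 0, 100)

with c_t a config constant (default 4 points per degree of tremor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal
from scipy.spatial.transform import Rotation

from .calibration import RigidTransform
from .kinematics import (ANGLE_NAMES, ArmModel, JointAngles, SegmentLengths,
                         forward_kinematics, scapulohumeral_rhythm)
from .skeleton import (DEVICE_JOINTS, MODEL_MARKERS, MODEL_TO_DEVICE,
                       SkeletonFrame)

__all__ = [
    "ProtocolAction", "ImpairmentSpec", "CameraSpec", "PROTOCOL",
    "get_action", "generate_trajectory", "render_views",
    "default_camera_pair", "make_assessment_dataset", "SimulationResult",
    "normalize_sequence", "resample_time",
]

#: Points of score lost per degree of tremor amplitude.
TREMOR_SCORE_WEIGHT = 4.0


@dataclass(frozen=True)
class ProtocolAction:
    """One protocol action: a workspace sweep or a proximal reach."""

    id: str
    kind: str                      # "reachable" | "proximal"
    azimuth_deg: float = 0.0       # sweep plane azimuth (vertical sweeps)
    elevation_deg: float = 0.0     # fixed elevation (horizontal sweeps)
    sweep_amplitude_deg: float = 180.0
    duration_s: float = 4.0
    target_angles_deg: Optional[Tuple[float, ...]] = None  # proximal preset


def _rw_vertical(az: float) -> ProtocolAction:
    return ProtocolAction(id=f"RW-V{az:g}", kind="reachable",
                          azimuth_deg=az, sweep_amplitude_deg=180.0)


def _rw_horizontal(elev: float, amp: float) -> ProtocolAction:
    return ProtocolAction(id=f"RW-H{elev:g}", kind="reachable",
                          elevation_deg=elev, sweep_amplitude_deg=amp)


# Proximal presets: per-action target arm angles, degrees, in chain order
# (sh_x, sh_y, sh_z, elb_x, wr_x, wr_z, hand_x).  The forward-kinematic
# image of each preset places the hand tip near the named body landmark.
_PROXIMAL_TARGETS: Dict[str, Tuple[float, ...]] = {
    "Side": (-34, 2, 1, 45, 53, 1, 33),
    "LumbarSpine": (-47, -18, -10, 39, 59, -7, 37),
    "Stomach": (-27, -21, -11, 64, 60, -8, 35),
    "ContralateralShoulder": (14, -52, -64, 84, 53, -20, 26),
    "IpsilateralShoulder": (-3, 0, 0, 134, 68, 0, 32),
    "Nose": (59, -27, -19, 113, 39, -17, 19),
    "Ear": (65, -24, -7, 130, 37, -12, 17),
    "HeadTop": (94, -16, -34, 106, 35, -20, 17),
}

#: The 16-action catalogue: 8 reachable-workspace sweeps + 8 proximal.
PROTOCOL: Tuple[ProtocolAction, ...] = tuple(
    [_rw_vertical(az) for az in (0.0, 45.0, 90.0, 135.0)]
    + [_rw_horizontal(e, 135.0) for e in (45.0, 90.0, 135.0)]
    + [_rw_horizontal(180.0, 180.0)]
    + [ProtocolAction(id=name, kind="proximal", duration_s=3.0,
                      target_angles_deg=t)
       for name, t in _PROXIMAL_TARGETS.items()]
)

_ACTION_INDEX = {a.id: a for a in PROTOCOL}
assert len(PROTOCOL) == 16


def get_action(action_id: str) -> ProtocolAction:
    try:
        return _ACTION_INDEX[action_id]
    except KeyError:
        raise KeyError(
            f"unknown action {action_id!r}; known: {sorted(_ACTION_INDEX)}"
        ) from None


@dataclass(frozen=True)
class ImpairmentSpec:
    """Explicit impairment model with its deterministic quality label."""

    rom_scale: float = 1.0
    tremor_amp_deg: float = 0.0
    tremor_band_hz: Tuple[float, float] = (4.0, 8.0)
    slowness: float = 1.0

    def __post_init__(self):
        if not 0 < self.rom_scale <= 1:
            raise ValueError("rom_scale must be in (0, 1]")
        if self.tremor_amp_deg < 0:
            raise ValueError("tremor amplitude must be >= 0")
        if self.slowness < 1:
            raise ValueError("slowness must be >= 1")

    @property
    def score(self) -> float:
        """100 * rom_scale - c_t * tremor_amp, clamped to [0, 100]."""
        raw = 100.0 * self.rom_scale - TREMOR_SCORE_WEIGHT * self.tremor_amp_deg
        return float(np.clip(raw, 0.0, 100.0))


@dataclass(frozen=True)
class CameraSpec:
    """One rendered viewpoint: pose, additive noise, occlusion, dropout."""

    pose: RigidTransform              # camera-in-world
    noise_sd_m: float = 0.0
    dropout_prob: float = 0.0
    occlusion_enabled: bool = True
    occlusion_margin_m: float = 0.15

    def __post_init__(self):
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")

    @property
    def world_to_camera(self) -> RigidTransform:
        return self.pose.inverse()


def _look_at(center: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Camera-in-world pose with +z toward the target, y up-ish."""
    z = np.asarray(target, float) - np.asarray(center, float)
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(up, z)
    if np.linalg.norm(x) < 1e-9:
        x = np.array([1.0, 0.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    r = np.stack([x, y, z], axis=1)  # columns are camera axes in world
    return RigidTransform(r, np.asarray(center, float))


def default_camera_pair(noise_sd_m: float = 0.0,
                        dropout_prob: float = 0.0,
                        occlusion_enabled: bool = True
                        ) -> Tuple[CameraSpec, CameraSpec]:
    """Two cameras 2 m apart with a 90 deg angle, both aimed at the torso."""
    cam_a = CameraSpec(pose=_look_at(np.array([-1.0, 0.0, 1.0]),
                                     np.zeros(3)),
                       noise_sd_m=noise_sd_m, dropout_prob=dropout_prob,
                       occlusion_enabled=occlusion_enabled)
    cam_b = CameraSpec(pose=_look_at(np.array([1.0, 0.0, 1.0]),
                                     np.zeros(3)),
                       noise_sd_m=noise_sd_m, dropout_prob=dropout_prob,
                       occlusion_enabled=occlusion_enabled)
    return cam_a, cam_b


# --- trajectory generation ----------------------------------------------

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def _sweep_direction(beta_rad: np.ndarray, azimuth_rad: np.ndarray
                     ) -> np.ndarray:
    """Arm direction at elevation beta in the vertical plane at azimuth.

    Azimuth 0 is the subject's right (+x), 90 deg is straight ahead
    (+z); elevation 0 hangs down (-y), 180 points up.
    """
    u = np.stack([np.cos(azimuth_rad) * np.ones_like(beta_rad),
                  np.zeros_like(beta_rad),
                  np.sin(azimuth_rad) * np.ones_like(beta_rad)], axis=-1)
    down = np.array([0.0, -1.0, 0.0])
    return (np.cos(beta_rad)[..., None] * down
            + np.sin(beta_rad)[..., None] * u)


_REST_DIR = np.array([0.0, -1.0, 0.0])
_TWIST_GRID = np.linspace(-np.pi, np.pi, 144, endpoint=False)


def _direction_to_shoulder_angles(d: np.ndarray, sc_fb: float, sc_ud: float,
                                  side_sign: float,
                                  prev: Optional[Tuple[float, float, float]]
                                  = None) -> Tuple[float, float, float]:
    """Shoulder Euler angles placing the straight arm along direction d.

    The girdle rotation (applied before the shoulder in the chain) is
    removed first so the composed chain reproduces d exactly.  With the
    distal joints at zero the arm markers are invariant to axial twist
    about d, so the twist is a free parameter: it is chosen on a grid to
    keep the stored angles inside the anatomical limit table while
    staying continuous with the previous frame's choice.
    """
    from .kinematics import DEFAULT_LIMITS_DEG
    r_sc = (Rotation.from_euler("z", side_sign * sc_fb)
            * Rotation.from_euler("y", side_sign * sc_ud))
    d_local = r_sc.inv().apply(d)
    axis = np.cross(_REST_DIR, d_local)
    na = np.linalg.norm(axis)
    dot = float(np.clip(np.dot(_REST_DIR, d_local), -1.0, 1.0))
    if na < 1e-12:
        g0 = Rotation.identity() if dot > 0 else Rotation.from_rotvec(
            [0.0, 0.0, np.pi])
    else:
        g0 = Rotation.from_rotvec(axis / na * math.acos(dot))
    twists = Rotation.from_rotvec(np.outer(_TWIST_GRID, _REST_DIR))
    import warnings as _warnings
    with _warnings.catch_warnings():
        # gimbal-locked grid entries get a zeroed third angle, which is a
        # valid member of the twist family; no information is lost
        _warnings.simplefilter("ignore", UserWarning)
        eul = (g0 * twists).as_euler("XYZ")      # (n, 3)
    stored = np.column_stack([-eul[:, 0], side_sign * eul[:, 1],
                              side_sign * eul[:, 2]])
    lims = np.radians(np.array([DEFAULT_LIMITS_DEG[n]
                                for n in ("sh_x", "sh_y", "sh_z")]))
    viol = (np.maximum(lims[:, 0] - stored, 0.0)
            + np.maximum(stored - lims[:, 1], 0.0)).sum(axis=1)
    cost = 100.0 * viol
    if prev is not None:
        cost = cost + np.abs(stored - np.asarray(prev)).sum(axis=1)
    else:
        cost = cost + np.abs(stored).sum(axis=1)  # prefer small angles
    best = int(np.argmin(cost))
    return tuple(float(v) for v in stored[best])


def _tremor_tracks(rng: np.random.Generator, n: int, fps: float,
                   amp_deg: float, band: Tuple[float, float],
                   n_channels: int) -> np.ndarray:
    """Band-limited angle noise, std scaled to amp_deg, in radians."""
    if amp_deg <= 0 or n < 16:
        return np.zeros((n, n_channels))
    lo, hi = band
    nyq = fps / 2.0
    hi = min(hi, 0.9 * nyq)
    lo = min(lo, 0.5 * hi)
    white = rng.standard_normal((n, n_channels))
    sos = sp_signal.butter(2, [lo, hi], btype="band", fs=fps, output="sos")
    shaped = sp_signal.sosfiltfilt(sos, white, axis=0)
    std = shaped.std(axis=0)
    std[std < 1e-12] = 1.0
    shaped = shaped / std * math.radians(amp_deg)
    return shaped


@dataclass
class SimulationResult:
    """Ground truth of one simulated action performance."""

    action: ProtocolAction
    impairment: ImpairmentSpec
    times: np.ndarray
    angles: List[JointAngles]
    frames: List[SkeletonFrame]
    side: str = "right"

    @property
    def score(self) -> float:
        return self.impairment.score


def generate_trajectory(action, impairment: ImpairmentSpec = ImpairmentSpec(),
                        fps: float = 30.0, seed: int = 0,
                        side: str = "right",
                        right: Optional[ArmModel] = None,
                        left: Optional[ArmModel] = None) -> SimulationResult:
    """Ground-truth joint-angle trajectory + model frames for one action.

    The elevation (or reach) profile is scaled by the impairment's
    rom_scale, tremor is added in joint-angle space, and the whole
    performance is time-dilated by the slowness factor.  The returned
    frames are the forward-kinematics images of the angle sequence.
    """
    if isinstance(action, str):
        action = get_action(action)
    if fps <= 0:
        raise ValueError("fps must be positive")
    right = right or ArmModel(side="right")
    left = left or ArmModel(side="left")
    rng = np.random.default_rng(seed)
    duration = action.duration_s * impairment.slowness
    n = max(int(round(duration * fps)), 2)
    times = np.arange(n) / fps
    phase = times / duration  # 0..1

    side_sign = 1.0 if side == "right" else -1.0
    arm_angles = np.zeros((n, 9))

    if action.kind == "reachable":
        amp = math.radians(action.sweep_amplitude_deg) * impairment.rom_scale
        sweep = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # 0->amp->0
        if action.id.startswith("RW-V"):
            beta = sweep
            azim = np.full(n, math.radians(action.azimuth_deg))
        else:  # horizontal sweep at fixed elevation
            beta = np.full(n, math.radians(action.elevation_deg))
            azim = sweep
        dirs = _sweep_direction(beta, azim)
        elev_deg = np.degrees(beta)
        prev = None
        for i in range(n):
            fb, ud = scapulohumeral_rhythm(elev_deg[i])
            sc_fb, sc_ud = math.radians(fb), math.radians(ud)
            prev = _direction_to_shoulder_angles(
                dirs[i], sc_fb, sc_ud, side_sign, prev=prev)
            arm_angles[i, :5] = (sc_fb, sc_ud) + prev
        # arm straight: elbow/wrist/hand stay zero
    else:
        target = np.radians(np.asarray(action.target_angles_deg, float))
        target = target * impairment.rom_scale
        # out-and-back minimum-jerk reach
        s = np.where(phase <= 0.5, _min_jerk(2 * phase),
                     _min_jerk(2 * (1 - phase)))
        arm_angles[:, 2:9] = s[:, None] * target[None, :]

    tremor = _tremor_tracks(rng, n, fps, impairment.tremor_amp_deg,
                            impairment.tremor_band_hz, 4)
    arm_angles[:, 2:6] += tremor  # shoulder (3) + elbow

    angles_seq: List[JointAngles] = []
    frames: List[SkeletonFrame] = []
    for i in range(n):
        ja = JointAngles()
        if side == "right":
            ja.right = arm_angles[i]
        else:
            ja.left = arm_angles[i]
        angles_seq.append(ja)
        f = forward_kinematics(ja, right, left, timestamp=float(times[i]))
        frames.append(f)
    return SimulationResult(action=action, impairment=impairment,
                            times=times, angles=angles_seq, frames=frames,
                            side=side)


# --- rendering to device views ------------------------------------------

#: Static standing-pose template for non-upper-limb device joints,
#: world frame relative to the neck origin.  Exists only so emitted
#: device frames are format-complete.
_BODY_TEMPLATE: Dict[str, np.ndarray] = {
    "PELVIS": np.array([0.0, -0.50, 0.0]),
    "SPINE_NAVAL": np.array([0.0, -0.35, 0.0]),
    "SPINE_CHEST": np.array([0.0, -0.20, 0.0]),
    "CLAVICLE_LEFT": np.array([-0.05, -0.02, 0.0]),
    "CLAVICLE_RIGHT": np.array([0.05, -0.02, 0.0]),
    "HIP_LEFT": np.array([-0.10, -0.50, 0.0]),
    "KNEE_LEFT": np.array([-0.10, -0.95, 0.0]),
    "ANKLE_LEFT": np.array([-0.10, -1.35, 0.0]),
    "FOOT_LEFT": np.array([-0.10, -1.40, 0.10]),
    "HIP_RIGHT": np.array([0.10, -0.50, 0.0]),
    "KNEE_RIGHT": np.array([0.10, -0.95, 0.0]),
    "ANKLE_RIGHT": np.array([0.10, -1.35, 0.0]),
    "FOOT_RIGHT": np.array([0.10, -1.40, 0.10]),
    "HEAD": np.array([0.0, 0.15, 0.0]),
    "NOSE": np.array([0.0, 0.18, 0.10]),
    "EYE_LEFT": np.array([-0.03, 0.20, 0.08]),
    "EAR_LEFT": np.array([-0.07, 0.17, 0.0]),
    "EYE_RIGHT": np.array([0.03, 0.20, 0.08]),
    "EAR_RIGHT": np.array([0.07, 0.17, 0.0]),
}

_DEVICE_TO_MODEL = {v: k for k, v in MODEL_TO_DEVICE.items()}


def _device_world_frame(model_frame: SkeletonFrame) -> SkeletonFrame:
    """Expand an 11-marker model frame to the 32-joint device layout."""
    tor = model_frame.position("TOR")
    joints: Dict[str, np.ndarray] = {}
    conf: Dict[str, float] = {}
    for dj in DEVICE_JOINTS:
        if dj in _DEVICE_TO_MODEL:
            m = _DEVICE_TO_MODEL[dj]
            joints[dj] = model_frame.position(m).copy()
            conf[dj] = model_frame.confidence.get(m, 1.0)
        elif dj == "THUMB_LEFT":
            joints[dj] = model_frame.position("LHAN") + np.array([-0.03, 0, 0.03])
            conf[dj] = 1.0
        elif dj == "THUMB_RIGHT":
            joints[dj] = model_frame.position("RHAN") + np.array([0.03, 0, 0.03])
            conf[dj] = 1.0
        else:
            joints[dj] = tor + _BODY_TEMPLATE[dj]
            conf[dj] = 1.0
    return SkeletonFrame(timestamp=model_frame.timestamp, joints=joints,
                         confidence=conf)


def _render_one(world_frames: Sequence[SkeletonFrame], cam: CameraSpec,
                rng: np.random.Generator) -> List[SkeletonFrame]:
    w2c = cam.world_to_camera
    out = []
    for f in world_frames:
        tor = f.position("NECK")
        view_dir = cam.pose.translation - tor
        view_dir = view_dir / np.linalg.norm(view_dir)
        joints: Dict[str, np.ndarray] = {}
        conf: Dict[str, float] = {}
        for name, p in f.joints.items():
            occluded = (cam.occlusion_enabled
                        and float(np.dot(p - tor, view_dir))
                        < -cam.occlusion_margin_m)
            dropped = cam.dropout_prob > 0 and rng.random() < cam.dropout_prob
            if occluded or dropped:
                joints[name] = np.zeros(3)
                conf[name] = 0.0
            else:
                pc = w2c.apply(p)
                if cam.noise_sd_m > 0:
                    pc = pc + rng.normal(0.0, cam.noise_sd_m, 3)
                joints[name] = pc
                conf[name] = f.confidence.get(name, 1.0)
        out.append(SkeletonFrame(timestamp=f.timestamp, joints=joints,
                                 confidence=conf))
    return out


def render_views(frames: Sequence[SkeletonFrame], cam_a: CameraSpec,
                 cam_b: CameraSpec, seed: int = 0
                 ) -> Tuple[List[SkeletonFrame], List[SkeletonFrame]]:
    """Render model frames to two 32-joint device streams.

    Each stream expresses positions in its own camera frame; occluded or
    dropped joints carry confidence 0 and the (0,0,0) sentinel.  A fixed
    seed reproduces both streams bit-identically.
    """
    world = [_device_world_frame(f) for f in frames]
    rng = np.random.default_rng(seed)
    stream_a = _render_one(world, cam_a, rng)
    stream_b = _render_one(world, cam_b, rng)
    return stream_a, stream_b


# --- assessment dataset --------------------------------------------------

def normalize_sequence(frames: Sequence[SkeletonFrame],
                       arm_length: float) -> np.ndarray:
    """(T, 11, 3) network input: centered at TOR, arm-length units."""
    arr = np.stack([f.marker_array(MODEL_MARKERS) for f in frames])
    arr = arr - arr[:, 0:1, :]
    return arr / arm_length


def make_assessment_dataset(n_samples: int, seed: int = 0,
                            fps: float = 12.0, n_frames: int = 48,
                            noise_sd_m: float = 0.003,
                            actions: Optional[Sequence[str]] = None,
                            side: str = "right"):
    """Synthetic (sequence, score, action) triples for score regression.

    Samples draw an action uniformly from the protocol, a rom_scale in
    [0.3, 1] and a tremor amplitude in [0, 5] deg; inputs are ground
    truth marker tracks with additive Gaussian noise, normalized to the
    TOR-centered arm-length frame, resampled to ``n_frames``.
    """
    rng = np.random.default_rng(seed)
    ids = list(actions) if actions else [a.id for a in PROTOCOL]
    arm = ArmModel(side=side)
    arm_len = arm.lengths.arm_length
    xs, ys, labels = [], [], []
    for i in range(n_samples):
        aid = ids[int(rng.integers(len(ids)))]
        imp = ImpairmentSpec(rom_scale=float(rng.uniform(0.3, 1.0)),
                             tremor_amp_deg=float(rng.uniform(0.0, 5.0)))
        sim = generate_trajectory(aid, imp, fps=fps,
                                  seed=int(rng.integers(2**31)), side=side)
        x = normalize_sequence(sim.frames, arm_len)
        x = resample_time(x, n_frames)
        if noise_sd_m > 0:
            x = x + rng.normal(0.0, noise_sd_m / arm_len, x.shape)
        xs.append(x.astype(np.float64))
        ys.append(sim.score)
        labels.append(aid)
    return np.stack(xs), np.array(ys), labels


def resample_time(x: np.ndarray, n_frames: int) -> np.ndarray:
    """Linear resampling of a (T, nodes, 3) array to a fixed length."""
    t_old = np.linspace(0.0, 1.0, x.shape[0])
    t_new = np.linspace(0.0, 1.0, n_frames)
    out = np.empty((n_frames,) + x.shape[1:])
    for j in range(x.shape[1]):
        for k in range(x.shape[2]):
            out[:, j, k] = np.interp(t_new, t_old, x[:, j, k])
    return out
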