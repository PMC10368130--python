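"""9-DOF-per-arm rigid-body model of the upper limb.

Each arm is a serial chain hanging off the torso: 2 DOF at the
sternoclavicular joint (shoulder-girdle), 3 at the glenohumeral shoulder,
1 at the elbow, 2 at the wrist and 1 at the hand — nine rotational
parameters per arm.  The torso itself carries a free rigid pose (three
rotations plus a translation) whose origin is the neck.  Forward
kinematics chains homogeneous transforms segment by segment and reads off
the 11 marker positions; the scapulohumeral rhythm couples girdle angles
to humeral elevation through piecewise-linear regression functions.

Rest pose: arms hanging at the sides, each arm's long axis along -y, the
shoulder offset from the neck along +/-x.  All internal angles are radians;
the rhythm functions take and return degrees because their regression
coefficients are degree-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .skeleton import MODEL_MARKERS, SkeletonFrame

__all__ = [
    "SegmentLengths",
    "JointAngles",
    "ArmModel",
    "ANGLE_NAMES",
    "DEFAULT_LIMITS_DEG",
    "rot",
    "hom",
    "forward_kinematics",
    "forward_kinematics_batch",
    "scapulohumeral_rhythm",
    "estimate_segment_lengths",
    "JointLimitError",
]

ANGLE_NAMES: Tuple[str, ...] = (
    "sc_fb", "sc_ud",          # sternoclavicular Rz, Ry
    "sh_x", "sh_y", "sh_z",    # glenohumeral Rx, Ry, Rz
    "elb_x",                   # elbow Rx
    "wr_x", "wr_z",            # wrist Rx, Rz
    "hand_x",                  # hand Rx
)

#: Default anatomical limits, degrees, per angle.  Config-overridable.
DEFAULT_LIMITS_DEG: Dict[str, Tuple[float, float]] = {
    "sc_fb": (-30, 30), "sc_ud": (-15, 60),
    "sh_x": (-60, 180), "sh_y": (-90, 90), "sh_z": (-90, 130),
    "elb_x": (0, 150),
    "wr_x": (-70, 80), "wr_z": (-20, 35),
    "hand_x": (-45, 45),
}


class JointLimitError(ValueError):
    """One or more joint angles violate their anatomical limits."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(f"{n}={np.degrees(v):.1f}deg outside [{lo},{hi}]deg"
                        for n, v, (lo, hi) in self.violations)
        super().__init__(f"joint limit violation: {msg}")


def rot(axis: str, angle) -> np.ndarray:
    """Elementary rotation matrix about a coordinate axis.

    ``angle`` may be a scalar or an array; the result gains the angle's
    leading dimensions, ending in (3, 3).
    """
    a = np.asarray(angle, dtype=float)
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    if axis == "x":
        rows = [[o, z, z], [z, c, -s], [z, s, c]]
    elif axis == "y":
        rows = [[c, z, s], [z, o, z], [-s, z, c]]
    elif axis == "z":
        rows = [[c, -s, z], [s, c, z], [z, z, o]]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    m = np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)
    return m


def hom(rotation: np.ndarray, translation) -> np.ndarray:
    """4x4 homogeneous transform(s) from rotation(s) and translation(s)."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    batch = np.broadcast_shapes(rotation.shape[:-2], translation.shape[:-1])
    t = np.zeros(batch + (4, 4))
    t[..., :3, :3] = rotation
    t[..., :3, 3] = translation
    t[..., 3, 3] = 1.0
    return t


@dataclass(frozen=True)
class SegmentLengths:
    """Segment lengths of one arm chain, meters.

    LSCAP: shoulder girdle (neck to shoulder); LUA: upper arm; LLA:
    forearm; LH: wrist to palm; LT: palm to hand tip.
    """

    LSCAP: float = 0.18
    LUA: float = 0.30
    LLA: float = 0.25
    LH: float = 0.08
    LT: float = 0.10

    def __post_init__(self):
        for name in ("LSCAP", "LUA", "LLA", "LH", "LT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name} must be positive")

    @property
    def arm_length(self) -> float:
        """Shoulder-to-tip reach: LUA + LLA + LH + LT."""
        return self.LUA + self.LLA + self.LH + self.LT

    def as_dict(self) -> Dict[str, float]:
        return {n: getattr(self, n) for n in ("LSCAP", "LUA", "LLA", "LH", "LT")}


@dataclass(frozen=True)
class ArmModel:
    """Chain definition for one arm: lengths, local offsets, limits.

    Local joint offsets are expressed in the parent segment's frame along
    the rest-pose axis; their norms equal the corresponding segment
    lengths by construction.
    """

    side: str = "right"
    lengths: SegmentLengths = field(default_factory=SegmentLengths)
    limits_deg: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS_DEG))

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def mirror_sign(self) -> float:
        """+1 for the right arm, -1 for the left (y/z rotations negate)."""
        return 1.0 if self.side == "right" else -1.0

    @property
    def offsets(self) -> Dict[str, np.ndarray]:
        s = self.mirror_sign
        L = self.lengths
        return {
            "q_shoulder": np.array([s * L.LSCAP, 0.0, 0.0]),
            "q_elbow": np.array([0.0, -L.LUA, 0.0]),
            "q_wrist": np.array([0.0, -L.LLA, 0.0]),
            "q_hand": np.array([0.0, -L.LH, 0.0]),
            "q_tip": np.array([0.0, -L.LT, 0.0]),
        }

    def bounds_rad(self) -> np.ndarray:
        """(9, 2) per-angle bounds in radians, chain order."""
        return np.radians(np.array([self.limits_deg[n] for n in ANGLE_NAMES]))

    @classmethod
    def from_config(cls, path_or_dict, side: Optional[str] = None
                    ) -> "ArmModel":
        """Build from a YAML/JSON config with `lengths` and `limits_deg`.

        An explicit ``side`` argument wins over the config's own entry,
        so one file can configure both arms.  Unlisted entries keep
        their defaults; the derived local offsets always follow the
        segment lengths along the rest-pose axis.
        """
        if isinstance(path_or_dict, dict):
            cfg = path_or_dict
        else:
            import yaml
            from pathlib import Path
            cfg = yaml.safe_load(Path(path_or_dict).read_text()) or {}
        lengths = SegmentLengths(**cfg.get("lengths", {}))
        limits = dict(DEFAULT_LIMITS_DEG)
        for name, pair in cfg.get("limits_deg", {}).items():
            if name not in limits:
                raise KeyError(f"unknown joint angle {name!r}")
            limits[name] = (float(pair[0]), float(pair[1]))
        return cls(side=side or cfg.get("side", "right"), lengths=lengths,
                   limits_deg=limits)

    def to_config(self) -> Dict:
        return {"side": self.side, "lengths": self.lengths.as_dict(),
                "limits_deg": {k: list(v)
                               for k, v in self.limits_deg.items()},
                "offsets": {k: v.tolist() for k, v in self.offsets.items()}}

    def check_limits(self, angles: np.ndarray) -> None:
        angles = np.asarray(angles, dtype=float)
        bad = []
        for i, name in enumerate(ANGLE_NAMES):
            lo, hi = self.limits_deg[name]
            deg = np.degrees(angles[i])
            if deg < lo - 1e-9 or deg > hi + 1e-9:
                bad.append((name, angles[i], (lo, hi)))
        if bad:
            raise JointLimitError(bad)


@dataclass
class JointAngles:
    """Full posture: 9 angles per arm plus the torso rigid pose.

    ``right``/``left`` are length-9 arrays in :data:`ANGLE_NAMES` order
    (radians); the torso pose is an intrinsic x-y-z rotation triple plus a
    translation of the neck origin.
    """

    right: np.ndarray = field(default_factory=lambda: np.zeros(9))
    left: np.ndarray = field(default_factory=lambda: np.zeros(9))
    torso_rot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torso_t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.right = np.asarray(self.right, dtype=float).reshape(9)
        self.left = np.asarray(self.left, dtype=float).reshape(9)
        self.torso_rot = np.asarray(self.torso_rot, dtype=float).reshape(3)
        self.torso_t = np.asarray(self.torso_t, dtype=float).reshape(3)

    def copy(self) -> "JointAngles":
        return JointAngles(self.right.copy(), self.left.copy(),
                           self.torso_rot.copy(), self.torso_t.copy())


def _torso_transform(torso_rot: np.ndarray, torso_t) -> np.ndarray:
    r = rot("x", torso_rot[..., 0]) @ rot("y", torso_rot[..., 1]) \
        @ rot("z", torso_rot[..., 2])
    return hom(r, torso_t)


def _arm_marker_positions(angles: np.ndarray, model: ArmModel,
                          t_world_torso: np.ndarray) -> np.ndarray:
    """Positions of the 5 arm markers (shoulder..tip) for one arm.

    ``angles`` may be (..., 9); markers come back as (..., 5, 3).  The
    left arm uses the same angle values but mirrored: rotations about the
    y and z axes change sign and the shoulder offset flips in x, so a
    mirrored posture reflects the right arm through the sagittal plane.

    x-axis angles are stored flexion-positive: a positive sh_x/elb_x/
    wr_x/hand_x carries the limb toward the subject's front (+z), which
    in this right-handed frame is a negative rotation about +x.  This
    makes the anatomical limit table (elbow 0..150 deg of flexion, etc.)
    read naturally.
    """
    a = np.asarray(angles, dtype=float)
    s = model.mirror_sign
    off = model.offsets

    # Sternoclavicular: Rz then Ry, rotating about the neck origin.
    t_sc = hom(rot("z", s * a[..., 0]) @ rot("y", s * a[..., 1]),
               np.zeros(a.shape[:-1] + (3,)))
    # Shoulder: Rx Ry Rz at the shoulder joint center.
    t_sh = hom(rot("x", -a[..., 2]) @ rot("y", s * a[..., 3])
               @ rot("z", s * a[..., 4]), off["q_shoulder"])
    # Elbow: Rx.
    t_el = hom(rot("x", -a[..., 5]), off["q_elbow"])
    # Wrist: Rx Rz.
    t_wr = hom(rot("x", -a[..., 6]) @ rot("z", s * a[..., 7]), off["q_wrist"])
    # Hand: Rx.
    t_ha = hom(rot("x", -a[..., 8]), off["q_hand"])

    w_sc = t_world_torso @ t_sc
    w_ua = w_sc @ t_sh
    w_fa = w_ua @ t_el
    w_ha = w_fa @ t_wr
    w_tip = w_ha @ t_ha

    def apply(t, q):
        return (t[..., :3, :3] @ np.asarray(q)) + t[..., :3, 3]

    p_sho = apply(w_sc, off["q_shoulder"])
    p_elb = apply(w_ua, off["q_elbow"])
    p_wri = apply(w_fa, off["q_wrist"])
    p_han = apply(w_ha, off["q_hand"])
    p_tip = apply(w_tip, off["q_tip"])
    return np.stack([p_sho, p_elb, p_wri, p_han, p_tip], axis=-2)


def forward_kinematics(angles: JointAngles,
                       right: ArmModel,
                       left: ArmModel,
                       check_limits: bool = False,
                       timestamp: float = 0.0) -> SkeletonFrame:
    """Map a full posture to the 11 model marker positions.

    Returns a model :class:`SkeletonFrame` with all confidences 1.
    Consecutive-marker distances equal the model segment lengths exactly —
    the chain construction conserves bone length for any angles.
    """
    if check_limits:
        right.check_limits(angles.right)
        left.check_limits(angles.left)
    t_wt = _torso_transform(angles.torso_rot, angles.torso_t)
    p_tor = t_wt[:3, 3].copy()
    pr = _arm_marker_positions(angles.right, right, t_wt)
    pl = _arm_marker_positions(angles.left, left, t_wt)
    names_r = ("RSHO", "RELB", "RWRI", "RHAN", "RTIP")
    names_l = ("LSHO", "LELB", "LWRI", "LHAN", "LTIP")
    joints = {"TOR": p_tor}
    joints.update({n: pr[i] for i, n in enumerate(names_r)})
    joints.update({n: pl[i] for i, n in enumerate(names_l)})
    return SkeletonFrame(timestamp=timestamp, joints=joints)


def forward_kinematics_batch(angles: np.ndarray, model: ArmModel,
                             t_world_torso: Optional[np.ndarray] = None
                             ) -> np.ndarray:
    """Vectorized single-arm FK: (..., 9) angles -> (..., 5, 3) markers.

    The swarm optimizer evaluates whole particle populations through this
    path; ``t_world_torso`` defaults to the identity.
    """
    if t_world_torso is None:
        t_world_torso = np.eye(4)
    return _arm_marker_positions(np.asarray(angles, float), model,
                                 t_world_torso)


def scapulohumeral_rhythm(beta_deg: float) -> Tuple[float, float]:
    """Girdle angles coupled to humeral elevation (degrees in, degrees out).

    Piecewise-linear regression of the forward/backward extension angle
    theta_fb and the upward/downward angle theta_ud of the
    sternoclavicular joint against the lift angle beta:

        theta_fb = -0.35*beta         (beta < 0)
                 = 0                  (0 <= beta <= 70)
                 = -0.22*beta + 15.4  (beta > 70)

        theta_ud = -0.3*beta          (beta < 0)
                 = 0                  (0 <= beta <= 30)
                 = 0.36*beta - 10.8   (beta > 30)

    Both functions are continuous at their breakpoints.
    """
    beta = float(beta_deg)
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta < 0:
        theta_fb = -0.35 * beta
    elif beta <= 70:
        theta_fb = 0.0
    else:
        theta_fb = -0.22 * beta + 15.4
    if beta < 0:
        theta_ud = -0.3 * beta
    elif beta <= 30:
        theta_ud = 0.0
    else:
        theta_ud = 0.36 * beta - 10.8
    return theta_fb, theta_ud


_SEGMENTS = (
    ("TOR", "RSHO", "LSCAP"), ("RSHO", "RELB", "LUA"),
    ("RELB", "RWRI", "LLA"), ("RWRI", "RHAN", "LH"), ("RHAN", "RTIP", "LT"),
)


def estimate_segment_lengths(frames: Sequence[SkeletonFrame],
                             side: str = "right",
                             min_frames: int = 10) -> SegmentLengths:
    """Median inter-marker distances over fully confident frames.

    Requires at least ``min_frames`` frames in which every marker of the
    requested arm (plus TOR) has nonzero confidence.
    """
    prefix = "R" if side == "right" else "L"
    needed = ["TOR"] + [prefix + m for m in ("SHO", "ELB", "WRI", "HAN", "TIP")]
    dists = {name: [] for _, _, name in _SEGMENTS}
    n_ok = 0
    for f in frames:
        if any(m not in f.joints or f.confidence.get(m, 0) <= 0
               for m in needed):
            continue
        n_ok += 1
        for a, b, name in _SEGMENTS:
            pa = f.position(a.replace("R", prefix, 1) if a != "TOR" else a)
            pb = f.position(b.replace("R", prefix, 1))
            dists[name].append(float(np.linalg.norm(pa - pb)))
    if n_ok < min_frames:
        raise ValueError(
            f"need >= {min_frames} fully confident frames, got {n_ok}")
    return SegmentLengths(**{k: float(np.median(v)) for k, v in dists.items()})
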