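"""Extrinsic calibration and two-stream fusion.

The two depth cameras are calibrated from 3-D point correspondences
(checkerboard corners expressed in each camera's frame) with the
least-squares rigid registration of Kabsch/Umeyama; synchronized frames
are then fused joint-by-joint by confidence-weighted averaging, falling
back to whichever camera sees a joint when the other reports it occluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .skeleton import SkeletonFrame

__all__ = [
    "RigidTransform",
    "DegenerateGeometryError",
    "SyncError",
    "estimate_rigid_transform",
    "fuse_frames",
    "fuse_streams",
]


class DegenerateGeometryError(ValueError):
    """Too few or geometrically degenerate correspondences."""


class SyncError(ValueError):
    """Frames are not synchronized within tolerance."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: rotation (det +1) plus translation, meters."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def to_json(self) -> str:
        return json.dumps({
            "rotation": self.rotation.reshape(-1).tolist(),
            "translation": self.translation.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.array(d["rotation"]).reshape(3, 3),
                   np.array(d["translation"]))


def estimate_rigid_transform(points_a: np.ndarray,
                             points_b: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform T with T(a_i) ~ b_i (Kabsch).

    Requires at least 3 non-collinear correspondences; the SVD solution
    is constrained to a proper rotation (no reflection).
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("correspondence lists must have equal lengths")
    if a.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need >= 3 correspondences, got {a.shape[0]}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear (or coincident) point sets leave rotation about the line free
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12) or sv[0] < 1e-12:
        raise DegenerateGeometryError("correspondences are collinear")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    return RigidTransform(r, t)


#: Sentinel position written for joints no camera saw.
OCCLUDED_SENTINEL = np.zeros(3)


def fuse_frames(master: SkeletonFrame,
                subordinate: SkeletonFrame,
                t_sub_to_master: RigidTransform,
                sync_tol_s: float = 0.005) -> SkeletonFrame:
    """Fuse one synchronized frame pair into the master camera's frame.

    Per joint: confidence-weighted average of the master position and the
    transformed subordinate position; when one confidence is 0 the other
    position is taken verbatim; when both are 0 the joint keeps the
    occlusion sentinel with confidence 0.  Fused confidence is the
    maximum of the two.
    """
    if abs(master.timestamp - subordinate.timestamp) > sync_tol_s:
        raise SyncError(
            f"timestamps {master.timestamp:.4f}s / "
            f"{subordinate.timestamp:.4f}s differ beyond {sync_tol_s}s")
    joints: Dict[str, np.ndarray] = {}
    conf: Dict[str, float] = {}
    for name in master.joints:
        pm = master.joints[name]
        cm = master.confidence.get(name, 0.0)
        if name in subordinate.joints:
            ps = t_sub_to_master.apply(subordinate.joints[name])
            cs = subordinate.confidence.get(name, 0.0)
        else:
            ps, cs = pm, 0.0
        if cm <= 0 and cs <= 0:
            joints[name] = OCCLUDED_SENTINEL.copy()
            conf[name] = 0.0
        elif cs <= 0:
            joints[name] = pm.copy()
            conf[name] = cm
        elif cm <= 0:
            joints[name] = ps.copy()
            conf[name] = cs
        else:
            w = cm / (cm + cs)
            joints[name] = w * pm + (1.0 - w) * ps
            conf[name] = max(cm, cs)
    return SkeletonFrame(timestamp=master.timestamp, joints=joints,
                         confidence=conf)


def fuse_streams(master: Sequence[SkeletonFrame],
                 subordinate: Sequence[SkeletonFrame],
                 t_sub_to_master: RigidTransform,
                 sync_tol_s: float = 0.005) -> list:
    """Fuse two streams by nearest-timestamp pairing.

    Each master frame is paired with the subordinate frame closest in
    time; pairs beyond the sync tolerance raise :class:`SyncError`.
    """
    if not master or not subordinate:
        raise ValueError("streams must be non-empty")
    sub_times = np.array([f.timestamp for f in subordinate])
    out = []
    for mf in master:
        j = int(np.argmin(np.abs(sub_times - mf.timestamp)))
        out.append(fuse_frames(mf, subordinate[j], t_sub_to_master,
                               sync_tol_s))
    return out
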