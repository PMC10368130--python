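"""Joint catalogues, skeleton frames and the upper-limb marker graph.

Two frame vocabularies coexist: the 32-joint *device* view emitted by an
Azure-Kinect-style body tracker, and the 11-marker *model* view used by the
rigid upper-limb model (torso/neck plus five markers per arm).  Conversions
between the two, and the tree graph connecting the 11 markers, live here.

Coordinate convention: right-handed, x to the subject's right, y up,
z toward the camera; all positions in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "DEVICE_JOINTS",
    "MODEL_MARKERS",
    "MODEL_TO_DEVICE",
    "SkeletonFrame",
    "LimbGraph",
    "MissingJointError",
    "to_model_frame",
    "build_limb_graph",
]

#: The 32 device joints, Azure-Kinect-style naming/order.
DEVICE_JOINTS: Tuple[str, ...] = (
    "PELVIS", "SPINE_NAVAL", "SPINE_CHEST", "NECK",
    "CLAVICLE_LEFT", "SHOULDER_LEFT", "ELBOW_LEFT", "WRIST_LEFT",
    "HAND_LEFT", "HANDTIP_LEFT", "THUMB_LEFT",
    "CLAVICLE_RIGHT", "SHOULDER_RIGHT", "ELBOW_RIGHT", "WRIST_RIGHT",
    "HAND_RIGHT", "HANDTIP_RIGHT", "THUMB_RIGHT",
    "HIP_LEFT", "KNEE_LEFT", "ANKLE_LEFT", "FOOT_LEFT",
    "HIP_RIGHT", "KNEE_RIGHT", "ANKLE_RIGHT", "FOOT_RIGHT",
    "HEAD", "NOSE", "EYE_LEFT", "EAR_LEFT", "EYE_RIGHT", "EAR_RIGHT",
)

#: The 11 model markers: torso plus the five-marker chain of each arm.
MODEL_MARKERS: Tuple[str, ...] = (
    "TOR",
    "RSHO", "RELB", "RWRI", "RHAN", "RTIP",
    "LSHO", "LELB", "LWRI", "LHAN", "LTIP",
)

#: Frozen model-marker -> device-joint map.  TOR is the neck joint: the
#: rigid model's base frame sits at the neck.  The TIP markers are the
#: device hand-tip joints.
MODEL_TO_DEVICE: Dict[str, str] = {
    "TOR": "NECK",
    "RSHO": "SHOULDER_RIGHT",
    "RELB": "ELBOW_RIGHT",
    "RWRI": "WRIST_RIGHT",
    "RHAN": "HAND_RIGHT",
    "RTIP": "HANDTIP_RIGHT",
    "LSHO": "SHOULDER_LEFT",
    "LELB": "ELBOW_LEFT",
    "LWRI": "WRIST_LEFT",
    "LHAN": "HAND_LEFT",
    "LTIP": "HANDTIP_LEFT",
}

assert len(MODEL_MARKERS) == 11
assert set(MODEL_TO_DEVICE) == set(MODEL_MARKERS)


class MissingJointError(KeyError):
    """A frame lacks a joint required by the requested conversion."""

    def __init__(self, joint: str):
        super().__init__(joint)
        self.joint = joint

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"frame is missing required joint {self.joint!r}"


@dataclass
class SkeletonFrame:
    """One timestamped set of 3-D joint positions with confidences.

    ``joints`` maps a joint name to a length-3 position (meters);
    ``confidence`` maps the same names into [0, 1], with 0 marking an
    occluded or untracked joint.
    """

    timestamp: float
    joints: Dict[str, np.ndarray]
    confidence: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.joints = {k: np.asarray(v, dtype=float).reshape(3)
                       for k, v in self.joints.items()}
        for name in self.joints:
            self.confidence.setdefault(name, 1.0)

    def position(self, joint: str) -> np.ndarray:
        try:
            return self.joints[joint]
        except KeyError:
            raise MissingJointError(joint) from None

    @property
    def names(self) -> List[str]:
        return list(self.joints)

    def is_device_frame(self) -> bool:
        return set(DEVICE_JOINTS).issubset(self.joints)

    def is_model_frame(self) -> bool:
        return set(MODEL_MARKERS).issubset(self.joints)

    def marker_array(self, order: Sequence[str] = MODEL_MARKERS) -> np.ndarray:
        """Positions stacked as an (n, 3) array in the given name order."""
        return np.stack([self.position(n) for n in order])

    def confidence_array(self, order: Sequence[str] = MODEL_MARKERS) -> np.ndarray:
        return np.array([self.confidence.get(n, 0.0) for n in order])


def to_model_frame(frame: SkeletonFrame) -> SkeletonFrame:
    """Select the 11 model markers from a 32-joint device frame.

    Positions and confidences are carried over verbatim through the frozen
    marker->device map.  Raises :class:`MissingJointError` naming the first
    absent device joint.
    """
    joints: Dict[str, np.ndarray] = {}
    conf: Dict[str, float] = {}
    for marker in MODEL_MARKERS:
        device = MODEL_TO_DEVICE[marker]
        if device not in frame.joints:
            raise MissingJointError(device)
        joints[marker] = frame.joints[device].copy()
        conf[marker] = float(frame.confidence.get(device, 1.0))
    return SkeletonFrame(timestamp=frame.timestamp, joints=joints, confidence=conf)


# --- the 11-marker limb graph -------------------------------------------

#: 10 segments: torso->shoulder->elbow->wrist->hand->tip per arm.
_EDGES: Tuple[Tuple[str, str], ...] = (
    ("TOR", "RSHO"), ("RSHO", "RELB"), ("RELB", "RWRI"),
    ("RWRI", "RHAN"), ("RHAN", "RTIP"),
    ("TOR", "LSHO"), ("LSHO", "LELB"), ("LELB", "LWRI"),
    ("LWRI", "LHAN"), ("LHAN", "LTIP"),
)


@dataclass(frozen=True)
class LimbGraph:
    """The 11-node, 10-edge tree connecting the upper-limb markers."""

    nodes: Tuple[str, ...]
    edges: Tuple[Tuple[str, str], ...]

    @property
    def adjacency(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        a = np.zeros((len(self.nodes), len(self.nodes)))
        for u, v in self.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
        return a

    def degree(self, node: str) -> int:
        return sum(node in e for e in self.edges)


def build_limb_graph() -> LimbGraph:
    """Build the two-chain upper-limb tree rooted at the torso marker."""
    return LimbGraph(nodes=MODEL_MARKERS, edges=_EDGES)
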