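"""Skeleton CSV dialect and sidecar helpers.

One row per joint per frame:

    frame_index,timestamp_s,joint,x_m,y_m,z_m,confidence

UTF-8, '.' decimal separator, frames sorted by frame_index.  Every
writer also drops a JSON sidecar recording the producing command, the
seed and a hash of the configuration, so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .skeleton import SkeletonFrame

__all__ = ["read_skeleton_csv", "write_skeleton_csv", "write_sidecar",
           "ParseError"]

_COLUMNS = ["frame_index", "timestamp_s", "joint", "x_m", "y_m", "z_m",
            "confidence"]


class ParseError(ValueError):
    """Malformed skeleton CSV; carries the offending line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_skeleton_csv(frames: Sequence[SkeletonFrame], path) -> None:
    """Serialize frames in the documented dialect (stable joint order)."""
    rows = []
    for i, f in enumerate(frames):
        for name in f.joints:
            p = f.position(name)
            rows.append((i, f.timestamp, name, p[0], p[1], p[2],
                         f.confidence.get(name, 1.0)))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_skeleton_csv(path) -> List[SkeletonFrame]:
    """Parse the skeleton dialect back into frames.

    Raises :class:`ParseError` naming the first malformed line and
    rejects non-monotone frame timestamps.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header != _COLUMNS:
            raise ParseError(1, f"expected header {','.join(_COLUMNS)}")
        frames: Dict[int, SkeletonFrame] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != 7:
                raise ParseError(lineno,
                                 f"expected 7 fields, got {len(parts)}")
            try:
                idx = int(parts[0])
                ts = float(parts[1])
                joint = parts[2]
                xyz = np.array([float(parts[3]), float(parts[4]),
                                float(parts[5])])
                conf = float(parts[6])
            except ValueError as e:
                raise ParseError(lineno, str(e)) from None
            if idx not in frames:
                frames[idx] = SkeletonFrame(timestamp=ts, joints={},
                                            confidence={})
            frames[idx].joints[joint] = xyz
            frames[idx].confidence[joint] = conf
    ordered = [frames[i] for i in sorted(frames)]
    ts = [f.timestamp for f in ordered]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ParseError(0, "non-monotone timestamps across frames")
    return ordered


def write_sidecar(path, command: str, seed: Optional[int] = None,
                  config: Optional[dict] = None, **extra) -> None:
    """JSON sidecar next to an output file: provenance + config hash."""
    payload = {"command": command, "seed": seed}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        payload["config_hash"] = hashlib.sha256(
            blob.encode()).hexdigest()[:16]
        payload["config"] = config
    payload.update(extra)
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(payload, indent=1, default=str))
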