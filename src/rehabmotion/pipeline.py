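"""End-to-end pipeline: simulate -> fuse -> preprocess -> IK -> report.

One seeded run of the whole measurement-and-assessment chain on
synthetic data: an action performance is simulated and rendered to two
camera views, the cameras are calibrated from synthetic checkerboard
correspondences, the streams are fused, denoised, reconstructed through
the rigid-model CBPSO inverse kinematics, and the result is summarized
as a movement-quality score, a reachable-workspace envelope, an SNR
table and per-joint attention importance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import calibration, filters, ik, network, simulate, workspace
from .kinematics import ArmModel
from .skeleton import SkeletonFrame, to_model_frame

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with desk-scale defaults."""

    action: str = "RW-V90"
    rom_scale: float = 0.8
    tremor_amp_deg: float = 1.0
    fps: float = 15.0
    seed: int = 0
    camera_noise_sd_m: float = 0.004
    camera_dropout_prob: float = 0.1
    filter_spec: filters.FilterSpec = field(
        default_factory=lambda: filters.FilterSpec(sample_rate_hz=15.0))
    swarm: ik.SwarmConfig = field(default_factory=ik.SwarmConfig)
    net: network.NetConfig = field(default_factory=network.NetConfig)
    n_train_samples: int = 24
    train_epochs: int = 4
    train_lr: float = 0.005
    ik_stride: int = 1      # solve every k-th frame (speed knob)


def _checkerboard_world(n: int = 12) -> np.ndarray:
    xs = np.linspace(-0.3, 0.3, 4)
    ys = np.linspace(-0.2, 0.2, 3)
    pts = [(x, y, 0.6) for y in ys for x in xs]
    return np.asarray(pts[:n])


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[Path] = None) -> Dict:
    """Execute all stages with one seed; returns the report dict.

    Any stage failure propagates with the stage name prepended.
    """
    report: Dict = {"config": {
        "action": config.action, "rom_scale": config.rom_scale,
        "tremor_amp_deg": config.tremor_amp_deg, "fps": config.fps,
        "seed": config.seed}}
    stage = "simulate"
    try:
        imp = simulate.ImpairmentSpec(rom_scale=config.rom_scale,
                                      tremor_amp_deg=config.tremor_amp_deg)
        sim = simulate.generate_trajectory(config.action, imp,
                                           fps=config.fps, seed=config.seed)
        cam_a, cam_b = simulate.default_camera_pair(
            noise_sd_m=config.camera_noise_sd_m,
            dropout_prob=config.camera_dropout_prob)
        stream_a, stream_b = simulate.render_views(
            sim.frames, cam_a, cam_b, seed=config.seed + 1)

        stage = "calibrate"
        board = _checkerboard_world()
        pts_a = cam_a.world_to_camera.apply(board)
        pts_b = cam_b.world_to_camera.apply(board)
        t_b_to_a = calibration.estimate_rigid_transform(pts_b, pts_a)

        stage = "fuse"
        fused_cam = calibration.fuse_streams(stream_a, stream_b, t_b_to_a)
        # express in the world frame through the master camera pose
        fused = []
        for f in fused_cam:
            joints = {n: (cam_a.pose.apply(p)
                          if f.confidence.get(n, 0) > 0 else p)
                      for n, p in f.joints.items()}
            fused.append(SkeletonFrame(timestamp=f.timestamp, joints=joints,
                                       confidence=dict(f.confidence)))
        fused_model = [to_model_frame(f) for f in fused]

        stage = "preprocess"
        config.filter_spec.validate_strict()
        clean = filters.filter_stream(fused_model, config.filter_spec)

        stage = "ik"
        frames_ik = clean[::max(config.ik_stride, 1)]
        sides = ("right",) if sim.side == "right" else ("left",)
        sol = ik.solve_sequence(frames_ik, config.swarm, sides=sides)

        stage = "snr"
        truth = sim.frames[::max(config.ik_stride, 1)]
        snr_raw = filters.stream_snr_table(
            fused_model[::max(config.ik_stride, 1)], truth)
        snr_rec = filters.stream_snr_table(sol.frames, truth)
        report["snr"] = {"raw_vs_truth": snr_raw,
                         "reconstructed_vs_truth": snr_rec}

        stage = "workspace"
        prefix = "R" if sim.side == "right" else "L"
        hand = np.stack([f.position(prefix + "HAN") for f in sol.frames])
        sho = np.stack([f.position(prefix + "SHO") for f in sol.frames])
        arm_len = ArmModel(side=sim.side).lengths.arm_length
        try:
            env = workspace.compute_envelope(hand, sho, arm_len,
                                             side=sim.side)
            report["workspace"] = {
                "total_rsa": env.total_rsa,
                "quadrant_rsa": env.quadrant_rsa.tolist()}
        except ValueError as e:   # proximal reaches may not span a region
            report["workspace"] = {"total_rsa": 0.0,
                                   "quadrant_rsa": [0.0] * 4,
                                   "note": str(e)}

        stage = "assess"
        x_train, y_train, _ = simulate.make_assessment_dataset(
            config.n_train_samples, seed=config.seed + 2,
            n_frames=32, side=sim.side)
        net = network.build_network(config.net, seed=config.seed)
        history = network.train(net, x_train, y_train,
                                epochs=config.train_epochs,
                                lr=config.train_lr, seed=config.seed)
        seq = simulate.normalize_sequence(sol.frames, arm_len)
        seq = simulate.resample_time(seq, 32)
        score = float(network.predict(net, seq))
        report["assessment"] = {"score": score,
                                "score_label": sim.score,
                                "final_train_mse": history[-1]}

        stage = "importance"
        imp_map = network.joint_importance(net, {config.action: seq})
        report["importance"] = {
            a: v.tolist() for a, v in imp_map.items()}
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, default=float))
    return report
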