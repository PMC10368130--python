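# rehabmotion

Quantitative upper-limb rehabilitation assessment from marker-less motion
capture. The package implements, end to end and without hardware, a
posture-measurement and movement-scoring chain for stroke rehabilitation:

1. **Two-camera skeleton fusion.** Synthetic depth-camera body-tracking
   streams (32 joints per frame, two viewpoints 2 m apart at 90°) are
   extrinsically calibrated from 3-D point correspondences
   (Kabsch/Umeyama least squares) and fused joint-by-joint with
   confidence-weighted averaging, so joints occluded in one view are
   filled from the other.
2. **Rigid-body model + CBPSO inverse kinematics.** Each arm is a
   9-DOF serial chain (2 sternoclavicular + 3 glenohumeral + 1 elbow +
   2 wrist + 1 hand) hanging off a free torso pose. Per frame, joint
   angles are recovered by *crossbreed particle swarm optimization*:
   the classical inertia-weight update

   v ← ω v + c₁r₁(pbest − x) + c₂r₂(gbest − x),  x ← x + v

   extended with a genetic-style blend of parent pairs,
   child(x) = P_c·parent₁(x) + (1−P_c)·parent₂(x), which lets particles
   escape local minima of the redundant chain. The fitness is the
   confidence-weighted squared distance ‖y − F(x)‖² between observed
   markers y and the forward-kinematic image F(x), plus a soft
   scapulohumeral-rhythm prior coupling girdle angles to humeral
   elevation through piecewise-linear functions θ_fb(β), θ_ud(β).
   Reconstruction is bone-length exact by construction, which is what
   repairs occlusion-induced position jumps.
3. **Reachable workspace.** Hand trajectories are normalized to the
   shoulder and arm length, projected to the unit sphere, bounded by an
   alpha shape, smoothed with a closed centripetal Catmull-Rom spline,
   and quantified as relative surface area (RSA = area/4π) in four
   shoulder quadrants (inner/outer × above/below).
4. **Attention-extended STGCN score regression.** A spatial-temporal
   graph convolutional network over the 11-marker limb graph regresses
   a continuous 0–100 movement-quality score. Per partition k
   (Â_k = A_k + I, A₀ = I, A₁ = A), a ConvLSTM produces per-frame
   self-attention maps S_k that modulate the graph convolution
   G = σ(φ(Â_k ⊙ S_k) Z W_k); three parallel temporal convolutions
   (kernels 3/5/7) and a stacked LSTM head (80, 40, 40, 80) complete
   the model, trained with Adam on mean squared error. The network and
   its reverse-mode autodiff engine are implemented in NumPy. The
   attention maps double as per-joint *importance* profiles.

A synthetic motion simulator drives everything: it generates the
16-action assessment protocol (8 reachable-workspace sweeps, 8 proximal
touch targets such as nose, ear, lumbar spine) with an explicit
impairment model — range-of-motion scaling, 4–8 Hz band-limited tremor
in joint-angle space, time dilation — and a documented deterministic
quality label, score = clip(100·rom_scale − 4·tremor_amp, 0, 100).

## Worked example

Simulate an impaired vertical sweep at azimuth 90° and score it:

```
$ rehabmotion simulate --action RW-V90 --rom-scale 0.7 --tremor 2.0 \
      --fps 30 --seed 7 --out demo/
wrote 3 streams + label to demo (score 62.0)
```

The emitted `label.json` records the ground-truth quality label,
`{"score": 62.0, "impairment": {"rom_scale": 0.7, "tremor_amp_deg": 2.0}}`:
70% of full range costs 30 points and 2° of tremor costs 8 more.

The same run through the library, reconstructing the pose by CBPSO and
quantifying the workspace:

```python
import numpy as np
from rehabmotion.simulate import generate_trajectory, ImpairmentSpec
from rehabmotion.ik import SwarmConfig, solve_sequence
from rehabmotion.workspace import compute_envelope
from rehabmotion.kinematics import ArmModel

sim = generate_trajectory("RW-V90",
                          ImpairmentSpec(rom_scale=0.7, tremor_amp_deg=2.0),
                          fps=5, seed=7)
sol = solve_sequence(sim.frames, SwarmConfig(seed=0), sides=("right",))
hand = np.stack([f.position("RHAN") for f in sol.frames])
sho = np.stack([f.position("RSHO") for f in sol.frames])
env = compute_envelope(hand, sho, ArmModel("right").lengths.arm_length)
print(env.total_rsa, env.quadrant_rsa)
```

prints a reconstruction whose marker RMS error against the generating
ground truth is 1.2 mm over 20 frames, and a workspace envelope with
total RSA 0.0109 split over the quadrants as
[0.0039, 0.0011, 0.0037, 0.0021] — a single sweep plane covers a thin
band of the sphere; the full 8-sweep protocol at full range covers
RSA ≈ 0.375.

The whole chain (simulate → calibrate → fuse → filter → IK →
workspace → train → score → importance) runs as one command:

```
rehabmotion run --action RW-V90 --seed 0 --out report/
```

## Layout

| module | contents |
| --- | --- |
| `skeleton` | joint catalogues, frames, the 11-marker limb graph |
| `simulate` | protocol actions, impairment model, two-camera rendering |
| `calibration` | Kabsch extrinsics, confidence-weighted fusion |
| `filters` | median + zero-phase Butterworth, SNR accounting |
| `kinematics` | homogeneous transforms, FK, scapulohumeral rhythm |
| `ik` | CBPSO solver (swarm, crossbreed operator, sequencing) |
| `workspace` | spherical normalization, alpha shape, spline, RSA |
| `autodiff`, `network` | NumPy autodiff + the attention-STGCN regressor |
| `metrics` | MAD / RMSE / MAPE |
| `io`, `cli`, `pipeline` | skeleton CSV dialect, subcommands, full run |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
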