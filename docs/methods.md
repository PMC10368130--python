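# Methods

This note documents the models, defaults and design choices behind
`rehabmotion`, and what the synthetic experiments do and do not show.

## Rigid-body model of the upper limb

Each arm is a serial chain rooted at the neck: torso (free rigid pose:
intrinsic x-y-z rotation + translation), sternoclavicular joint
(Rz·Ry, 2 DOF), glenohumeral shoulder (Rx·Ry·Rz, 3 DOF, offset by the
girdle segment), elbow (Rx, 1 DOF), wrist (Rx·Rz, 2 DOF), hand (Rx,
1 DOF) — nine rotational parameters per arm. Marker positions are the
chain's homogeneous-transform products applied to local joint offsets
whose norms equal the segment lengths, so **bone-length conservation is
structural**: any angle vector yields inter-marker distances equal to
the segment lengths to machine precision. Default segment lengths
(m): girdle 0.18, upper arm 0.30, forearm 0.25, wrist-palm 0.08,
palm-tip 0.10; estimable from data as median inter-marker distances
over confident frames.

Conventions. Right-handed frame, x to the subject's right, y up, z
toward the (frontal) camera; meters; radians internally. The left arm
mirrors the right: rotations about y and z change sign and the
shoulder offset flips in x, so equal angle vectors produce postures
mirrored through the sagittal plane. x-axis angles are stored
flexion-positive (positive elbow flexion carries the forearm toward
the subject's front), which lets the anatomical limit table read
naturally. Default limits (deg): sc_fb ∈ [−30, 30], sc_ud ∈ [−15, 60],
sh_x ∈ [−60, 180], sh_y ∈ [−90, 90], sh_z ∈ [−90, 130],
elb_x ∈ [0, 150], wr_x ∈ [−70, 80], wr_z ∈ [−20, 35],
hand_x ∈ [−45, 45]. The sc_ud ceiling is 60° rather than a more
conservative 45° because the rhythm function itself prescribes
θ_ud(180°) = 0.36·180 − 10.8 = 54° at the protocol's own maximal
elevation; a 45° cap would make the model's nominal full-range sweep
infeasible.

The scapulohumeral rhythm couples girdle angles to humeral elevation β
(degrees):

    θ_fb = −0.35β (β<0);  0 (0≤β≤70);  −0.22β + 15.4 (β>70)
    θ_ud = −0.3β  (β<0);  0 (0≤β≤30);  0.36β − 10.8  (β>30)

Both are continuous at their breakpoints. The coupling is applied as a
**soft prior** in inverse kinematics (weight 10⁻⁵ m²/rad²), not a hard
constraint: the regression stems from unimpaired movement and should
bias, not dictate, the girdle/humerus split in patients.

## CBPSO inverse kinematics

Per frame and per arm, the 9 angles minimize

    f(x) = Σ_j w_j ‖y_j − F(x)_j‖² + w_r Δrhythm(x)² + w_c ‖x − x_prev‖²

over the limit box, where w_j are marker confidences (occluded markers
drop out; fewer than 3 confident markers raises an underdetermined
error), w_r = 10⁻⁵ is the rhythm prior and w_c = 10⁻⁶ a temporal
continuity prior that pins degrees of freedom the visible markers do
not constrain (e.g. wrist angles while the hand is occluded) to the
previous frame's solution; both weights are small enough that a
noise-free fully-visible frame is still solved to sub-millimetre
marker RMS. The torso pose is taken from the torso marker directly
(identity orientation — the protocol instructs subjects not to rotate
the trunk), keeping the swarm dimension at 9.

Swarm defaults: N = 60 particles, ω = 0.72, c₁ = c₂ = 1.49, velocity
clamp 0.25 of the box width, position clamping with velocity zeroing,
max 300 iterations, fitness tolerance 10⁻⁸ m². Crossbreeding fires
each iteration with probability 0.5 on a uniformly drawn pool of 20%
of the swarm: parents are paired, each parent replaced by a child with
position P_c·x₁ + (1−P_c)·x₂ (P_c = 0.6) and velocity
(v₁+v₂)/‖v₁+v₂‖·‖v_parent‖ (falling back to the parent's velocity when
the sum vanishes); personal-best memories stay with the slots. With
the crossbreed probability set to zero the solver is bit-identical to
classical PSO.

Convergence hygiene: sequences warm-start each frame from the previous
solution (a third of the swarm is seeded in a 0.05-rad cluster around
the warm start); a solve whose fitness stalls above tolerance is
polished by narrowing restarts (re-seeded CBPSO in boxes of half-width
0.3/0.1/0.03 rad around the incumbent) and, if still poor, re-run cold
up to twice. These are scheduling choices around the same optimizer,
not a different algorithm.

## Synthetic data generator

The generator defines the study conditions. The 16-action protocol:
vertical-plane sweeps at azimuths 0/45/90/135° traversing elevation
0→180→0 (azimuth 0 = frontal abduction plane, 90 = sagittal flexion
plane), horizontal sweeps at elevations 45/90/135° traversing azimuth
0→135→0 plus one at elevation 90° spanning 0→180, and eight proximal
reaches (side, lumbar spine, stomach, contralateral/ipsilateral
shoulder, nose, ear, head top). Sweeps follow a raised-cosine
elevation profile with the arm straight and the rhythm coupling
applied; shoulder Euler angles are chosen per frame from the free
axial-twist family to stay inside the anatomical limits while
remaining continuous. Proximal reaches are out-and-back minimum-jerk
interpolations in joint-angle space to frozen per-action target-angle
presets; the presets were derived once by bounded least squares so
each action's fingertip lands within ~2 cm of its named body landmark,
and are config constants.

Impairment: rom_scale ∈ (0, 1] multiplies angular amplitude;
tremor is band-limited Gaussian angle noise (default 4–8 Hz, std
scaled to the requested amplitude) added to the shoulder and elbow
angles — adding it in angle space keeps corrupted motion biologically
connected; slowness ≥ 1 dilates time. The quality label is the
documented deterministic formula score = clip(100·rom_scale −
4·tremor_amp_deg, 0, 100): strictly increasing in range of motion,
strictly decreasing in tremor. This label model is artifact-defined —
it stands in for clinician scores, which no public data provides.

Rendering: two cameras at (±1, 0, 1) m looking at the torso (2 m
apart, 90° between view axes). Occlusion marks a joint unseen when it
lies more than 15 cm behind the torso plane relative to that camera;
dropouts are i.i.d. Bernoulli; both produce confidence 0 and a (0,0,0)
sentinel. Non-upper-limb device joints come from a static standing
template so frames are format-complete. What the simulator does *not*
emulate: soft-tissue artifacts, tracking-model biases correlated with
pose, camera rolling shutter, multi-person scenes. Passing tests
therefore demonstrate correctness of the algorithms under the stated
noise model, not clinical accuracy.

## Preprocessing and SNR

Median filter (default window 5) then zero-phase 6th-order Butterworth
low-pass, in that order. The nominal 30 Hz cutoff exceeds Nyquist at
the 30 fps capture rate, so the effective cutoff is
min(30 Hz, 0.45·fs); the CLI refuses a configured cutoff at or above
Nyquist outright. SNR is defined as 10·log₁₀(var(reference)/
var(raw − reference)) per joint per axis; against simulator ground
truth it compares raw fused streams with rigid-model reconstructions,
and in the field (no ground truth) the processed signal serves as the
reference.

## Reachable workspace

Shoulder-centred hand directions (frames with extension below 0.2 arm
lengths dropped) are charted by stereographic projection from the
antipode of the data centroid — conformal, and singular only at a
direction the hand cannot reach — where a Delaunay alpha shape
(default radius: max of 2.5× the median nearest-neighbour spacing and
0.25× the chart extent, so the envelope bridges between sweep planes)
yields the outer boundary as a simple cycle through data points. The
boundary is smoothed by a closed centripetal Catmull-Rom spline,
re-projected to the sphere, fan-triangulated from its spherical
centroid, subdivided, and measured by l'Huilier spherical-triangle
areas; each micro-triangle is assigned to a quadrant by its centroid's
side of the horizontal and sagittal planes, so quadrant areas add to
the total exactly. RSA normalizes by the full sphere 4π (configurable;
the hemisphere convention differs by a factor 2). Quadrants: Q1
inner-above, Q2 inner-below, Q3 outer-above, Q4 outer-below.

## Assessment network

Input: (T × 11 × 3) marker sequences, torso-centred and divided by arm
length, resampled to T = 32 frames for the bundled experiments.
Temporal lift: channel concatenation of the raw sequence with its
temporal convolution (kernel 9), read as the ⊕/⊗ composition of the
lift stage. Three blocks; in each, per partition (A₀ = I, A₁ = A;
Â_k = A_k + I; φ = D^(−1/2)·D^(−1/2) with D the degree matrix of Â_k),
a ConvLSTM with 1×1 gates over the marker axis produces per-frame maps
S_k = tanh(P·vec(h_t)) ∈ (−1,1)^(11×11) (the hidden-to-map reduction
is a learned linear projection — the reduction is otherwise
unspecified in the source method), which modulate Â_k elementwise
before the degree-normalized graph convolution; then three parallel
temporal convolutions (kernels 3/5/7, 6 channels each) are
concatenated with a 1×1 residual. A 4-layer LSTM (80/40/40/80,
dropout 0.25 between layers, forget-gate bias initialized to +1,
input-weight gain 2 to preserve variance through the stack) reads the
flattened node features; its outputs are mean-pooled over time into a
linear scalar head (bias initialized mid-scale at 50). Mean pooling
rather than last-hidden readout is deliberate: protocol movements end
back at rest, so the score-relevant evidence is distributed over the
sequence, not concentrated at its end.

Training: Adam on MSE (0–100 score scale), batch 4, global-norm
gradient clipping at 5 (the recurrent stack otherwise exhibits loss
spikes that saturate the nonlinearities and freeze the output).
The config retains the nominal learning rate 0.1 for fidelity to the
source description, but training at that rate is unstable; the
package's experiments use 0.005, and a non-finite loss raises rather
than returning silently broken weights. All training is seeded and
bit-reproducible on fixed hardware.

Joint importance: per action, the mean absolute attention map entry
per node (over time, partitions, rows and columns), min-max scaled to
[0, 1] across the 11 nodes.

## Bundled experiment sizes

The test-suite experiments are sized for a single CPU: FK→IK round
trips use 3 frames per action (48 frames across the 16 actions);
the occlusion study uses one 40-frame sweep at 10 fps with 20%
per-camera dropout; the regression benchmark uses 200 sequences of a
single action (vertical sweep at 90° azimuth — scores in this protocol
are per-action judgements, and a single-action benchmark makes the
amplitude→score mapping identifiable at this sample size), an 80/20
split, 15 epochs, and three seeded runs whose test MADs are averaged —
the same repeated-training-and-average protocol used for the published
metric tables; the overfit check trains 8 samples until MSE < 1. The
ablation compares the full model against the same network with all
attention maps frozen to 1 and against a predict-the-mean baseline.

## Known limitations

- The torso orientation is assumed fixed; trunk-rotation compensation,
  common in hemiparetic reaching, is outside the current model.
- Wrist/hand angles are unidentifiable whenever the distal markers are
  occluded; the continuity prior carries them through gaps, which is a
  smoothness assumption, not a measurement.
- The quality label is a synthetic surrogate; agreement with clinical
  scales (FMA, Brunnstrom) cannot be established without patient data,
  and the published per-patient error tables are not reproducible here
  for the same reason.
- The alpha-shape default is heuristic; sparse protocols (few sweep
  planes) make the envelope sensitive to the radius choice.
- Single-precision-free NumPy training is CPU-bound; the bundled
  experiment sizes reflect that.
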