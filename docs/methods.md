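# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `bedfall` pipeline, in the order the data flows.

## Rigid-body world

The bed–human world consists of an infinite floor plane at z = 0, a box
bed (default 2.0 m × 0.9 m footprint, 0.5 m high — typical single-bed
geometry; the paper trail of published bed-simulation work rarely states
dimensions, so these are package defaults, configurable in `WorldConfig`),
and one humanoid. The humanoid is a 13-particle articulated body whose
particles double as the skeleton keypoints: a rigid torso cluster (head,
shoulders, hips, all pairwise distance-constrained) with four two-segment
limbs attached through shoulder/hip ball joints and elbow/knee hinges.
Segment offsets approximate a 1.7 m adult; particle masses sum to 60 kg
with a plausible segment distribution (hips 10 kg each, head 5 kg, distal
segments lighter).

Dynamics are integrated with position-based dynamics (PBD): semi-implicit
gravity prediction, eight Gauss–Seidel sweeps projecting the 18 bone
distance constraints, unilateral contact projection against the floor and
the bed top face, then velocity reconstruction with contact friction
(contacted particles retain a fraction 1 − μ of tangential velocity,
μ = 0.85, and never rebound). PBD with stiff constraints approximates
rigid-segment behavior well at the 3 s horizon used here and is
unconditionally stable at the default Δt_sim = 1/60 s, which divides both
the 3 s window (180 steps) and the 30 fps label grid (2 steps per frame).
The step kernel is JIT-compiled and operates on episode batches; a batch
of one reproduces any batched row bit-for-bit, so per-episode replay from
a logged seed and bulk dataset generation are numerically identical.

Contact classification: every particle–surface contact after a step is
reported as humanoid–bed, humanoid–floor, or hand–floor (the two wrists
are the configured "hand" segments). Bed contact only engages for
particles approaching the top face from above, so a limb that has slid off
the edge cannot snap back up through the bed; bed side faces are not
collided (a limb brushing a side face simply continues to the floor),
a simplification that slightly advances some fall times. Instability is
defined as any non-finite coordinate or a coordinate magnitude above 50 m
after a step; unstable episodes are discarded and counted.

The engine state is maximal-coordinate (particle positions/velocities).
Generalized coordinates — root pose plus joint angles — exist at
configuration time: the sampler produces them and forward kinematics maps
them to particle space at episode setup. This split keeps the sampling
surface expressed in joint space, as the protocol requires, while the
integrator stays in the representation PBD needs.

## Initial-state sampling

Planar position is uniform on the bed footprint shrunk by a 0.1 m edge
margin. Two orientation strategies are implemented exactly as specified by
the protocol:

* **pose-stratified** — one of four coarse lying modes drawn uniformly
  (supine, prone, left-lateral, right-lateral; presets are 0°, 180°, ∓90°
  rolls about the bed's long axis with the reference body lying along +x,
  left side at +y), perturbed per axis with zero-mean Gaussian noise
  (σ = 15°);
* **fully-random** — Euler angles independently uniform on [−180°, 180°]
  per axis. Uniform Euler angles are *not* uniform on SO(3); that bias is
  deliberate, because it is what the protocol states. Ball joints, by
  contrast, are sampled genuinely uniformly on the rotation group
  (normalized 4-D Gaussians).

All Euler conversions use one global convention (extrinsic xyz), recorded
in every run manifest. Hinges are uniform within their limits (elbows and
knees, [0, 2.6] rad flexion); hinges without limits would use a ±45°
default range. Joint sampling is identical for both strategies.

Each episode owns an integer seed; all of its randomness flows from
`default_rng(seed)` in a fixed draw order shared by the per-episode API
and the batched generator, so any logged episode can be replayed alone.

## Episode execution and labeling

Pre-pose interpolates from the reset pose (neutral supine, centered) to
the target configuration in joint space — linear in positions and hinge
angles, slerp in quaternions — over 1.0 s of substeps with velocities
zeroed throughout, ending with the root 2.0 m above the bed top. The body
then falls under gravity until the first humanoid–bed contact (timeout
2.0 s of simulated time, generous for a 2 m drop); at that instant
velocities are zeroed and the clock reset to t = 0. The batched generator
skips the physically inert interpolation substeps and starts the drop from
the interpolation endpoint, which is the same state by construction.
Episodes that never touch the bed (timeout) and episodes flagged unstable
are rejected and tallied, never silently dropped; dataset quotas are
filled by continued simulation.

The rollout runs uncontrolled dynamics for T = 3 s. A fall is the first
step at which any non-hand particle contacts the floor; hand–floor
contact alone is non-terminal (it models protective bracing, which would
otherwise inflate the positive class). Labels are computed on the 30 fps
grid: n_f = ⌊F s_f Δt_sim⌋ (flooring chosen where the grid mapping is
ambiguous; the alternative rounding shifts n_f by at most one frame, a
factor γ on the label), y = γ^{n_f} for falls (γ = 0.99), y = 0 otherwise.
Non-grid-aligned products are nudged by 1e−9 before flooring so exact
frame boundaries do not round down. Binary labels are stored alongside y
rather than re-derived downstream.

## Datasets

Training sets are class-balanced by simulating until exact quotas
(⌈N/2⌉ falls) are reached, discarding surplus episodes of a filled class;
with the default geometry the raw fall rate is ≈ 0.55 under stratified
sampling, so balancing discards modestly. Test sets are pose-balanced:
exactly n/4 accepted episodes per mode, modes pinned at the sampler, drawn
from a seed stream disjoint from training (spawned `SeedSequence`
children). The natural class mix of the test set is retained (≈ 0.57 fall
prevalence at the defaults). Splits are seeded shuffles; train/validation
is 9:1, one split shared across training seeds. CSVs carry a `#`-prefixed
JSON metadata line (γ, F, T, bed bounds, engine version) and full float
precision, so round-trips are bit-exact.

## Models and training

Five families share the 26-D input and the continuous target: the MLP
(26→256→128→1, ReLU, dropout 0.1 — the primary model), a 1-D CNN over the
keypoint axis (2×13 input, two valid length-3 convolutions 2→32→64, global
average pooling, 64→64→1 head), a GCN on the fixed anatomical skeleton
graph (self-loops, symmetric normalization, two width-64 layers, flattened
13·64 = 832 head 832→256→128→64→1), a 300-tree unlimited-depth random
forest (scikit-learn), and a single-layer hidden-64 LSTM over the first
five 30 fps frames (episodes that fall before frame 4 repeat the last
frame at or before the fall; the label stays the initial-state y). The
neural families are implemented directly in numpy with hand-written
gradients and Adam (β = 0.9/0.999, ε = 1e−8), float64 throughout, which
makes training bitwise-deterministic per seed; backward passes are
verified against central finite differences in the test suite.

Training minimizes mini-batch MSE at lr 10⁻³, batch 512, ≤ 50 epochs,
returning the minimum-validation-MSE checkpoint (the only selection
criterion the loss defines). Outputs are unclipped real scores — clipping
to [0, 1] would silently change MSE against y. Note that with batch 512
and 50 epochs, Adam takes few steps on small datasets; the protocol's
reference scale (10⁵ samples) gives ~9,000 updates, and unit tests that
probe convergence on small synthetic sets shrink the batch instead of
changing the protocol.

## Evaluation

AUROC uses trapezoidal ROC integration (equal to the positive-outranks-
negative probability with ties counting one half); AUPRC uses step-wise
average-precision integration, avoiding the optimistic linear PR
interpolation. The decision threshold τ maximizes F1 on validation scores
over all midpoints between consecutive unique sorted scores (±∞
sentinels), ties broken toward the smaller τ (higher recall); the decision
rule is score ≥ τ. Zero-denominator conventions: precision, recall and F1
are 0 when undefined. Per-posture reports reuse the globally calibrated τ;
a single-class subgroup reports NaN ranking metrics rather than failing.
All benchmark metrics are means ± std over training seeds {41…45}.

## Surrogate generator

The physics-free surrogate emulates the statistical structure the learning
stack assumes: coherent 13-point skeletons (scaled body template, rotated
around bed-aligned headings, jittered), with an episode "falling" iff its
minimum signed distance to the nearest edge of the normalized bed square
is below a cutoff (0.15), and the fall frame growing linearly with that
distance — so risk decreases monotonically with distance from the edge,
mirroring what a static in-bed skeleton plausibly encodes. Labels go
through the real risk labeler. The default template scale (0.7) keeps a
bed-centered body safely inside the cutoff and yields a ≈ 0.75 natural
fall rate before balancing. Passing surrogate tests demonstrates that the
models can recover a smooth edge-proximity risk rule from u; it says
nothing about contact dynamics, pose settling, or the simulator's pose
distribution.

## Problem sizes and reproducibility

The package's reference protocol is 100,000 balanced pose-stratified
training samples and a 50,000 pose-balanced test set; because the engine
is batch-vectorized, the full protocol generates in about a minute and the
five-seed MLP benchmark completes in a few minutes on one CPU, so both the
test suite and `scripts/acceptance.py` run it at full scale. The sampling
ablation is run at 10,000/4,000 and the learning curve over
N ∈ {2,500, 5,000, 10,000} nested subsets of one pool (nesting reduces
variance across N). Every run manifest records geometry, integrator
settings, sampler convention, label parameters, seeds and engine version.

## Known limitations

The bed is rigid (no mattress compliance or rails) and frictional
parameters are fixed; the humanoid is a single coarse morphology without
self-collision, and bed side faces are not collided. Skeletons are
noise-free and strictly 2-D (height information is discarded by design,
matching camera-based sensing assumptions). Dynamics are uncontrolled —
no active motion — and the horizon is 3 s. Class balance and pose balance
are experimental constructions, not bedside prevalence. Results therefore
quantify learnability under matched simulator dynamics, not clinical
performance.
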