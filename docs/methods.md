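# Methods

## Model

A Neural Associative Skill Memory stores a repertoire of sensorimotor skill
sequences in a single two-layer temporal predictive coding (tPC) network
whose graphical structure is a hidden Markov model. At step `μ` the hidden
state `z^μ` (n_hidden units) is predicted from the previous settled hidden
state through the recurrent weights `W_H`, and predicts the observation
`x^μ` (n_obs channels) through the top-down weights `W_F`:

    ε_z = z^μ − W_H f(ẑ^{μ−1}),   ε_x = x^μ − W_F f(z^μ)
    F_μ = ‖ε_z‖² + ‖ε_x‖²

Everything the package does is a gradient flow on the per-step energy `F_μ`:

* **Inference** (value-neuron dynamics): explicit-Euler descent
  `ż ∝ −ε_z + f′(z) ⊙ W_Fᵀ ε_x`, fixed step `inference_lr`, for
  `inference_iters` iterations, starting at the temporal prediction
  `W_H f(ẑ^{μ−1})` (so the hidden error is zero at the first iterate;
  `ẑ^{−1} = 0`). No momentum or line search — the simplest faithful
  integration of the dynamics.
* **Learning** (memorisation): after `z^μ` settles, one local update per
  matrix per step — `ΔW_H = η ε_z f(ẑ^{μ−1})ᵀ`, `ΔW_F = η ε_x f(z^μ)ᵀ` —
  then the settled `z^μ` is carried forward as the next step's `ẑ`. Each
  update touches only quantities available at the current step, which is
  the locality claim the test suite asserts structurally and numerically
  (both update directions match finite differences of `F_μ` to relative
  error < 1e-4).
* **Offline recall**: the hidden state is settled on the first `T_n`
  observations of a trial (the cue), then the model rolls forward
  ballistically, `ẑ^μ = W_H f(ẑ^{μ−1})`, `x̂^μ = W_F f(ẑ^μ)` — the HMM
  forward pass, which is the fixed point of the observation-settling
  dynamics for this two-layer model.
* **Online recall / monitoring**: each observed step is clamped, the
  hidden state settled, and the converged energy `F_μ` recorded. This
  per-step energy is the out-of-distribution signal used for fault
  detection.

The activation `f` is `tanh` by default; `linear` is selectable, in which
case settled inference has the closed form
`(I + W_FᵀW_F) z = W_H z_prev + W_Fᵀ x`, used as an oracle in the tests.
There are no bias terms. Weights are initialised Kaiming-uniform,
`U(±√(6/n_hidden))`, from a stored integer seed; one seed determines every
random draw, so any run is bit-reproducible.

Default hyperparameters: 256 hidden units, weight learning rate 1e-4, 1000
full-sequence presentations per skill at batch size 1, inference rate 1e-2
with 100 iterations per step. Sequences are Z-scored per channel (pooled
over trials and time, sd floor 1e-6) before training; recalled outputs are
mapped back to physical units.

### Two monitoring choices that matter

* **The first step of a trial is not monitored.** With the null prior
  `ẑ^{−1} = 0`, `F_0` contains `‖z⁰‖²` and measures initial-state
  inference, not prediction quality; empirically it is ~25× the later
  steps. Pooling it into the normal-operation distribution would push the
  95th-percentile threshold above every fault signal (20 trials × 15 steps
  puts 6.7% of the mass at step 0, beyond the 5% tail). Thresholds are
  therefore fitted, and detection scanned, from step 1 onward.
* **Isolation uses the forward prediction error.** With n_hidden ≫ n_obs
  the clamped inference can explain almost any observation away, so the
  *settled* ε_x is flat and uninformative. The per-channel error used for
  isolation is instead the error of the prediction made before the step is
  seen, `|x^μ − W_F f(W_H f(ẑ^{μ−1}))|`, which peaks sharply at the
  faulted channel. Detection still uses the converged energy.

## Fault detection, isolation, baseline

The detection threshold is the nearest-rank percentile (the
`⌈p/100·n⌉`-th order statistic) of per-step energies pooled over fault-free
trials, making the false-positive identity exact and testable: at p = 95
with n a multiple of 20 and distinct values, exactly 5% of the fitted
values lie above. Thresholds are calibrated on 20 *fresh* fault-free trials
(10 per skill) rather than the training demonstrations — in-sample
calibration understates out-of-sample variability (severely so for the
baseline, whose per-step σ̂ comes from only 10 demonstrations) and the
fitted FPR would not transfer.

A trial is detected if any post-fault step's energy exceeds the threshold;
the isolated joint is the joint channel with the largest forward prediction
error at the detection step (ties → lowest index).

The traditional-ASM baseline stores per-skill signal statistics — mean and
sd per (time step, channel) over the demonstrations — and monitors the sum
of squared Z-scored errors, with its own nearest-rank threshold fitted the
same way. It must be told the true skill label. Its isolation follows its
own definition: the argmax of |z| over *all* 25 channels, which is wrong
whenever an end-effector or force channel out-scores the locked joint —
the main reason its isolation accuracy trails the energy monitor's even
where its detection is comparable.

Reactive correction closes the loop with a proportional controller at the
low-level rate (40 Hz against the model's 2 Hz, linear interpolation
between predictions): each joint moves a fraction `gain` (default 0.5) of
its remaining error per low-level step, so an impulse disturbance decays
geometrically at rate (1 − gain).

## Synthetic plant

The plant replaces a physics-engine robot simulation with a kinematic
7-joint arm; the method consumes only the 25-channel time series, so the
kinematic proxy preserves everything the model sees. Channels: 7 joint
angles (degrees), 3 end-effector coordinates from forward kinematics over
an alternating-axis chain, 3 gripper channels (aperture + two fingers),
and 12 force/torque channels (two grippers × 6 components) carrying a load
profile while the object is held. Pick-and-place trials are scripted joint
waypoints (reach, grasp at t = 3 s, lift, transport, place) interpolated
to 15 steps at 2 Hz; every joint keeps moving in every segment, so a late
joint lock is still a real deviation. Skills A and B use different pick
and place locations.

Observation noise is i.i.d. Gaussian per channel with sd = 2% of the
channel's dynamic range across both skills' nominal trajectories — a
stand-in for "realistic simulation noise" whose true statistics are not
published. The 7+3+3+12 channel split is likewise a documented stand-in
for an unspecified 25-channel decomposition.

Joint-lock faults hold the faulted joint at its current commanded angle
plus the overshoot from the fault step onward, recompute the end effector
through the forward kinematics, and add a decaying force spike (10× the
grasp load, halving per step) if the end effector crosses the floor
(height −0.27 m, chosen just below the nominal workspace so that severe
joint-2 locks collide while nominal trials never do). The default
evaluation grid is 7 joints × fault times 1.0–6.0 s in 0.5 s steps ×
overshoots ±5/±10/±15° = 462 trials; zero overshoot is excluded because a
lock with no overshoot at the goal is not a detectable fault under this
plant (the published 980-trial count cannot be reconstructed from the
published ranges).

The follow-through dataset emulates the context-cued reaching paradigm: a
straight 12 cm start→target path plus a half-sine lateral bow of 2 cm,
signed by context (two mirrored contexts, cw/ccw), joint angles from
planar 2-link inverse kinematics, and a one-hot context cue. Cue onset is
step 0 for the two planning conditions and mid-movement (step ⌈T/2⌉ = 5)
for execution-only; `planning_and_execution` appends a 5-step
follow-through leg to the context's secondary target.

What the plant does **not** model: dynamics, torque control, contact
physics, grip slip, multi-step fault cascades, or realistic sensor noise
spectra. Passing tests show the method's properties under stereotyped
trajectories with Gaussian noise — the regime the model class assumes —
not robustness to the full variability of physical robot data.

## Metrics

**DCD (directional compensatory deviation).** For a recalled 2-d
end-effector path, deviations are measured perpendicular to the
start→target line (positive along the +90° normal of S→T). Within the
window from the start up to the path's closest approach to the target (so
a follow-through leg cannot dominate), the DCD is the *signed deviation at
the point of maximum absolute deviation*, multiplied by the context's
compensation sign. This reading keeps the statistic symmetric under the
null of no expressed memory — a signed-max variant would be positively
biased and could never test non-significant — while agreeing on the
analytic cases (straight line → 0, compensatory bow of amplitude a → +a,
opposite bow → −a). It is invariant under rigid motions applied jointly to
path and anchors.

**Separation test.** One-sided Wilcoxon signed-rank across seeds
(α = 0.05) that per-seed DCD exceeds zero; each per-seed value averages
the recalled paths of 12 fresh noisy cues per context and then the two
contexts' signed scores.

**Speed–accuracy.** Offline-recall MSE (normalised units, all channels,
against the noise-free plan) as a function of the number of cued inference
iterations, median over seeds. The BPTT baselines accept and ignore the
iteration argument; their curve is constant by construction.

## Baseline RNNs

Vanilla tanh sequence-to-sequence RNNs trained by BPTT with hand-derived
numpy gradients (validated against finite differences): S-to-M maps
sensory channels (end-effector + cue) to motor channels (joints); SM-to-SM
maps all channels to all channels. Training mirrors the recall protocol:
the real observation enters only at the first step, afterwards S-to-M
receives zeros and SM-to-SM feeds back its own predictions with gradients
flowing through the feedback path (teacher forcing available behind a
flag). The reduced runs use Adam (lr 5e-3) behind the optimiser flag:
plain SGD at the reference rate of 1e-4 leaves these small numpy RNNs
effectively untrained within 1200 presentations, and an untrained baseline
would make every comparison vacuous.

## Reduced study protocols

Chosen so each full study runs on one CPU in minutes, and fixed before the
studies were scored:

| study | setting |
|---|---|
| fault study | 10 demos/skill, n_hidden 256, 200 epochs, 95th percentile, 462-cell grid |
| follow-through | 4 demos/context, n_hidden 128, 600 epochs (tPC); 64 hidden, 1200 Adam steps (RNNs); 6 seeds; recall averaged over 12 cues/context |

## Numerical choices and degenerate inputs

* Nearest-rank percentile (not interpolated) so the FPR identity is exact.
* sd floors: 1e-6 in Z-scoring and baseline statistics; constant channels
  normalise to zero and round-trip through the stored mean.
* Isolation ties break to the lowest joint index.
* Non-finite values during inference or BPTT raise a divergence error
  naming the iteration.
* Zero training epochs return the initial network unchanged; an empty
  sequence list is a usage error; a cue as long as the horizon is a usage
  error.
* Model files round-trip bit-exactly (float64 `.npz`).

## Known limitations

* The capacity of a single weight pair is limited; long or many
  interleaved skills degrade recall before they degrade detection.
* Monitoring needs at least one preceding step; faults at the very first
  step are outside the detector's scope.
* The baseline comparison inherits the ambiguity of the traditional-ASM
  formula (statistics per phase vs per channel); our reading is documented
  above and in the per-method isolation definitions.
* DCD is a 2-d metric; it presumes the compensation axis is perpendicular
  to the start–target line.
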