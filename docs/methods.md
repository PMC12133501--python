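# Methods

`exotremor` simulates Parkinsonian tremor propagating through a coupled
7-DoF model of the human arm, models a cable-driven soft exoskeleton that
counteracts it, and trains a TD7 reinforcement-learning controller to
suppress the tremor during voluntary movements. This note records the
model, its assumptions, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Arm model and tremor propagation

The arm is described by seven generalized coordinates
q = [q1..q7] = [shoulder flexion/extension, shoulder abduction/adduction,
shoulder external/internal rotation, elbow flexion/extension, forearm
pronation/supination, wrist flexion/extension, wrist radial/ulnar
deviation]. Tremor and exoskeleton torques displace the arm from the
voluntary reference trajectory according to the linear coupled system

    I q̈ + D q̇ + K q = τ_T + τ_O,

where q is the *displacement from the reference pose*, I, D, K are 7×7
coupled inertia (kg·m²), damping (N·m·s/rad) and stiffness (N·m/rad)
matrices, τ_T is the tremor torque and τ_O the exoskeleton torque.
Torques serving the intentional task, task load and gravity are carried
by the reference movement itself and do not appear. Off-diagonal entries
of I/D/K are what propagates a tremor driven on one axis onto
anatomically coupled axes.

The shipped I/D/K values are diagonal-dominant placeholder matrices on
the anatomical order of magnitude (shoulder inertia ≈ 0.45 kg·m², elbow
≈ 0.08 kg·m², stiffness 1–8 N·m/rad) with small symmetric couplings;
subject-specific matrices load from the same three-block CSV format.
Positive-definiteness of I and positive-semidefiniteness of D and K are
validated on load — they are what makes the system dissipative and the
simulation stable.

**Integration.** Each control step (default dt = 1/30 s, matching the
30–40 Hz actuation rates of soft exoskeletons) integrates the system
with 20 fixed semi-implicit Euler substeps, which is stable for this
stiff linear system, exactly reproducible, and keeps the one-step
discretization error below 1e-4 rad at tremor-scale torques.

**Per-step re-initialization.** By default each control step starts the
displacement state from rest at the reference pose rather than carrying
the previous simulated state, so the simulated trajectory stays anchored
to the voluntary movement; carrying state across steps is available via
`EnvConfig(carry_state=True)` for ablation. A consequence worth noting:
with re-initialization the induced deviation at each step is (to first
order) proportional to that step's net torque, which makes the control
problem close to reactive.

**Kinematics.** World frame: x forward, y left, z up; the arm hangs
along −z in the neutral pose. The shoulder rotation is the intrinsic
composition R(q1 about −y) · R(q2 about −x) · R(q3 about −z), followed
by elbow flexion about the humeral −y axis; positive q1/q2/q4 are
forward flexion, rightward abduction, and elbow flexion respectively. No
convention is canonical for this joint set; this one was frozen so each
coordinate matches its anatomical name in the documented frame. Segment
lengths default to 0.30/0.28/0.18 m (upper arm / forearm / hand) with
mass ratios 0.52/0.33/0.15.

## Tremor model

Parkinsonian rest tremor is approximated as the superposition of two
sine waves — a first harmonic f1 and a second harmonic f2 — plus i.i.d.
Gaussian noise (σ = 0.1 by default; the literature gives no value, and
0.1 leaves the harmonic structure clearly dominant), normalized to unit
peak and scaled per joint axis by `amplitude_scale ×` a per-axis maximum
tremor torque table (placeholders 0.1–2 N·m, largest at the shoulder).
Harmonics are drawn uniformly: f1 ∈ [4, 6] Hz and f2 ∈ [8, 12] Hz in the
training profile, widened to [3.75, 6.25] / [7.5, 12.5] Hz for
out-of-distribution testing. When several axes tremble they share one
(f1, f2) pair — and, by default, phases — which produces the coupled
oscillation seen across joints in patients. The two harmonics have equal
pre-normalization weight (no relative amplitude is established in the
literature we model from; the ratio is configurable). Tremor is present
at every simulation step; episode-level on/off durations are not
modelled.

## Exoskeleton actuation

Seven tension actuators (cables) each pull an endpoint P2 toward an
anchor P1: five span the shoulder (torso → upper-arm sleeve) and two the
elbow (upper-arm → forearm sleeve). The default coordinates are
plausible placements for a fabric exosuit, not measurements; the elbow
extensor is routed over a posterior standoff so its moment arm keeps a
consistent sign over the elbow's range. Commanded force maps to a 3-D
force via the unit vector from endpoint to anchor (‖F‖ preserved); a
literal componentwise cosine-of-atan2 decomposition is retained as
`mode="as_printed"` for reproducibility, although for generic geometry
it does not preserve the force magnitude (an x-aligned cable yields a
spurious Fz) — the regression tests pin this discrepancy deliberately.
Torque about the spanned joint is τ = r × F with r from joint to
endpoint (lever sign switchable), summed per joint and projected onto
the instantaneous q1–q4 rotation axes. No actuators span the wrist, so
τ_O is always zero on q5–q7.

Per-actuator maxima default to 40 N (shoulder) and 30 N (elbow), giving
Fs = 200 N and Fe = 60 N.

## RL environment

One environment wraps one reference movement. Reference movements are
synthetic: a minimum-jerk out-and-back sweep of the movement's principal
axis with small slow drift on the remaining axes, which keeps the
voluntary spectrum below 2 Hz — cleanly separable from the 4–12 Hz
tremor band. Two seed-varied generations per movement emulate two
recording sessions. Durations default to 4 s (configurable); real
recordings in the underlying protocol are not publicly deposited, so
this generator stands in for them and reproduces only their two salient
features (single-joint sweep, band-limited spectrum) — not inter-subject
variability, segmentation artifacts, or sensor noise. Passing tests
therefore demonstrates correctness of the machinery, not performance on
patient data.

**Episode randomization** (uniform, drawn at reset): I/D/K scale factors
([0.9, 1.1] training / [0.875, 1.125] testing), per-actuator
commanded-to-actual force precision ([0.97, 1.03] / [0.96, 1.04]),
per-actuator endpoint shift along one random local axis ([0, 2] cm /
[0, 2.5] cm, emulating sleeve sliding), and the tremor parameters above.
Tremor-affected axes are fixed per episode.

**Observation (R^80).** Normalized histories of actuator forces (7×2),
tremor torque on the four trainable axes (4×3), actuator endpoint
positions (7×3×2) and elbow/wrist positions (2×3×2): 14+12+42+12 = 80.
The listed blocks admit several decompositions totalling 80; the builder
is configuration-driven and this default is one documented reading.
Forces are normalized by per-actuator maxima, torques by the per-axis
maximum tremor torque, positions by arm reach; everything is clipped to
[−1, 1]. The force/position histories end at the last completed control
interval, while the torque history ends at the tremor measured for the
interval the chosen action acts in: the controller reacts to the tremor
it currently senses. (With the strictly lagged alternative the policy
must extrapolate a two-harmonic signal from three samples at 30 Hz —
below the second harmonic's Nyquist rate — which turns the control
problem into prediction of an aliased signal.)

**Action (R^7).** Mapped affinely from [−1, 1] to [0, F_max] per
actuator, then scaled by the episode's precision factor.

**Reward.** r = w_a·r^a + w_τ·r^τ + w_F·r^F + w_as·r^as + w_u·r^u with
weights 0.5 / 0.9 / 0.05 / 0.05 / 0.5:

* r^a = w_a·n_a — a constant bonus per tremor-affected axis. As
  written the axis weight appears both inside and outside (an effective
  0.25·n_a); the literal form is the default and
  `single_weight_axes=True` applies the weight once.
* r^τ = exp(−mean_i (|τ_e,i| − |τ_t,i|)/(|τ_t,i| + 1)) over affected
  axes, with τ_e = τ_T + τ_O the residual torque: >1 iff the exoskeleton
  suppressed on average.
* r^F = exp(−ΣF/(Fe+Fs)) — minimal-force incentive.
* r^as = −Σ_i (F_i(t) − 2F_i(t−1) + F_i(t−2))² / (N(Fe+Fs)²) — the
  smoothness term is a penalty, so the squared second difference enters
  negated (the printed positive form is available behind
  `smoothness_as_printed=True`).
* r^u = exp(−Σ|τ_u|/(Fe+Fs)²) on the non-tremor axes, with absolute
  values so sign cancellation cannot inflate it.

Every step logs the five components and the decomposition identity
(total = weighted sum, to 1e-12) is asserted in tests. Note that with
Fe+Fs = 260 N the force and unwanted-torque terms are numerically weak
relative to r^τ; the reward's optimum still has all unnecessary
actuators off, but the gradient toward it is shallow — visible in
training as slow decay of idle shoulder-actuator force.

## TD7 learner

TD3 core (deterministic policy gradient, twin critics with clipped
double-Q bootstrapping, delayed policy updates, target networks) plus
the TD7 additions: a state encoder f(s) → z_s and a state-action encoder
g(z_s, a) → z_sa trained to predict the next state's embedding, critics
Q(z_sa, z_s, s, a), actor π(z_s, s); loss-adjusted prioritized replay
(priority max(|δ|^α, 1), α = 0.4, paired with a Huber critic loss); and
policy checkpointing (the best-evaluating snapshot is the deployed
policy). The behavioral-cloning term used for offline RL is omitted —
training here is online.

Task modifications: the replay divides into one sub-buffer per reference
movement with equal per-movement batch allocation (movement trajectories
of different lengths would otherwise be oversampled); exploration adds
*pink* (1/f) noise, generated spectrally per episode, instead of white
noise — temporally correlated exploration suits fine force control and
smooths the explored torque profiles; and action/policy noise scales
carry a 0.5× reduction factor, since small force changes produce large
torque differences through the anatomy.

All networks are small ELU MLPs (hand-written numpy forward/backward
with Adam): the package's control problem has 80-dimensional inputs and
a few thousand parameters per network, where a dense-layer
implementation is simple, dependency-free and fast on one CPU. The
actor head is tanh with a pre-tanh output bias that starts the policy
near the zero-force rest state in which every episode begins; an
optional head scale (> 1, clipped to [−1, 1] at execution, with
clip-aware gradients) is available because the zero-force action sits
exactly at the saturated edge of an unscaled tanh. The reference
hyperparameters (lr 3e-4, γ 0.99, batch 256, hard target updates every
250 steps, policy delay 2) are config defaults.

## Evaluation metrics

* **Amplitude suppression** = 100·(1 − RMS(suppressed − ref)/
  RMS(tremor_only − ref)) over affected axes: 100 % at perfect
  restoration, 0 % for no intervention, negative when the exoskeleton
  amplifies. (No closed-form definition is canonical; the RMS ratio is
  the standard tremor-suppression measure and reproduces the endpoints.)
  Time-resolved curves use the same ratio on a sliding window of one
  first-harmonic period.
* **Occurrence** = percentage of steps where the affected-axis deviation
  is strictly below the tremor-only deviation while every unaffected
  axis stays within ε of the reference (default ε = 5 % of the
  movement's angular range).
* **Torque suppression** = the same RMS ratio on τ_e vs τ_T.

The full protocol sweeps all 15 non-empty subsets of {q1..q4} × 4
movements × n episodes under testing-profile randomization; axis-first
and episode-first averaging are both reported. A perfect-cancellation
oracle (τ_O = −τ_T injected past the actuator model) anchors the metrics
at 100 %, and a model-based feedforward baseline (non-negative
least-squares inversion of the nominal actuation map) marks what perfect
system identification could achieve through the real, randomized
actuators — about 90 % mean amplitude suppression; the per-episode
precision and endpoint-shift draws set that ceiling.

## Scaled-down learning experiment

The acceptance-level learning check trains on one movement
(elbow flexion/extension, 2 s episodes at 30 Hz) with a single-axis
elbow tremor for 6×10⁴ agent steps — minutes on one CPU — and evaluates
the checkpoint policy on 100 training-profile episodes against the
zero-action baseline. Hyperparameters for this short-horizon variant:
γ = 0 (per-step re-initialization carries no state between control
steps, so credit is instantaneous; the replay, twin-critic and
embedding machinery operate unchanged), lr 1e-3, batch 256, exploration
noise decaying linearly to 10 % of its initial scale (final-policy
precision matters more than late exploration). The trained controller
reliably exceeds the zero-action
return and its best evaluation episodes reach ≥ 99 % peak windowed
amplitude suppression; mean suppression at this budget is far below the
feedforward ceiling — closing that gap is what the full-scale (≥ 10⁶
step, all movements × all axis subsets) training is for.

## Known limitations

* All anatomical tables (I/D/K, joint ranges, torque scales, actuator
  coordinates, force maxima) are documented placeholders pending
  subject-specific measurements.
* The displacement dynamics are linear; no muscle model, contact, or
  nonlinear multibody effects.
* The reference-movement generator does not reproduce patient
  variability; results quantify the control machinery, not clinical
  performance.
* Observations are noiseless and fully Markovian given the episode's
  randomization draw; sensor noise and partial observability are out of
  scope.
* The shoulder rotator cable can torque q3 in only one direction, so
  tremor subsets involving q3 have an asymmetric actuation ceiling —
  consistent with the hardware layout this emulates.
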