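# Methods

## Model

One rigid shank+foot segment rotates about the knee of a supine subject
whose pelvis and thigh are fixed with the hip at 90°.  Knee flexion θ is
positive, 0° is full anatomical extension, and the segment makes angle θ
with the upward vertical, so gravity contributes the flexing moment
`m·g·d·sin θ`.  The equation of motion is

    I·θ̈ = Σₘ rₘ(θ)·Fₘ + m·g·d·sin θ + M_applied + M_limit,

where `M_applied` is the knee-axis moment of the examiner's measured 6-DOF
wrench (`app_par·f_y − app_perp·f_x + m_z` in the shank frame) and
`M_limit` a one-sided hyperextension penalty (1000 N·m/rad plus 2 N·m·s/rad
damping, engaged only for θ < 0, logged when active).

Five lumped muscles cross the knee: hamstrings (HAM), vasti (VAS), rectus
femoris (RF), biceps femoris short head (BFS), gastrocnemius (GAS).  Their
muscle-tendon lengths are quadratic polynomials `l_MT(θ)` with moment arm
`r = −dl_MT/dθ` (flexor positive).  The polynomials are a configurable
model artifact chosen to give physiological arms (HAM ≈ 2.4–4.5 cm flexor,
VAS ≈ 2.4–3.5 cm extensor), hamstrings passive engagement near full
extension (fiber strain ≈ 0.27 at 0°), vasti engagement only toward deep
flexion (peak strain ≈ 0.29 at 110°, i.e. the lag phase of their passive
curve), and RF/BFS/GAS below optimal length over the whole range, so their
passive contribution vanishes — consistent with treating only HAM and VAS
passive properties as estimable.

### Muscle model

Thelen-style Hill model, pennation 0 (muscles are lumped; a group-average
fiber-to-tendon ratio replaces architecture detail):

- passive: `F̄_pe = (e^{K·(L̃−1)/S} − 1)/(e^K − 1)`, clamped to 0 below
  optimal length (a slack fiber is force-free).  `S` = strain at maximal
  isometric force (`F̄_pe(1+S) = 1` identically), `K` = shape factor.
- active force-length: Gaussian `exp(−(L̃−1)²/γ)`, γ = 0.45.
- force-velocity: Hill hyperbola `(1+u)/(1−u/A_f)` shortening (A_f = 0.25,
  zero force at −v_max), saturating eccentric branch with plateau 1.4 and a
  C1-continuous slope `1 + 1/A_f` at zero velocity.  `v_max` = 10 optimal
  lengths/s.  No activation scaling of v_max.
- tendon (elastic mode): exponential toe to 0.609·ε₀ then linear,
  renormalised to reach exactly 1 at the isometric strain ε₀ = 0.033.
  Rigid mode sets fiber length to `l_MT − l_slack` directly.
- activation: first-order with τ_act = 10 ms, τ_deact = 40 ms; the resting
  activation 0.01 is a hard floor (the drive is `max(excitation, 0.01)`),
  so controller silence decays activation to rest, never below.

Defaults overridable per muscle; reference maximal forces and lengths are
adult values lumped per group, embedded in `limb.py`.

### Scaling

Subject models scale from an adult reference (1.75 m, 75 kg, tibia
0.43 m): all lengths (segment, COM, l_opt, l_slack, the l_MT map) by the
tibia-length ratio — preserving the fiber-to-tendon ratio — segment mass by
the body-mass ratio, inertia by mass·length², and every maximal isometric
force by (mass ratio)^(2/3).  Segment constants use standard tables
(shank+foot = 6.1 % body mass, COM at 60.6 % and gyration radius 73.5 % of
tibia length from the knee).

## Estimation pipeline

1. **Screening.** Slow-trial hamstrings EMG with RMS > 10 % of the MVC
   reference (strictly greater) marks a non-relaxed subject.
2. **Inverse dynamics.** `M_net = I·θ̈ − M_gravity − M_applied` with θ̈ from
   zero-lag 4th-order Butterworth filtering (6 Hz slow / 20 Hz fast,
   configurable) followed by central differences.  The filtered angle and
   velocity are returned with the moment so states stay consistent.
3. **Moment-angle curve.** Samples are averaged in 1° bins (0.25 s trimmed
   at each record edge where differentiation is boundary-limited), removing
   dwell-time weighting.  The binned mean angular velocity travels with the
   curve.
4. **Contracture fit.** Nelder–Mead over log(S_ham, K_ham, S_vas, K_vas)
   (log-parameterisation keeps the search unbounded while the parameters
   stay positive and the exponential well-defined), start (0.6, 4, 0.6, 4),
   objective = RMS(model moment − net moment) on the angle grid with the
   model's muscle analysis evaluated at the measured states: resting
   activation 0.01 and the force-velocity factor at the binned velocity.
   Evaluating isometrically instead leaves a systematic ~0.1 N·m residual
   from the resting-activation active term and biases S_ham by ~15 %; at
   measured states noise-free recovery is exact to optimizer tolerance
   (xatol 1e-4, fatol 1e-6 N·m, both below reporting precision).
5. **Reflex threshold.** EMG onset by an approximated GLR variance-change
   detector: the channel is whitened by the baseline SD (first 100 ms), a
   20 ms sliding window forms `g = (W/2)(r − 1 − ln r)` for variance ratio
   r > 1, onset is the first crossing of h = 10 sustained 10 ms, refined by
   backtracking to the first clearly supra-baseline sample.  T is the
   smoothed hamstrings MT lengthening velocity 30 ms before onset (with a
   rigid tendon, fiber velocity ≡ MT velocity, matching this estimate).
6. **Gain sweep and selection.** Forward simulations at G ∈ {0, 1, 2, 4}
   share everything but the gain.  Stretch-phase RMS (until 0.4 s in CP,
   0.6 s in TD; hold phase until 1 s) is computed against the measured
   angle; the optimal gain minimises stretch-phase RMS, ties breaking
   toward the lower gain (least spasticity consistent with the data).
   Cohort summaries use sample (n−1) SDs.

## Forward simulation

State: [θ, θ̇, five activations, (five fiber lengths in elastic mode)].
Fixed-step classical RK4 at the 1 ms control step; controller excitation
and the wrench are refreshed every step and also evaluated at the RK
substep times.  The reflex reads the target muscle's fiber velocity from a
per-step buffer, linearly interpolated at t − t_d, outputting zero during
the initial warm-up.  Initial angle is the trial's first sample, initial
velocity zero, activations at the floor, elastic fiber lengths from static
equilibrium (vectorised bisection, residual < 1e-8 N).

Numerical notes: step-halving changes the final angle by < 1e-6° for
smooth (no-reflex, limit-free) dynamics; the reflex law is discontinuous
at threshold (jump G·T), so the switch is located to one step and overall
convergence there is first order (observed ≈ 0.07° per halving on a fast
stretch).  In elastic mode the fiber-velocity inverse is clamped to the
force-velocity range [0, 1.39] to keep the Thelen singularity at low
activation bounded.

## Synthetic data generator

The generator emulates the study design: 9 TD-like and 11 CP-like
children, each with one slow (7 s, 100°→5°, quintic ramp) and one fast
(0.35 s stretch, 1 s record) trial, sampled at 200 Hz (slow) and 1 kHz
(fast).

- **Causal structure.** The examiner's wrench is the generative input: a
  feedforward inverse-dynamics moment along the intended trajectory plus a
  hand impedance (Kp = 40 N·m/rad, Kd = 3 N·m·s/rad).  The impedance is
  physical, not cosmetic: supine with the hip at 90° the shank is an
  inverted pendulum mid-range, stabilised in vivo by the examiner's grip,
  and a firm hand pushes through a reflex catch to end range, as examiners
  do.  Measurement noise (angle σ = 0.5°, force σ = 0.5 N by default) is
  added after simulation and never feeds back into the dynamics.
- **Fast trials are generated in two passes**: the closed-loop pass designs
  and records the wrench; the measurement itself comes from re-running the
  stretch open loop from the recorded wrench through the same code path
  the analysis pipeline uses.  Predicted-vs-measured RMS then carries no
  artefact of how the hand was discretised, and re-simulation from a
  trial's own inputs reproduces its angle exactly.  Slow trials stay
  single-pass: multi-second open-loop re-simulation of the unstable
  mid-range is ill-conditioned, and the pipeline only ever runs inverse
  dynamics on them.
- **Ground truth.** Passive parameters are drawn from truncated normals at
  the group means/SDs (TD: S_ham 0.77±0.15, K_ham 3.59±0.63, S_vas
  4.21±8.19, K_vas 16.12±15.28; CP: 0.57±0.11, 4.65±1.27, 1.40±1.73,
  8.73±3.95), S floored at 0.2 (hamstrings) / 0.5 (vasti) and K at 1 —
  lower vasti values would, with this geometry, demand joint moments far
  beyond what an examiner can apply.  Thresholds are uniform on
  0.05–0.11 m/s (mid-range of simulated fast-stretch MT velocities,
  ≈0.2 m/s peak).  TD subjects have G = 0 (no fast-stretch EMG in TD);
  CP subjects draw G = 0 with probability 1/11, otherwise one of
  {1, 2, 4}.  Anthropometry is pediatric (mass 34±12.5 kg, height
  1.45±0.15 m, truncated).
- **EMG** is amplitude-modulated Gaussian noise: SD = 0.02 MVC background
  plus 0.3 MVC per unit above-resting activation, so the reflex delay and
  activation dynamics are embedded in the signal.  Onset detection on such
  channels trails the true supra-threshold crossing by the 30 ms delay
  plus a few ms of activation rise and detector latency; the resulting
  upward bias of T̂ does not disturb gain selection in the tested
  conditions.
- The generator defaults to rigid tendons: at passive-stretch force levels
  tendon strain is below 1 % and a rigid tendon makes fiber velocity
  identical to MT velocity — exactly the assumption under which T is
  estimated.  The elastic mode is fully implemented and cross-checked
  against rigid in the tests.

## What passing tests do and do not show

The synthetic world shares its muscle model with the estimator, so
parameter-recovery results demonstrate the pipeline's internal consistency,
identifiability and noise robustness — not that the constitutive model is
the right description of spastic muscle.  Real assessments add viscosity,
tonic and length-dependent reflex activity, sustained post-stretch EMG,
soft-tissue motion and sensor artefacts, none of which the generator
emulates; the vasti parameters in particular are weakly identified when
trials do not reach deep flexion, exactly as the curve geometry predicts.

## Problem sizes

The test suite and the acceptance script use desk-scale cohorts chosen as
representative rather than exhaustive: 20 noisy subjects for the S_ham
error statistic, 10 noise-free subjects for gain identification, single
fixed subjects for the dynamic identities.  All are regenerated from seeds
at run time.

## Known limitations

- No viscosity, history dependence or short-range stiffness; no tonic or
  length-dependent reflex component (the controller is purely
  velocity-dependent by design).
- Moment-arm polynomials are plausible but not subject-specific wrapping
  geometry; absolute S/K values depend on the chosen paths.
- The hyperextension penalty is a numerical guard, not a ligament model;
  simulations that overshoot full extension (deliberately mismatched
  gains) can transiently penetrate several degrees.
- Open-loop forward simulation of multi-second slow stretches is
  ill-conditioned (gravity-unstable mid-range); slow trials are therefore
  analysed through inverse dynamics only.
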