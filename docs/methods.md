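# Methods

## The model

Quiet stance is modelled in the sagittal plane as a linearised inverted
pendulum,

    J·θ̈(t) = m·g·h·θ(t) − T(t),

with COM height *h* = 0.96 m, mass *m* = 68.5 kg and ankle moment of inertia
*J* = 76.4 kg·m² (whole-body values, fixed). Corrective ankle torque comes
from a proportional–derivative controller acting on a delayed state
estimate:

    T(t) = Kp·θ̂(t−Δ) + Kd·θ̂̇(t−Δ).

The estimate blends two sensory channels, each available as a position and
a velocity cue:

* **space** — body orientation relative to gravity/support
  (vestibular + proprioceptive): θ_space = θ + n;
* **touch** — the horizontal hand–object distance from light fingertip
  contact with a robot whose position is a programmed gain *G* times body
  position (optionally with a device lag). The raw signal
  s = G·x_body(t−lag) − x_body maps back to an angle estimate
  θ_touch = −s/h + n; with zero lag this is (1 − G)·θ + n, so G = 0
  reproduces true sway, G = 1 (a "free-floating object") carries no sway
  information, and G = 2 reverses the sign of the feedback.

θ̂ = w_space·θ_space + w_touch·θ_touch_corrected, with w_touch + w_space = 1
and w_touch = 0 encoding no contact.

A single noise source *n* — white noise passed through a first-order
low-pass with time constant τ_noise and scaled by k_noise — is added
identically to both channels' position cues; its analytic derivative feeds
the velocity cues, so no spurious channel conflict arises from
differentiating noise.

**Conflict estimator.** The touch channel cannot distinguish self-motion
from object motion. The model compares the two velocity cues,
d = θ̇_touch − θ̇_space (the noise cancels; with zero device lag d = −G·θ̇),
and when |d| exceeds the threshold Te a correction is subtracted from the
touch loop. Two forms are implemented:

* `literal` — subtract the full difference d once |d| > Te;
* `deadzone` (default) — subtract only the supra-threshold excess
  sign(d)·(|d| − Te).

The velocity correction is integrated (pure integrator by default) and the
integral subtracted from the touch *position* cue, so sustained object
motion is progressively discounted in both cues. Fitted Te values are
mode-dependent and not comparable across modes.

## Default parameters and why

| parameter | default | units | rationale |
|---|---|---|---|
| Kp | 1.5·m·g·h ≈ 968 | N·m/rad | see below |
| Kd | 0.25·Kp ≈ 242 | N·m·s/rad | see below |
| Δ (delay) | 0.10 | s | physiological lumped latency |
| w_touch | 0.3 | – | moderate reliance on touch |
| Te | 0.008 | rad/s | ≈ 2 s.d. of θ̇ at G = 0 |
| mode | deadzone | – | see below |
| leak_tau | ∞ | s | see below |
| k_noise | 0.08 | rad | ≈ 4 mm RMS AP sway at G = 0 |
| τ_noise | 1.5 | s | sway power concentrated below 1 Hz |
| dt | 1/1200 | s | 10× the 120-Hz sensor rate |

The controller triple (Kp, Kd, Δ) was selected with a discrete-time
frequency-domain scan of the *linear* loop (conflict off): the effective
position-loop gain is k_eff(G) = w_space + w_touch·(1 − G), and we require
the band-integrated (0.025–4 Hz) position **and** velocity power of the
linear loop to decrease monotonically as k_eff grows over the stable gain
range, while G = +1 remains only marginally stable and G = +2 is statically
unstable (k_eff·Kp < m·g·h). Stiffer/longer-delay settings break velocity
monotonicity through a delay-induced resonance; softer settings destabilise
G = +1. A startup check (spectral radius of the exact discrete closed loop,
including the integer-step delay) aborts a simulation whose G = 0 loop is
unstable.

Three defaults deviate from the most literal reading of the source
mechanism and deserve explanation:

* **Pure integration of the position-cue correction (leak_tau = ∞).** With
  a leaky integrator the correction vanishes at DC — but DC is exactly
  where the inverted pendulum with reversed haptic gain is statically
  unstable, so any finite leak lets G = +2 topple no matter how small Te
  is. Pure integration makes the corrected touch position cue track the
  space cue during sustained conflict and stabilises the reversed-gain
  conditions. A finite leak remains available in the configuration.
* **Deadzone conflict subtraction.** Subtracting the *full* difference once
  the threshold is crossed injects discontinuous corrections whose size is
  the whole conflict signal; at strongly negative gains (large |d| from
  modest sway) this drags those conditions' power up toward the static-
  object level and breaks the monotone gain–power profile. Subtracting
  only the supra-threshold excess preserves small-signal behaviour at
  negative gains while saturating to nearly full correction during the
  large excursions that dominate G = +2. Literal mode is retained as an
  option.
* **Zero device lag in fitted simulations.** The 60-ms body→robot latency
  of the physical device has little effect on the closed loop and is off
  by default in model batteries; the synthetic experiment generator uses
  the measured 0.060 s.

## Simulation and analysis pipeline

Fixed-step semi-implicit Euler at dt = 1/1200 s; the feedback delay is a
ring buffer of round(Δ/dt) steps; traces are decimated (plain stride — the
loop is strongly low-pass) to 120 Hz for analysis. Divergence
(|θ| > 0.5 rad) is flagged on the trace, never raised, so ablation studies
can count unstable runs. Every stochastic quantity is a pure function of
its seed.

The empirical pipeline mirrors standard posturography: velocity is obtained
by differentiating position after a zero-phase second-order 5-Hz Butterworth
low-pass; PSDs are mean-removed rectangular periodograms of non-overlapping
40-s segments (0.025-Hz resolution), averaged, and band-integrated over
0.025–4 Hz; hand force is the 3-D vector magnitude; force–position coupling
uses the unbiased normalised cross-correlation, reporting the signed value
at the extremum of |R| (ties: smallest |lag|, then positive lag).

Condition-level inference is a classical one-way repeated-measures ANOVA
(uncorrected df, as sphericity correction is not applied by default; a
Greenhouse–Geisser-corrected p is attached as a labelled extra) with
Tukey-adjusted pairwise comparisons via the studentized-range distribution
evaluated with scipy.

## Model fitting

Three free parameters — k_noise, τ_noise, Te — are fitted by trust-region
nonlinear least squares (scipy `least_squares`, log-parameter space with
bounds, so positivity holds by construction) on residuals

    r(g, f) = √(1/f) · (S_target(g, f) − S_sim(g, f)),

stacked over the 160 in-band frequencies and all gain conditions of the
target's mean *velocity* spectra; position spectra are comparison output
only. Each objective evaluation simulates the full battery with a fixed
seed, so the objective is deterministic and repeated evaluation is
bit-identical. Each gain condition uses an independent noise realisation
derived from that seed — as in the experiment, where conditions carry
independent sway noise — which lets the objective average Monte-Carlo error
across the nine conditions. Divergent simulations contribute constant
penalty residuals (10³ × the largest target PSD value) so the optimiser
retreats smoothly from infeasible regions. Multi-start is supported and all
(start, converged-to) pairs are recorded.

Routine fitting and the recovery experiments run at 410 s per condition
(ten 40-s segments after the 10-s discard); the full 2810-s protocol is a
parameter away (`duration=2810`). With a matched noise realisation the
objective vanishes at the truth and recovery is exact to optimiser
precision. With an independent target realisation at 410 s, Te is recovered
within ~10%, while the noise gain and filter constant carry larger,
strongly anticorrelated errors (median ~25–30%, favourable realisations
< 10%): above the noise corner 1/(2πτ) ≈ 0.11 Hz the sway spectra constrain
mainly the combination k²/τ, and at ten segments per condition the
periodogram noise at the band's low edge leaves a genuine k–τ ridge — the
minimiser of a finite-duration objective can sit measurably off the truth.
This is estimator variance, not an optimisation failure (verified by
comparing the objective at the truth against the converged point and by
uncapped re-optimisation), and it shrinks with the protocol's duration.

## Synthetic experiment generator

The generator emulates the study design: 14 subjects × (9 gains + no-touch)
× 5 trials × 50 s at 120 Hz, first 10 s discarded, robot position =
G × trunk position delayed by 60 ms. Per subject, stature (h, m, with
J ∝ m·h²) is jittered log-normally (σ = 5%, ≈ ±10% at 2σ) and noise gain
log-normally (σ = 10%); controller gains scale with the subject's m·g·h.
Hand force is a minimal delayed linear coupling: AP force =
−stiffness × (hand–body displacement delayed by lag_s) + a static contact
vector (0.4 N) + low-pass noise; off-axis components carry baseline + noise
only. Defaults (stiffness 8 N/m, lag 0.55 s) reproduce the intended
structure as measured by the pipeline itself: trial-mean |F| < 1 N in
≥ 99% of trials, positive force–position peak correlation below gain +1
with reversal at +2, and peak lags inside 0.4–0.7 s for gains ≤ 0.5.
No-touch trials run with w_touch = 0 and baseline + noise force channels so
condition tables stay complete.

What the generator does **not** emulate: grip mechanics and grip-force
modulation, frontal-plane dynamics, multi-segment kinematics,
non-stationarity (fatigue, adaptation), and perceptual/cognitive effects.
Passing pipeline tests on this synthetic set therefore demonstrates the
*internal consistency* of model + pipeline + statistics, not agreement with
human data; absolute sway magnitudes are a configured choice
(≈ 4 mm RMS at G = 0), not an empirical claim.

## Numerical choices and degenerate inputs

* Exact ZOH discretisation of the noise filter:
  n[k+1] = a·n[k] + (1−a)·k_noise·w[k], a = e^(−dt/τ); derivative
  (k_noise·w[k] − n[k])/τ. Stationary s.d. has the closed form
  (1−a)·k_noise/√(1−a²), used as a test oracle.
* The linear-limit cross-check evaluates the *exact discrete* transfer
  function of the implemented loop (semi-implicit integrator, integer-step
  delay, ZOH noise filter) rather than the continuous-time idealisation,
  so the comparison is limited only by periodogram averaging.
* Unbiased cross-correlation normalisation can push |R| marginally above 1
  at extreme lags (documented property of the 1/(N−|k|) edge factor).
* Zero-variance inputs to correlation raise a dedicated error; non-finite
  states or torques raise an invalid-numeric error; empty integration
  bands, non-uniform sampling and short series raise configuration errors.
* Tukey p-values are computed to scipy's studentized-range precision
  (≲ 1e-6), validated in tests against published 5% quantiles.

## Known limitations

* Sagittal plane only; single-segment body.
* The controller parameter set is a defensible choice, not an estimate;
  only the noise pair and Te are fitted, since plant/controller dynamics
  are not identifiable from spontaneous sway alone.
* Conflict-threshold estimates depend on the subtraction mode and on the
  position-cue correction rule; both are configuration, and fitted Te
  values should be reported together with them.
* At 410 s the spectral objective retains visible Monte-Carlo noise; fits
  intended for interpretation should use the 2810-s protocol and several
  noise realisations (the multi-start and dispersion machinery supports
  this).
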