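# Methods

`fusionddm` models rapid two-alternative decisions about two briefly flashed,
opposite vernier stimuli ("feature fusion"): stimulus 'A' followed immediately
(or after a blank gap) by stimulus 'B' with the opposite offset.  The paradox
the model addresses is that for equal stimulus durations the *second*
stimulus dominates the percept, the more so the longer both stimuli last —
the opposite of what classical one-stage accumulator models predict.

## The two-stage model

**Input.**  A trial is a piecewise-constant signed signal u(t): +1 while 'A'
is shown, −1 while 'B' is shown, 0 otherwise.  Time is continuous, in
milliseconds; segment intervals are half-open [start, end) so u is
single-valued at transitions.  Stimulus geometry (offset sizes, contrast) has
no computational role and is not represented.

**Stage one — leaky integration.**  The delayed input is integrated by a
noise-free leaky integrator

    dE/dt = (u(t − δ) − E) / τ,   E(0) = 0,

with leak time constant τ and sensory delay δ.  The fixed point under
constant input u is u itself, so E is bounded in [−1, 1]; any input gain is
absorbed into the drift scaling k of the next stage.  Because u is piecewise
constant, E has an exact piecewise-exponential closed form, which is what
the implementation evaluates (no ODE solver in the production path; a
fixed-step fourth-order integrator serves as the independent oracle in the
tests).  The leak is the ingredient that produces second-stimulus dominance:
for a fused equal-duration pair the buffered evidence is

    E(t_off) = −(1 − e^(−d/τ))²,

negative (favouring 'B') and growing in magnitude with the common duration d.

**Buffering and the decision-stage onset T2.**  At stimulus termination
(plus δ) the integrated evidence is frozen — "written into a buffer".  The
decision stage starts at a fixed time T2 after stimulus onset, not at
stimulus offset:

* stimulus ends before T2 → the buffered value k·E(t_off) is the constant
  mean drift of the decision stage;
* stimulus outlasts T2 → the momentary k·E(t) drives the decision stage from
  T2 until the offset, after which the drift stays frozen.

A fixed T2 is what keeps mean reaction times flat across total stimulus
durations of 20–80 ms (an offset-triggered start would add the stimulus
duration to the reaction time); the harness test suite checks both sides of
this contrast.

**Stage two — Ratcliff drift-diffusion.**  A decision variable X starts at z
between absorbing boundaries 0 (choice 'B') and a (choice 'A') and follows
dX = v(t) dt + σ dW.  Across trials, z and the non-decision time t_nd are
uniform (mean ± width/2) and a Gaussian offset with standard deviation η is
added to the drift once per trial (drawn once and applied uniformly in time,
also when the drift profile is time-varying).  The reaction time is
t_nd + first-passage time; t_nd absorbs T2, buffering and motor delays.
Deadline trials (no crossing by t_max) are reported as 'none' and logged,
never resampled.

The diffusion coefficient σ is an explicit parameter (default 1 in boundary
units per √ms).  Conventions for σ differ across the literature, and fixing
one scale explicitly is what makes a, z, v, η identifiable; fitted values
are in σ-relative units.  The millisecond-realistic synthetic observer uses
σ² = 1.2·10⁻³ per ms (the σ = 1 per √s convention expressed in ms), which
puts first-passage times in the hundreds of milliseconds.

**Novelty trigger.**  The moment of buffering is set by a Bayesian change
detector rather than by fiat.  Two observation channels are sampled every
`dt` from the noise-free signal with independent Gaussian noise (sd
`obs_sd`): a signed channel feeding a three-hypothesis {A, B, blank}
posterior (with per-step change hazard h), and a *presence* channel (|u| +
noise) feeding the novelty signal

    N(t) = 1 − (1−h)·p(y | persist) / [(1−h)·p(y | persist) + h·p(y | alt)],

where "persist" is the running maximum-posterior presence hypothesis and
"alt" the other presence level.  N crosses 1/2 exactly when a change of
presence is the better prior-weighted explanation of the current sample.
The hazard weighting matters: an unweighted likelihood comparison sits at
N = 1/2 under steady stimulation whenever an alternative shares the same
observation mean, so a threshold of 0.5 would chatter on noise.  With the
defaults (h = 0.01/ms, obs_sd = 0.2, threshold 0.5, dt = 1 ms) the event
counts of the canonical schedules are deterministic in practice: a fused
A→B pair yields exactly two events (onset of 'A', termination of 'B') — no
event at the direct A→B transition, which is why the two verniers fuse —
while inserting a blank gap adds events at the termination of 'A' and onset
of 'B', which is why a 20 ms gap makes the verniers individually visible.
`buffer_time_from_novelty` picks the first event at which the schedule has
entered a blank.

## Reference (one-stage) models

All share stage two's noise and boundary conventions, so contrasts isolate
the integration architecture:

* **Standard one-stage**: v(t) = μ·u(t−δ), zero after stimulus end.  For
  equal pairs the first stimulus dominates, increasingly with duration.
* **Leaky one-stage (OU)**: dX = (μ·u − λ(X − z)) dt + σ dW.  The leak
  attracts toward the trial's starting point z (not toward 0) — the
  distinction matters when z ≠ a/2 — and therefore pulls X back toward the
  start but never across it: the first stimulus still dominates.
* **Leak-off variant**: leaky dynamics while the stimulus is on; at offset
  the leak is removed and the accumulated value is the *initial condition*
  of a free unbiased diffusion.  This does produce second-stimulus dominance
  at intermediate durations, converting to first-stimulus dominance for long
  ones.  Its mean state at offset is the stage-one closed form scaled by
  μ/λ with time constant 1/λ, which the tests exploit via the martingale
  identity P('A') = E[X_offset]/a of the unbiased post-offset diffusion.
* **Preprocessed one-stage**: v(t) = k·E(t) applied from δ onward with no
  buffer and no T2 gate.  The net drift integral of an equal pair is exactly
  zero (∫E dt = ∫u dt), so any first-stimulus dominance is an
  early-absorption effect — present whenever decisions fall inside the
  positive-E phase, absent the second-stimulus dominance of the data.

The difference between "integrated evidence as initial condition" (leak-off
variant) and "integrated evidence as drift" (two-stage model) is the
package's central architectural contrast.

## Fitting pipeline

**Signed reaction times.**  Per condition, 'B' decisions are encoded as
negative and 'A' decisions as positive reaction times, so both response
channels form one distribution per condition.

**Objective.**  The fit quality of a parameter set is the product over
conditions of two-sample Kolmogorov–Smirnov p-values between the data and a
model-simulated sample, *maximised* over the free parameters.  Model samples
use fixed nested seeds per condition (common random numbers), making the
objective deterministic for the optimiser.  The p-value uses the asymptotic
Kolmogorov distribution with the classical finite-sample correction
(en + 0.12 + 0.11/en).  At n = 400 the p-values under the null are
approximately uniform but conservative (the D statistic is discrete); the
deviation is one-sided toward larger p, so the objective never over-rejects.
Degenerate evaluations (a condition with no decided model trials) score 0.

**Optimisers.**  `fit_decision_stage` is a bounded Nelder–Mead simplex on
the summed log p-values with random restarts; any decision-stage field can
be freed, shared or per-condition (`drift:<label>`, `eta:<label>`).
For the common case of per-condition constant drifts with shared
decision-stage parameters, `fit_free_drifts` is a specialisation of the same
objective: one library of model samples (one entry per drift on a grid, all
entries sharing one seed so the objective varies smoothly in the drift)
serves every condition, and each condition's estimate is the vertex of a
quadratic fitted to the log-p peak region (all contiguous grid points within
2 log units of the maximum).  Averaging over the peak, rather than
interpolating three points, measurably reduces estimator noise.  Bootstrap
standard errors re-fit resampled data against the same library.

**Stage-one recovery.**  Given per-condition fitted drifts v_c, (τ, k) are
recovered by least squares against k·E(t_off; τ): τ is scanned on a grid
(1–200 ms, step 0.5 ms) with k solved in closed form per τ (regression
through the origin).  At least three distinct schedules are required.
Under independent Gaussian drift noise across the 12 conditions of the
duration-sweep design, the recovery simulations in the test suite show τ
lands within 20% of truth in ≈98% of replicates at noise sd 1·10⁻⁴
(≈5% of the drift range) but only ≈60% at twice that noise — the two-step
procedure is usable exactly because the KS drift fits at 400 trials per
condition sit near the lower noise level (measured RMSE ≈ 1.2–1.6·10⁻⁴).

**Calibration to dominance levels.**  With a symmetric start (z = a/2) and
no across-trial variability the constant-drift hit probability is logistic
in the drift, P('A') = 1/(1 + e^(−v·a/σ²)), so two observed equal-duration
dominance levels determine (τ, k) exactly; more are fitted by least squares
(`calibrate_stage_one_to_dominance`).

**T2 line scan.**  For each candidate T2, the full two-stage model is
simulated per condition (common random numbers across the grid) and the mean
squared error against observed per-condition dominance is minimised (ties →
smallest value; grid values at or below δ are infeasible and skipped).  Only
conditions whose stimulation outlasts T2 constrain it, so the scanned design
must include long totals.  At 400 trials per condition the observed
dominance is too noisy to localise T2 to ±10 ms; the recovery check
therefore uses 10⁴ trials per condition, at which the scan returns the
generating 100 ms exactly in the seeded runs.

**Free vs predicted drifts.**  `compare_drifts` is a two-way
repeated-measures ANOVA (variant × condition, observers as subjects)
returning the variant main effect.  When the per-subject variant differences
have zero spread the RM error term vanishes and the F ratio degenerates
numerically; since the 2-level variant effect equals a paired t-test on
subject means, that case is resolved analytically (identical grids → F = 0,
p = 1; constant nonzero shift → p = 0).

## Synthetic observers and what they do (not) show

The human data of the original experiments are not deposited, so the
harness generates synthetic observers from the two-stage model itself.  The
default observer uses τ = 20 ms, k = 1.2·10⁻³ per ms, δ = 30 ms, T2 =
100 ms, a = 1, z = 0.5 ± 0.05, η = 2·10⁻⁴ per ms, t_nd = 350 ± 50 ms,
σ² = 1.2·10⁻³ per ms.  These values were chosen to be jointly realistic:
equal-duration dominance near the observed 60%/67%, median reaction times
near 500 ms (the boundary used for the fast/slow responder split), and under
1% of trials outside the 300–1200 ms analysis window (the published filter
excluded <3%).  The designs mirror the experiments: ratios 1:1/4:1/1:4 at
totals 20/40/80/160 ms; a 12-step sweep of the first-vernier duration over
[0, 40] ms at fixed total 40 ms (equally spaced including both endpoints —
the original spacing is not printed); 10 ms verniers with a variable blank
gap; 400 repetitions per condition.

Passing tests on these observers demonstrate *internal* consistency —
correct simulation, estimator behaviour at the experimental data scale, and
the qualitative contrasts between architectures.  They cannot demonstrate
that real observers obey the model: synthetic data contain no lapses, no
motor errors, no sequential dependencies, no learning or fatigue, and their
across-trial variability is exactly the Ratcliff form.  Published
per-observer quantities (individual reaction-time quantiles, the exact
fast/slow group shapes) are therefore not reproduction targets.

## Numerical choices

* **First-passage simulation.**  Euler–Maruyama with a Brownian-bridge
  absorption check: after each step, the probability that the within-step
  bridge touched a boundary, exp(−2(b−x₀)(b−x₁)/(σ²Δt)), is evaluated and a
  crossing drawn accordingly (skipped when it underflows, i.e. beyond
  ~e⁻³⁰).  For piecewise-constant drift the Gaussian step is exact in
  distribution, so the bridge check removes the leading O(√Δt) bias of naive
  Euler first-passage simulation (a boundary shift of ≈0.583·σ√Δt per
  boundary, several binomial standard errors at the simulation sizes used
  here); the residual error is the exponentially small probability of
  crossing both boundaries within one step.  A dt-halving test bounds the
  residual bias.  Default Δt = 0.1 ms (0.25 ms for the millisecond-scale
  observer, 0.01 ms for the σ = 1 reference runs), t_max = 5 s.
* **Drift sampling.**  Time-varying profiles are sampled at step midpoints;
  after the freeze time the buffered constant is used directly, so buffered
  conditions cost no profile evaluations.
* **Reaction-time resolution.**  Crossing times are recorded at the end of
  the step, so reaction times carry a +Δt/2 average offset — negligible
  against non-decision-time widths but accounted for in the mean-decision-
  time test tolerance.
* **Problem sizes.**  Dominance and slope checks use 10⁵ trials per point
  (binomial SE ≈ 0.16%); hit-probability oracle checks use 20 random
  parameter sets at 10⁵ trials, Δt = 0.05 ms; the recovery study runs 10
  replicates of 12 × 400 trials with a 61-point drift grid and 2·10⁴-trial
  model libraries; the T2 scan uses 10⁴ trials per condition both in the
  data and per grid value.  These sizes make the statistical assertions
  sharp while keeping the full suite runnable on a single CPU.
* **Seeding.**  Every public simulation takes an explicit integer seed;
  nested seeds are derived with fixed affine maps and kept below 2³¹.  The
  numba kernels seed NumPy's legacy generator internally, so identical
  seeds give bit-identical trial tables.

## Known limitations

* No analytic first-passage densities for time-varying drift (empirical
  CDFs by simulation are the intended fitting device); no collapsing bounds
  or urgency signals.
* The KS p-values are asymptotic and conservative at n = 400; objective
  *values* are therefore not comparable across very different sample sizes.
* The two-step (drifts → τ, k) estimator is near its noise ceiling at 400
  trials per condition: τ recovery within 20% holds in ≈93% of replicates,
  not always.
* The novelty detector is a deliberately simple re-specification (hidden
  presence state, Gaussian observations); it reproduces the qualitative
  event structure but is not fitted to data, and its posterior output is
  diagnostic only.
* One-stage refutation grids cover drift magnitudes μ ∈ [0, 2.45] per ms at
  the σ = 1 scale; the qualitative conclusion is insensitive to the range
  because dominance is monotone in μ for these designs.
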