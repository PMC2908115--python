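# Methods

`cpface` re-implements, as a tested and reusable pipeline, the statistical
machinery of presentation-time psychophysics studies comparing congenital
prosopagnosia (CP) participants against age-matched controls: adaptive
threshold estimation, constrained psychometric fitting and inversion,
nested mixed-model ladders with likelihood-ratio tests, and normative
residual ("abnormality") scoring.  Because participant-level data of such
studies are rarely deposited, the package ships a synthetic cohort
generator that reproduces the statistical structure all downstream stages
assume, so every stage is exercised end to end without any download.

## Adaptive staircase (accelerated stochastic approximation)

Presentation times evolve by

    x_{n+1} = x_n − c / (2 + m_n) · (z_n − φ)

with answer z_n ∈ {0, 1}, target fraction φ = 0.80, initial step constant
c, and m_n the number of shifts in the answer sequence (correct↔incorrect),
counted from the second answer on.  A correct answer shortens the next
presentation, an error lengthens it by a four-fold larger step (0.8c′ vs
0.2c′), so the equilibrium proportion correct is φ.  Defaults x₀ = 200 ms
and c = 100 ms are mandatory configuration keys.  An upper clamp at
2000 ms guards against divergence for near-chance observers; clamp events
are counted on the run.

Durations are physically realizable only as whole monitor frames
(5 ms at 200 Hz, ≈5.88 ms at 170 Hz); the presented time is the nearest
frame count with a one-frame floor.  The recursion itself carries the
**unquantized** value.  This is deliberate: if the recursion is run on the
quantized duration, the shrinking correct-answer step eventually falls
below half a frame and is rounded away while the larger error step still
registers — the run is absorbed several frames above threshold (we measure
≈92% final-16 accuracy instead of 80%).  With the raw-value recursion the
same simulation yields 80.6%.

The threshold estimate (PT80) is the arithmetic mean of the presented
(quantized) times of the last 16 trials.

## Psychometric model and PT90 inversion

Correctness as a function of presentation time x is

    p(x) = γ + (1 − γ − λ) · F(x),   F(x) = 1 / (1 + exp(−β(x − α)))

with the guess rate γ fixed by the design (0.5 for 2AFC, 0.25 for 4AFC),
a free lapse rate 0 ≤ λ ≤ 0.05, and positivity constraints α > 0, β > 0.
The inner curve runs on the linear-ms scale by default (a positive
location constraint is only meaningful on a scale where the location is a
time); log-ms is available by configuration.  Fitting maximizes the
Bernoulli log-likelihood with multi-start L-BFGS-B (8 deterministic
starting points plus the best point of a dense grid — seedless and
reproducible); the convergence flag requires a small projected gradient.
Degenerate data (all answers identical) return a flagged boundary fit
rather than raising.  Confidence intervals for α come from the profile
likelihood (χ²₁ cutoff) rather than the bootstrap.

Criterion inversion is closed-form: x* = α + logit((p − γ)/(1 − γ − λ))/β,
raising a descriptive error when the criterion lies outside (γ, 1 − λ).
The 90% criterion (PT90) mirrors the rotation experiments, which raise
the target from 80% to 90% to avoid floor effects on rotated views.

A caution surfaced during validation: fitting a *single* long staircase
run overestimates β, because the adaptive rule concentrates samples at
the 80% point and couples placements to previous answers; the inverted
PT90 then lands at ≈88% true accuracy.  The closed-loop benchmark
therefore generates its 500 trials as 16 restarted runs (~31 trials
each), whose descending limbs repeatedly sample the upper range; the loop
is then unbiased (mean ≈89.7%, single-replicate sd ≈2.2 points).  The
benchmark reports the mean over 12 replicates for stable precision.

## Preprocessing

Reaction-time analyses keep feedback-training trials, drop the very first
training block (task familiarization), keep correct answers only, and
dismiss reaction times *above* 2000 ms or *below* 500 ms — values exactly
at a bound are kept (the original convention is unstated; ours is fixed
and logged).  Experiments 5 and 6 use 500–8000 ms and 500–4000 ms presets.
Rules apply in a fixed precedence (malformed → pool → phase → first block
→ correctness → RT bounds) with per-rule audit counts that reconcile
exactly with the input count; filtering is idempotent.  Reaction times
enter linear models as −1/RT (seconds), threshold estimates as
mean-centered natural logs.

## Mixed-model ladders and LR tests

Each experiment is analyzed with a nested ladder: a nullmodel with age
and the experimental covariates plus participant random effects, then a
group main effect, then group-by-covariate interactions.

* Experiments 1/2, −1/RT (Gaussian): fixed intercept + age + block;
  random intercept and block slope with unstructured 2×2 covariance;
  ladder +group, +group×block.
* Experiments 1/2, log PT80 (Gaussian, one observation per participant):
  fixed intercept + age; ladder +group.
* Experiments 3/4, accuracy (binomial-logit): fixed intercept + age +
  |rotation| (nominal: 0/30/60/90, so ±30° share a level) + centered log
  presentation time; random intercept; ladder +group, +group×PT
  ("PT interaction"), +group×PT+group×rotation ("full interaction").
* Experiments 5/6, accuracy: intercept + age + centered log PT; random
  intercept; ladder +group, +group×PT.

All fits use maximum likelihood (never REML) so LR tests on fixed effects
are valid.  Gaussian mixed models are fitted with statsmodels MixedLM
(OLS when no random effects); the binomial random-intercept GLMM
maximizes the exact marginal likelihood via adaptive Gauss–Hermite
quadrature (15 nodes, conditional mode and Laplace curvature per
participant; validated to 1e−6 nats against direct numerical
integration).  Group coding is control = 0, CP = 1, so positive
coefficients on −1/RT mean slower CP responses.

Nested models are compared by χ² LR tests with df equal to the
parameter-count difference; the statistic is clipped at zero, and the
test refuses non-nested specs, non-converged fits, and fits whose
order-independent data fingerprints differ.  The χ² reference is known to
be mildly anti-conservative for fixed effects in mixed models; the type-I
simulation below quantifies this.  Interaction estimates carry Wald
intervals from the ML covariance (a Bayesian refit is out of scope).

## Normative residual scoring

The nullmodel is fitted to control observations only; each participant's
abnormality score is the average difference between their observations
and the *population-level* prediction (fixed effects only, random effects
zeroed — the "hypothetical average control with the same covariates").
CP participants are scored against the all-controls reference; every
control is scored against a reference refitted without them
(leave-one-out), warm-started from the full fit with convergence
re-verified.  For binomial models the default score is on the link scale,
logit(clipped empirical accuracy) − mean linear predictor; a
response-scale switch exists.  Scores are compared with Wilcoxon
rank-sum tests (exact permutation branch for combined n ≤ 30 without
ties, normal approximation with continuity and tie correction otherwise)
and paired contrasts with Wilcoxon signed-rank (exact for ≤ 25 nonzero
differences).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed once:

| quantity | default | rationale |
|---|---|---|
| cohort | 16 CP + 2 matched controls each | two controls per CP, same age cluster and monitor |
| age clusters | N(23, 2²) and N(54, 9²), weights ½/½ | a younger and an older subgroup |
| control threshold | lognormal, geometric mean 20.9 ms, sd 0.25 log-units | centered on the control median PT80 scale |
| age slope | +0.006/yr on log-threshold | mild slowing with age |
| CP multiplier | 1.6 | ratio of group median thresholds (34.2/20.9) |
| psychometric slope | β = 0.1/ms × lognormal(0, 0.2) jitter | thresholds ~tens of ms |
| lapse | 0.02 | attentive adult observers |
| rotation penalty | 0.8 log-odds per 30° step, equal across groups | rotation hurts both groups alike by default |
| −1/RT model | intercept −2.0 s⁻¹ (500 ms), age +0.008, block −0.04, CP shift +0.5 | practice speeds responses; CP slower on faces |
| random effects | intercept sd 0.2, block-slope sd 0.03; residual sd 0.3 (all 1/s) | participant-level variation |

Reaction times are drawn by adding Gaussian noise on the −1/RT scale and
rejecting draws outside (0, 20 s) (cap 1000 redraws).  Shoe-task
thresholds are drawn from the control distribution for *all* observers
and the CP reaction-time shift is not applied on shoe trials, so group
differences are face-selective by construction.  Trial templates follow
the six experiment designs (feedback training to criterion with a
three-round minimum, staircase test blocks of 8 with 4 targets each,
2×56-trial rotation blocks for faces and 4×24 for shoes, 192
Latin-square-counterbalanced 4AFC trials, 12 cycles of 8 training + 32
duration-balanced test trials).  Matched controls receive the same
stimulus ordering streams as their CP participant.  Unlimited
presentation is encoded as a missing value, not a large number.
Experiments 5/6 always run at 200 Hz; experiments 1–4 on the
participant's monitor (170 or 200 Hz).

What the generator does *not* emulate: real stimulus content (stimuli are
abstract tokens), gaze behavior, learning within the test phase,
sequential dependencies in accuracy beyond the staircase itself,
heavy-tailed RT contamination beyond the rejection bounds, and any
featural-vs-holistic mechanism.  Passing tests therefore demonstrate the
correctness and calibration of the *statistical machinery* under its own
assumptions, not conclusions about real CP cohorts.

## Operating characteristics (computed by the test suite)

* Staircase: 500 simulated 64-trial runs average 80% ± 3 points correct
  over the final 16 trials; fixed answer sequences reproduce a hand
  recursion exactly.
* Closed loop: inverting the fitted model at 90% yields 90% ± 3 points
  empirical accuracy (12-replicate mean).
* Oracles: exact Wilcoxon branches equal full enumeration for all group
  sizes ≤ 8; the psychometric MLE dominates a dense 50×50×5 grid; the
  binomial GLMM log-likelihood agrees with a 51-node quadrature within
  1e−4 nats.
* Calibration: the group main-effect LR test (10+20 participants × 24
  trials) and the one-sided rank-sum on threshold residuals (16 CP vs 32
  controls, 64-trial staircases) hold type-I error within [0.03, 0.08] at
  nominal 0.05 over 400 null replicates; power at a doubled CP threshold
  exceeds 90% over 200 replicates.  These problem sizes were chosen as
  the smallest at which the operating characteristics are stable.
* Recovery: Gaussian LMM fixed effects within 3 SE; median relative error
  of the psychometric location below 10% over 200 datasets.

## Known limitations

* The binomial GLMM supports random intercepts only (as the analyses
  require); crossed stimulus effects are out of scope.
* Link-scale binomial residuals clip empirical accuracies of 0 or 1 to
  half a trial, which compresses extreme scores.
* The LR χ² reference is asymptotic; with very small cohorts the
  simulated type-I error sits at the upper edge of the nominal band.
* MixedLM occasionally reports boundary variance estimates on small null
  cohorts; such fits are flagged and excluded from LR tests rather than
  silently used.
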