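# Methods

## Task model

Outcomes are drawn per trial from Normal(μ_t, σ_N²) on a 0–100 scale, with
σ_N = 3.33 (low noise) or 8.33 (high noise). The generative mean μ_t is
piecewise constant: on each trial after the first it resets, independently
with hazard H = 0.125, to a fresh uniform draw. A session comprises 4 runs
of 70 trials, two per noise condition, condition order randomized.

Two choices depart deliberately from the loosest reading of the task
description:

- **Mean support.** New means are drawn uniformly from [20, 80]
  (`mean_margin = 0.2`) rather than the full scale. Means near the
  boundary would force outcome truncation that distorts the realized
  outcome SD; the margin keeps truncation bias under 2% in both noise
  conditions (verified by simulation in the test suite). Setting
  `mean_margin = 0` restores the full scale.
- **Phase-count constraint.** A hazard of 0.125 over 70 trials implies
  ≈ 9.75 stable phases in expectation, which is inconsistent with the
  described 4–6 phases per run. Both regimes are therefore available:
  *unconstrained* mode is the pure hazard process (used for all
  hazard-rate checks), and *constrained* mode rejection-samples whole mean
  sequences until the phase count lands in [4, 6] (the default for cohort
  simulation, since it matches the experienced task). A configurable
  attempt cap turns an infeasible constraint into an explicit error. No
  minimum jump size between consecutive means is enforced.

Outcome truncation is by resampling, never clipping: clipping would put
point masses at 0 and 100 and corrupt SD-based checks.

## Reduced Bayesian observer

The observer maintains a belief mean B_t and relative uncertainty
τ_t ∈ [0, 1), the share of predictive variance attributable to belief
imprecision rather than outcome noise. On observing prediction error
δ_t = X_t − B_t:

- change-point probability (CPP) compares a uniform change likelihood
  against the Gaussian no-change predictive density:
  Ω_t = (H/W) / (H/W + (1−H)·φ(δ_t; 0, σ_pred²)), with
  σ_pred² = σ_N²/(1−τ_t). The predictive variance includes belief
  uncertainty; the variant with plain σ_N² is not offered because the
  τ-dependent form is the standard composition in the normative-model
  literature this observer follows.
- relative uncertainty updates as τ_{t+1} = N/(N + σ_N²), where
  N = Ω σ_N² + (1−Ω) τ σ_N² + Ω(1−Ω)(δ(1−τ))² mixes the single-sample
  posterior variance after a change, the decayed prior uncertainty absent
  a change, and the variance contributed by uncertainty about whether a
  change occurred.
- the learning rate composes both: α = Ω + (1−Ω)τ (`lr_form="standard"`),
  which is bounded in [0, 1] without clipping. The additive form
  α = Ω + τ + Ωτ is available as `lr_form="as_printed"` for sensitivity
  analysis; it exceeds 1 (e.g. 1.25 at Ω = τ = 0.5) and is clipped.

H and σ_N are the true generative values, not estimated per subject: the
analysis runs one fixed normative model per participant. τ resets to 0.5 at
each run start — a belief founded on effectively one observation — and is
configurable; whether carrying τ across runs would be more faithful is
unknowable from behavior alone, and run starts are also context breaks for
participants.

When conditioned on a subject, the subject's own prediction is the belief
mean in both the Ω computation and the τ update; excluded trials propagate
τ unchanged and emit missing Ω/α.

## Raw-behavior metrics

Learning rates are α_t = (B_{t+1} − B_t)/δ_t, clipped to [0, 1]; δ_t = 0 or
an invalid endpoint yields a missing value (such trials carry no
information about updating speed). Performance error is deviation from the
hidden mean, |B_t − μ_t|, with the signed value retained. TAC counts 1 on
each phase-start trial (including run starts) and increments within the
phase.

**Belief precision** is the effective sample size of the outcomes
integrated into the current belief. Each run starts with unit weight on the
founding belief; a trial with learning rate α gives the newest outcome
weight α and shrinks all existing weights by (1−α). Precision is
1/Σ w_k² over these sum-to-one weights, so a full update (α = 1) resets it
to exactly 1, α = 0 leaves it unchanged, and a constant α converges to
(2−α)/α. Because the founding belief counts as one integrated observation,
precision is bounded by 1 + (outcomes seen this run). The variant that
reports ESS − 1 (precision 0 after a full update) is available by flag;
the ESS form is this package's fixed definition of the measure and all its
internal checks are stated against it. Missing learning rates propagate
weights unchanged and yield missing precision for that trial.

**Exclusions.** Trials with RT > 3 s or no response are invalid; a run with
more than 25% invalid trials is dropped; a subject losing a run is excluded
(configurable policy).

## Synthetic cohort

Agents are generative mirrors of the first-level regression: the update is
U_t = w_pe·δ_t + w_cpp·Ω_t·δ_t + w_ru·τ_t·δ_t + Normal(0, noise_sd²),
computed against the observer trajectory conditioned on the agent's own
predictions, except on lapse trials where the update is exactly 0
(probability `p_lapse0`) or exactly δ_t (`p_lapse1`). This design makes
first-level recovery an identity check and separates pipeline bugs from
model misfit. Defaults: w_pe = 0.77, w_cpp = 0.08, w_ru = 0.07 (the group
coefficients the cohort emulates), noise_sd = 5, lapse probabilities 0.15
each — enough to reproduce the bimodal learning-rate histogram with modes
at 0 and 1 seen empirically. Lapses are excluded from the definition of the
"true" weights but not from analysis, so recovered weights are attenuated
relative to truth by design; the attenuation is documented behavior, not a
bug.

Questionnaire scores load linearly on a latent trait z ~ N(0, 1):
score_j = mean_j + sd_j·(λ_j z + ε_j), with instrument means/SDs and floors
set to the descriptive statistics of the population the generator emulates,
and residuals correlated at 0.3 among the three PLE components (PDI, ASI,
CAPS) to reflect their overlapping constructs; inter-trait correlations are
free parameters of the generator, not calibrated claims. The PLE composite
is the sum of the z-scored PDI, ASI, and CAPS. Scores are continuous,
floored/ceiled at instrument bounds; no item-level simulation. Default
trait-to-behavior links plant w_pe and w_cpp decreasing in z, mirroring the
negative trait associations the analysis is designed to detect.

The recovery benchmark cohort (`recovery_cohort_spec`) uses noise-only
agents (noise SD 2, no lapses) with wide weight spreads; the δ·τ regressor
is substantially collinear with δ within a session, so the w_ru spread is
set widest to keep its truth-correlation identifiable at 100 agents.

## Inference

First level: OLS of U_t on {δ, δΩ, δτ}, each mean-centered within subject,
intercept included; interactions use the **signed** prediction error
(signed updates cannot be predicted from sign-free regressors). Fits with
fewer than 30 usable trials are flagged unreliable and dropped from group
summaries. Second level: trait scores (z-scored) regressed on the three
unstandardized coefficients. The specificity panel runs one such regression
per questionnaire and applies Benjamini–Hochberg across the full family of
3 × 7 = 21 predictor-by-score tests. The binned learning-rate analysis
aggregates α over trials with |δ| > 50 and |δ| < 5 (configurable cutoffs)
and emits both regression directions, which share the t statistic.

Trajectory models (performance error or precision over TAC × noise ×
trait) are linear mixed models fitted by REML with a subject random
intercept and random slopes for TAC, noise, and their interaction. In place
of an exhaustive stepwise term search, a fixed fallback order is used: on
non-convergence or a singular random-effect covariance, random terms drop
in the order TAC:noise → noise → TAC, with a likelihood-ratio comparison
logged at each step; if nothing converges, a two-stage estimate
(per-subject OLS slopes regressed on the trait) is reported and labelled as
such. Noise is coded 0 = low, 1 = high.

Power: omnibus F of a k-predictor regression, numerator df k, denominator
df n − k − 1, noncentrality λ = f²·n, evaluated on the noncentral-F
distribution. At n = 300, k = 3, f² = 0.058, α = 0.05 this gives 0.950.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the tolerance checked: 10⁴–2×10⁵ draws for generator
SD/hazard rates, 100 agents for parameter recovery, a 300-subject cohort
with 500 outcome replicates for second-level type-I calibration and
detection-rate checks (the second level consumes only per-subject
coefficients and trait scores, so outcome replication does not require
re-simulating identical behavior), and 20 full-pipeline replicates for
planted-sign recovery. Ties and degenerate inputs resolve to missing
values, never silent defaults: zero-variance regressors, zero-variance
traits, and infeasible rejection sampling all raise.

## Limitations

- The full CPP/RU recursions are reconstructed from the normative-model
  literature the analysis follows; the source analysis prints only their
  roles. They are isolated in one module behind closed-form-tested
  operations.
- Synthetic agents are regression mirrors, not resource-rational learners:
  passing recovery tests demonstrates the pipeline's correctness, not that
  real participants satisfy the generative form. Real data enter only
  through the `reproduce` adapter.
- The exact supplementary formula of the original precision measure is not
  public; ESS = 1/Σw² is this package's fixed definition.
- The mixed-model term search is a documented fixed drop order, not an
  exhaustive stepwise search.
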