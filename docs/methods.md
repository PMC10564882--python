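# Methods

## The scientific question and the model

In the rubber hand illusion (RHI), stroking a visible fake hand in synchrony
with a participant's hidden real hand induces illusory ownership of the fake
hand; asynchronous stroking is the control condition. A long-debated claim
is that people with accurate heartbeat perception — high cardiac
interoceptive accuracy (CIA) — are less susceptible to the illusion.
`rhibayes` estimates the size of that modulation from single-item Likert
ownership ratings, one per participant per condition.

Because a Likert rating is ordinal, the outcome is modeled with an
ordered-probit (cumulative-probit) regression: a latent normally distributed
ownership intensity

    IHO*_i = (β₁ + r_i)·cond + β₂·CIA_i + β₃·cond·CIA_i + e,
    r_i ~ Normal(0, σ_r²),   e ~ Normal(0, 1),

is partitioned by K−1 strictly increasing cutpoints τ into the K observed
categories (`cond` = 0 asynchronous, 1 synchronous). The individual
synchrony effect — "illusion susceptibility" — is δ₁,ᵢ = β₁ + β₃·CIA_i +
r_i, so β₃ is the slope of an implicit regression of susceptibility on CIA
and r_i is its residual. Two structural choices follow from this equation
and from probit identification:

* **No intercept, fixed or random.** Location on the latent scale is
  absorbed entirely by the K−1 free cutpoints; adding an intercept would
  leave the likelihood invariant under a joint shift and destroy
  identification.
* **Latent residual SD fixed at 1.** The ordered-probit convention; all
  coefficients are in latent-SD units.

CIA enters on its raw 0–1 scale, uncentered. The standardized interaction
effect (below) is interpreted as the contrast between hypothetical CIA = 0
and CIA = 1 populations, which only makes sense on the raw scale.

K is declared by the user (7 for a −3..+3 item, 11 for a 1..11 item), never
inferred from the observed categories, so unobserved extreme categories
still get cutpoints and the model dimension cannot drift with sparse data.

## CIA scoring

The heartbeat tracking task yields three trials of recorded (`HB_rec`) and
reported (`HB_rep`) beat counts. Per-trial accuracy is
1 − |HB_rec − HB_rep| / HB_rec and CIA is the mean over the three trials.
The formula does not actually enforce the nominal [0, 1] range: reporting
more than twice the recorded count drives a trial term negative. Such
scores are retained and flagged rather than clamped (an optional clamp
exists for sensitivity checks), because silently truncating would hide a
data-quality problem. Trial durations are carried through the data model
but do not enter the score.

## Priors

Weakly informative defaults, all configurable via `PriorConfig` (YAML or
programmatic):

| block | default | notes |
|---|---|---|
| β₁, β₂, β₃ | Normal(0, 2.5) | latent-SD units |
| σ_r | half-Cauchy(0, 2.5) | alternatives: half-normal, half-t, exponential |
| each τ_k | Student-t(3, 0, 2.5) | heavy-tailed; ordering is enforced structurally, not by the prior |

The cutpoint prior family is our own choice (the ordering constraint is a
reparameterization, so any weakly informative location-scale density works);
Student-t(3, 0, 2.5) mirrors the scale of the coefficient prior with heavier
tails.

## Posterior computation

The built-in sampler is a self-contained adaptive random-walk
Metropolis-within-Gibbs scheme; no external probabilistic-programming engine
is required. Unconstrained parameterization: log σ_r; cutpoints as (τ₁,
log-increments); random slopes non-centered as r_i = σ_r·z_i with z_i ~
Normal(0, 1) (the centered form is available and agrees — a tested
invariance). Each sweep performs

1. a scalar Gaussian random-walk update of every global parameter, step
   sizes Robbins–Monro-adapted toward 44% acceptance during warmup;
2. one joint proposal of all globals using a Haario-style adaptive
   covariance (Welford-accumulated over warmup, scale adapted toward 23%
   acceptance) — this is what lets the sampler cope with the strong
   posterior correlations among β₁, β₃ and the cutpoints;
3. a vectorized independent Metropolis update of all z_i at once, exact
   because the z_i are conditionally independent given the globals, with
   per-participant adapted steps.

All adaptation freezes at the end of warmup, so the post-warmup chain is a
valid fixed-kernel Markov chain. Defaults follow the study protocol: 4
chains × 4000 iterations, warmup 2000. Per-chain random streams are spawned
from the master seed (`numpy.random.SeedSequence.spawn`), making runs
bitwise reproducible; chains run sequentially.

Category probabilities are floored at 1e−300 before logs (documented so the
quadrature oracle in the tests applies the same guard). Initialization:
coefficients and z at 0, σ_r at 1, cutpoints at standard-normal quantiles of
the pooled empirical category frequencies (clamped away from 0/1, ties from
empty categories separated by 1e−3), all jittered per chain; a chain retries
its jitter up to 10 times if the start is degenerate and errors otherwise.

Correctness of the sampler is established three ways in the test suite:
prior recovery (likelihood switched off, posterior quantiles must match the
closed-form prior quantiles — this exercises every transform Jacobian),
centered/non-centered agreement, and an end-to-end comparison against an
independent affine-invariant ensemble sampler (emcee) run directly on the
package's `log_posterior`.

## Diagnostics and summaries

R-hat is the rank-normalized split-chain variant by default (delegated to
`arviz.rhat`); the classic split-chain statistic is implemented in-package
(`method="split"`). The acceptance rule is R̂ ≤ 1.1 for all reported
parameters. Identical constant chains return 1.0 by convention. Parameter
summaries are posterior medians with 95% equal-tailed credible intervals;
the highest-posterior-density interval (shortest contiguous window of the
sorted draws containing ⌈0.95·M⌉ of them, ties to the leftmost) is used
only where the R² posterior's pile-up at 0 makes equal tails misleading.

## Effect sizes

* **Standardized β₃** = β₃/σ_r per draw (Cohen-d-like), summarized by
  median and 95% equal-tailed CrI.
* **Bayesian R²** per draw: V_fit/(V_fit + σ_r²) with V_fit the N−1 sample
  variance of the fitted susceptibility component β₃·CIA_i over
  participants. The residual variance is the *modeled* σ_r², not the
  empirical variance of the realized r_i draws — this is the reading of the
  Gelman-style definition that makes R² collapse to ~0 (with an HPDI lower
  bound at numerical zero) when β₃ ≈ 0; the empirical-variance alternative
  is available via `residual="empirical"`. Every per-draw value lies in
  [0, 1] by construction. Summarized by median and 95% HPDI.
* **Per-participant susceptibility** β₁ + β₃·CIA_i + r_i per draw;
  participants are classified by whether the 95% equal-tailed interval
  includes 0.

## Synthetic data

The generator draws exactly from the model: CIA_i from a configurable
distribution on [0, 1] (default Beta(5, 2.7), mean ≈ 0.65, right-skewed —
a realistic heartbeat-tracking score shape), r_i ~ Normal(0, σ_r), latent
responses η + Normal(0, 1) cut at the configured cutpoints (default for
K = 7: symmetric, unit-spaced −2.5..2.5). Default truth (β₁, β₂, β₃, σ_r) =
(0.5, 0.25, 0.33, 2.2) with N = 50 puts the generator in the weak-induction,
high-uncertainty regime of the primary study design. One rating per
participant per condition, matching the single post-block ownership rating.

The heartbeat-trial generator inverts the CIA formula: recorded counts from
a constant heart rate over the 25/35/45 s trial durations, reported counts
chosen as the integers whose per-trial accuracy is nearest the target
(under-reporting preferred on ties); integer rounding bounds the achieved
score within about 0.5/min(HB_rec) of the target per trial.

What the generator does **not** emulate: proprioceptive drift, stimulation
jitter and order effects, demand characteristics, item-to-item correlation
across the questionnaire, or measurement drift in the pulse signal. Passing
recovery tests therefore demonstrate that the estimator works when the
model is true; they say nothing about robustness to those violations.

## Problem sizes and test design

Batched simulation checks use reduced chain lengths (4 × 3000, warmup 1500)
and N = 200–500, sizes at which posterior medians are stable while a
10–20-replicate batch completes in minutes on one CPU; single-fit checks use
the full 4 × 4000 default. The quadrature oracle for the likelihood uses
`scipy.integrate.quad` at 1e−15/1e−13 tolerances so the oracle's own error
is negligible against the 1e−8 comparison.

## Known limitations

* With one rating pair per participant and CIA concentrated near its mean
  (spread of Beta(5, 2.7) ≈ 0.16 SD), `cond` and `cond × CIA` are nearly
  collinear: the marginal posteriors of β₁ and β₃ are strongly
  anti-correlated and individually wide (posterior SD of β₃ ≈ 0.5–0.7 even
  at N = 500). Point-estimate recovery of β₁/β₃ to tight tolerances is
  therefore data-limited, not sampler-limited — interval coverage is
  calibrated (tested), but medians can sit far from the truth on unlucky
  realizations. β₁ + 0.65·β₃ is what the data identify well.
* The random-walk sampler needs its full warmup for the adaptive covariance
  to learn these correlations; very short runs (≲ 4 × 1000) can leave
  R̂ ≳ 1.1 on the coefficients.
* Each questionnaire item is modeled separately; there is no joint
  multi-item model, no logit link, and no model-comparison machinery
  (LOO/WAIC) — out of scope by design.
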