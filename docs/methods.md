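# Methods

`oilab` implements a complete, testable pipeline for measuring
*outcome-irrelevant learning* — the reward-dependent tendency to assign
value to a response key that is known with certainty not to predict
reward — and its moderation by visual working-memory capacity. Because the
pipeline must be verifiable offline, a synthetic-cohort generator with
known ground truth stands in for human data; externally deposited
trial-level tables can be ingested through the same schemas.

## Task environment

The dual task is a restless four-card bandit interleaved with change
detection. Each block has 4 cards and 50 trials; on every trial the cards
are dealt without replacement into two successive two-card offers, and the
chosen card pays 0/1 with probability `p[card, trial]`. Each bandit trial
sits between the encoding and probe phases of a change-detection trial
whose array depends on the block's load condition: a block-fixed colour
(no load), one random colour (low load), or four distinct random colours
out of nine (high load). Six blocks, two per load condition, split across
two sessions. A standalone single-probe change-detection session (120
trials, set sizes 4 and 8, balanced same/different probes) measures
capacity.

Reward probabilities follow a Gaussian random walk with reflecting
boundaries. The walk parameters are configuration, with defaults
`step_sd = 0.025` per trial, bounds `(0.2, 0.8)`, uniform initialization
in `(0.3, 0.7)`: restless-bandit designs keep probabilities away from 0
and 1 so both outcomes occur for every card, and reflection (rather than
clipping) avoids probability mass piling up at the bounds. Walks are
drawn independently per subject; nothing downstream conditions on walks
being shared, and per-subject walks make cohort replicates exchangeable.
Screen geometry is abstracted to slot indices; presentation timing is out
of scope.

## Generative agents

The generator is the simplest mechanism that produces the measured
signature: a Rescorla–Wagner learner over cards coupled with a second
delta-rule learner over response keys,

    Q(chosen card) += alpha_card * (r - Q),   V(pressed key) += alpha_key * (r - V),

with choices by softmax over the additive value `Q(card) + V(key side)`,
`P(left) = logistic(beta * [(Q_l + V_left) - (Q_r + V_right)])`. With
`alpha_key > 0` a rewarded first offer raises the pressed key's value and
makes the same key more likely at the second offer — exactly the
stay/previous-outcome dependence the regression measures. Q starts at the
reward midpoint 0.5 and V at 0 so early choices are unbiased. Key values
reset between blocks by default (configurable), keeping blocks
exchangeable. This is a *generator*, not a claim about the human
mechanism, and it is never fitted to data.

Memory probes use a slot model: `min(kappa, N)` of the N array items are
encoded; an encoded probe is answered correctly, otherwise the agent says
"same" with probability `guess` (0.5), so accuracy is
`kappa/N + (1 - kappa/N)/2` — the exact inversion of the Cowan-K formula.
Kappa is continuous and used fractionally (integer slots are an optional
mode) to keep recovery curves smooth. Dual-task probes reuse the slot
model with set sizes 1 (low load) and 4 (high load); no-load probes need
no memory and are answered correctly up to a 6% lapse (a 94%-accuracy
ceiling, the observed regime for such blocks). Low-load accuracy is
therefore near ceiling for any `kappa >= 1` — an idealization; the
embedded capacity estimate is consequently driven by the high-load
probes.

Cohort defaults define the study conditions: 40 subjects;
`kappa ~ N(3, 1)` clipped to `[0.25, 7.5]` (the typical Cowan-K range);
`alpha_card ~ N(0.3, 0.1)`; `beta ~ N(3, 1)`;
`alpha_key = clip(0.3 - 0.08 * (kappa - 3) + N(0, 0.05), 0, 1)`, i.e. a
negative capacity link of 0.08 per memory item, strong enough that a
40-subject cohort identifies the moderation. Reaction times are lognormal
(`meanlog 6.55`, `sdlog 0.35`, clipped into the plausible 200–4000 ms
band) contaminated with fast (< 200 ms, probability 0.01 per offer) and
slow (> 4000 ms, probability 0.008) responses; together with the
first-trial drop this yields ~5.5% removed trials, the same regime the
filters are specified for. Contamination is injected independently of
choice quality, so the filter module never sees ground truth.

What the generator does *not* emulate: sequential effects in RTs,
perseveration that is independent of reward, attention lapses in the
bandit, load effects on choice (the load manipulation alters only the
memory arrays, by design), or any dependence of encoding on reward.
Passing recovery tests therefore show the estimator chain is correct and
calibrated for data of this structure — not that human data satisfy the
model.

## Data treatment

A trial is removed whole if it is the block's first trial or if either
offer's RT is strictly below 200 ms or strictly above 4000 ms (boundary
values are retained; the stay observation needs both offers, so the trial
is the filter unit). Missing RTs count as invalid. Removal fractions are
reported both per trial and per offer. Participants are excluded for (a)
below-chance (< 0.5) standalone set-size-4 accuracy, (b) more than 30% of
their own trials removed (evaluated after trial filtering, first-of-block
drops included), or (c) one response key on more than 80% of retained
offers — all strict comparisons.

Capacity is `K = N * (2 * accuracy - 1)` per set-size condition, averaged
across conditions; for balanced single-probe designs this equals
`N * (hit - false_alarm)` algebraically, which the tests verify on random
confusion tables. Negative K values are retained (informative for the
below-chance exclusion). The capacity covariate is z-scored across
included subjects with the sample (n−1) standard deviation. The
learning-accuracy covariate is the fraction of offers on which the chosen
card had the strictly higher true reward probability (ties excluded).

## Hierarchical Bayesian regression

Stay (key repetition across a trial's two offers) is regressed on the
first offer's outcome in a Bernoulli-logit mixed model. Four nested
models share the random-effects structure (subject-level intercept,
previous outcome, load, previous outcome × load — held fixed across
models even where fixed effects omit load) and differ in fixed effects:
null (previous outcome only), capacity, load, and full. Coding: previous
outcome centred at ±1/2, so its coefficient is the marginal group-level
effect; load as sum-to-zero contrasts of a three-level factor; capacity
z-scored. A flag adds the learning-accuracy covariate and its interaction
with previous outcome for the robustness analysis.

Priors are weakly informative and configurable for wider/narrower
sensitivity runs: Normal(0, 1) on fixed effects (appropriate for
binary/standardized predictors). The random-effect covariance uses the
Huang–Wand hierarchical inverse-Wishart with `nu = 2` and scale `A = 1`,
giving marginal half-t(2, 1) priors on the standard deviations and a
near-uniform correlation prior. This family was chosen over
half-Normal + LKJ because it is conditionally conjugate, which enables
the exact sampler below while keeping the same weakly-informative
character.

Sampling is a blocked Gibbs sweep under Pólya-Gamma augmentation
(`omega_i ~ PG(1, psi_i)` makes every conditional Gaussian): omega →
fixed effects → per-subject random effects → covariance → auxiliary
scales. The PG(1, z) draws use the exact alternating-series rejection
sampler (numba-compiled, ~0.3 µs per draw), so a full-scale fit (40
subjects, ~11,000 observations) takes seconds per chain. Defaults are 4
chains × 1000 post-warmup draws (tests and the acceptance script use 2 ×
~500, which keeps split-R̂ ≲ 1.02 at study scale); split-R̂ and bulk ESS
are computed on all fixed effects and a R̂ > 1.01 is warned about, never
silenced. Being a conjugate Gibbs sampler there are no divergences to
count. Pointwise log-likelihoods (conditional on the subject effects, the
convention of mainstream GLMM tooling) are stored per kept draw for
PSIS-LOO; stacking weights maximize the LOO log score over the simplex
and Pareto-k > 0.7 fractions are reported.

Summaries per coefficient: posterior median, 95% HDI (sorted-window
shortest interval, ties toward the lower start), probability of direction,
% of posterior inside the ROPE, a Savage–Dickey point-null BF10 (prior
density at 0 over a Silverman-bandwidth kernel estimate of the posterior
density at 0, capped and flagged beyond 10^4), a ROPE Bayes factor
(posterior vs prior odds of lying outside the ROPE), and the odds ratio
exp(median). The default ROPE is ±0.013 log-odds — the image of a
negligible effect size d = 0.007 on the stay probability via the logistic
sd π/√3. Marginal stay probabilities per outcome level are computed at
the covariate centre with random effects at zero (the typical-subject
probability).

The capacity–learning association is summarized by a Bayesian correlation
between per-subject posterior-mean previous-outcome coefficients and
capacity estimates: with the bivariate-normal nuisance parameters
marginalized under Jeffreys priors and a uniform prior on ρ, the posterior
reduces to the classical one-dimensional density
`p(rho | r, n) ∝ (1 - rho²)^((n-1)/2) (1 - rho r)^(3/2 - n)`, evaluated on
a grid and sampled by inverse CDF; a full 5-parameter MCMC fit is the
cross-check in the test suite.

## Calibration and recovery conventions

Null calibration aggregates over 10 replicate null cohorts: a single
replicate's probability of direction is ~Uniform(50, 100) under the null
(its expectation is 75 by construction), so the pipeline pools the
replicate posteriors with equal weight and requires the pooled pd to stay
below 75%, alongside a ≤ 10% rate of 95%-HDIs excluding zero. Moderation
recovery requires a negative interaction median in ≥ 9/10 linked-cohort
replicates and a group effect monotone in `alpha_key`. Model-comparison
self-consistency generates stay tables directly under the capacity model
(intercept 0.2, previous-outcome 0.6, interaction −1.5, random intercept
sd 0.25, residual random-slope sd 0.1) because conditional-likelihood
LOO separates nested mixed models only through shrinkage — with the
behavioural-agent defaults the weight split is a realistic ~60/40,
comparable to published stacking splits for this design.

## Problem sizes and numerical choices

Tests and the acceptance script run the full study geometry (6 × 50
trials, 40 subjects) with 2-chain, ~500-draw fits and 10 replicates per
calibration experiment — sizes at which every reported check is stable
under reseeding. Degenerate inputs fail loudly: zero-variance covariates,
subjects present in only one log, missing probe conditions, non-finite
design rows and non-binary outcomes all raise typed errors. HDI
computation requires ≥ 100 samples; constant samples give a zero-width
interval. The Savage–Dickey KDE is accurate (≲ 2%) when the null lies
within a few posterior sds of the bulk; far outside, the BF caps at 10^4
and is flagged rather than extrapolated.

The per-subject previous-outcome coefficient used in that correlation is
the posterior mean of the subject's full slope — fixed effect, plus the
fixed capacity-interaction contribution at the subject's capacity, plus
the subject's residual random slope. Because the residual slopes are
shrunk toward the model's regression line, the magnitude of the
resulting correlation depends on how much residual slope variance the
posterior retains; its sign, not its size, is the calibrated quantity.

## Known limitations

* The generator's effect sizes are deliberately larger than typical human
  effects so that 40-subject recovery experiments are decisive; absolute
  coefficient magnitudes are therefore not comparable to human data,
  only signs, orderings, and calibration properties.
* Embedded capacity uses low/high-load probes (set sizes 1 and 4); with
  near-ceiling low-load accuracy its scale differs from the standalone K.
* LOO uses conditional likelihoods; marginal (integrated-over-subjects)
  LOO would separate nested random-slope models more sharply but is not
  the convention this pipeline mirrors.
* The agent model is generator-side only; fitting reinforcement-learning
  models to data is out of scope by design.
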