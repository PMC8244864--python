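# Methods

`nestdecay` estimates how long great-ape nests remain visible in the
forest — the decay time that converts nest counts into ape counts — from
longitudinal nest-monitoring records, and probes when the cheap
single-revisit shortcut for the same quantity can be trusted. This note
documents the models, the estimators, the synthetic-data generator that
stands in for undeposited field data, and the numerical choices.

## The censored gamma survival model

Each monitored nest *i* has an observed age in whole days: for decayed
nests the days between construction and the day before the nest was found
fully decomposed (age class 5); for nests still recognizable at study end
the days to the censoring date, a lower bound on the true decay time.

Decayed ages follow a gamma distribution with shape `k_i = mu_i * theta`
and rate `theta`, so that `E[age_i] = mu_i` is the mean decomposition
time; censored nests contribute the survival probability
`1 - GammaCDF(age; k_i, theta)`. The mean is linked to categorical
covariates through a log link:

    mu_i = exp( sum_f coef_f[cat_f(i)] )

with one free coefficient per category of every included factor — forest
type F, exposure E, position P, construction type C, one of absolute (A)
or relative (H) nest height, lifetime rainfall W, lifetime storm rate S,
one of minimum (T) or differential (D) construction-day temperature,
construction-day rain R, and tree species Sp (the ten most frequent
species among single-tree nests plus an "other" category that also
absorbs all integrated nests).

Priors: `coef ~ Normal(0, 5)` on every coefficient and
`theta ~ Gamma(0.1, 0.1)` (shape/rate). `theta` is treated as a rate
throughout: the algebra `k = mu * theta` together with `mean = k / theta`
forces that reading.

**Identification.** There is deliberately no intercept and no reference
category, so adding a constant to all categories of one factor and
subtracting it from another leaves the likelihood unchanged (asserted to
machine precision in the tests). Raw coefficients are therefore not
interpretable; the package reports only identified quantities — per-nest
means `mu_i`, the cohort mean decay time, per-category decay summaries
(the empirical marginal of `mu_i` over the nests in the category),
within-factor contrasts in days, survival curves, and `theta`. How a
category's "average decay time" should marginalize over the other factors
is a genuine design choice; the empirical marginal over the observed
cohort was chosen because it needs no arbitrary baseline, at the cost of
mixing in the cohort's covariate composition.

## Posterior sampling

The posterior over (coefficients, log theta) is smooth and close to
Gaussian but extremely anisotropic: identified directions have curvature
of order 10^3 while the non-identified ridges are held only by the prior
(curvature 1/25). Sampling proceeds in two stages:

1. **Laplace preconditioning** — a MAP estimate by L-BFGS with
   finite-difference gradients evaluated through the batched likelihood,
   followed by a numeric Hessian and an eigendecomposition whitening
   transform.
2. **Independence Metropolis–Hastings** in the whitened space (the
   default sampler, id `laplace_imh`): the proposal is a fixed mixture of
   0.8 N(0, I) and 0.2 multivariate-t (5 degrees of freedom, scale 1.2)
   for tail insurance. The chain is exact MCMC whatever the quality of
   the Laplace approximation; a poor approximation only lowers the
   acceptance rate, which is recorded. Observed acceptance on full-size
   cohorts is ~0.6, giving an autocorrelation time of about two steps.
   64 independent chains advance in lock-step so each iteration is one
   vectorized likelihood evaluation.

An affine-invariant ensemble sampler (emcee, id `ensemble`, with
differential-evolution moves) is kept as an alternative engine and as the
generic MCMC used in the conjugate-posterior unit test. It mixes roughly
40× slower per step on this model and is not the default.

Two chains of 4,000 iterations (2,000 warmup) are the default regime;
each chain's post-warmup draws are thinned to `iterations - warmup`.
Convergence is checked with the rank-normalized split-Rhat (via ArviZ) on
identified quantities — the cohort mean decay and `theta` — with the
contract Rhat ≤ 1.01; violation warns, never passes silently. All
samplers are bit-reproducible given a seed; the log-theta coordinate
carries the Jacobian correction.

**Censored likelihood numerics.** The log survival uses the regularized
upper incomplete gamma function directly; where it underflows (ages far
beyond the mean) the leading terms of its large-argument asymptotic
series are used, avoiding the catastrophic cancellation of
`log1p(-CDF)`.

## Model selection (PSIS-LOO)

Pointwise out-of-sample predictive densities are estimated by
Pareto-smoothed importance sampling: per nest, the largest
`min(0.2 S, 3 sqrt(S))` raw importance ratios are replaced by expected
order statistics of a generalized Pareto distribution fitted to the tail
(delegated to `arviz.psislw`), weights truncated at the raw maximum. The
tail-shape diagnostic k-hat flags unreliable points above 0.7. ELPD,
p_loo, looic = −2·elpd and their standard errors are assembled from the
pointwise values; model comparisons report ELPD differences with SEs from
pointwise differences. The whole path is validated against brute-force
exact LOO (n refits) on small cohorts — agreement within the reported SE.

Covariate importance uses leave-one-covariate-out ablation (drop in
elpd_loo when a factor is removed), the four-way {A|H} × {T|D} candidate
comparison, and a posterior-correlation check between the identified W
and S category summaries (low correlation justifies keeping both rainfall
and storms despite their climatic dependence).

At n ≈ 30 a genuinely influential extreme age can push k-hat above 0.7
even for a well-specified model with several sparsely-populated cells;
the LOO oracle therefore runs on a homogeneous-mean cohort, where all
k-hat stay well below the threshold.

## The retrospective logistic estimator

A nest marked at construction and revisited once is Alive (1) if the
revisit precedes its known decay date, else Decayed (0). Logistic
regression of status on age at revisit gives
`P(alive at t) = logistic(a + b t)`, and the mean decay time is the area
under that curve, `log(1 + exp(a)) / (-b)` (softplus closed form; the
adaptive-quadrature cross-check agrees to < 0.1 day). Guard rails:
complete separation and single-status data raise; a slope above −1e−8
yields a NaN mean (no decay signal); b ≥ 0 has an infinite integral and
raises.

Revisit scenarios are derived from longitudinal truth: fixed offsets of
14 / 30 / 91 days after the *last* group was marked, 91 days after *each*
group was marked (snapped to a shared weekly field-visit calendar, which
is what spreads the realized ages over 91–97 days — without a shared
calendar this scenario has no age variation at all and is rejected), and
an independent uniform 7–360-day offset per group (per nest optional).
Censored nests whose censoring precedes the revisit have unknown status
and are dropped with a warning — a survivorship bias that grows with the
censoring rate and is one reason the retrospective estimate can sit below
the survival-model estimate.

Bootstrap CIs resample nest groups (nests in a group share construction
night and weather exposure; resampling nests would understate variance);
nest-level resampling is selectable. Failed replicates are recorded with
a failure taxonomy, never silently dropped. The subsampling experiment
analyses seeded random subsets of 75/50/25% of groups, ten draws each.

## The synthetic-data generator

The generator defines the study conditions under which everything is
tested. Defaults:

* **Climate** — daily records over two years (extendable); two dry
  seasons (February, May–August) via 12 monthly rainfall targets summing
  to ~1.8 m/year, seasonal wet-day and storm probabilities (~0.10–0.12/day
  in wet months, ~0.01 in dry ones); storms are planted as a single rain
  interval (evening c or night d) carrying 20 mm + Gamma(1.5, 10) on an
  otherwise sunny day, so the storm detector recovers planted storms
  *exactly* (a deterministic fix-up prevents ordinary wet days from
  accidentally qualifying); non-storm wet-day amounts are gamma draws
  calibrated so expected monthly totals track the targets; minimum
  temperature N(20, 1.5) °C, diurnal range N(6, 2) °C; an optional
  multiplicative yearly trend on non-storm rainfall (storm frequency held
  constant — the regime where a constant number of storms carries a
  growing share of a shrinking total).
* **Cohort** — 182 groups, Poisson(8.3) nests each (~1,500 nests),
  construction uniform over the marking window (default the whole study),
  weekly monitoring visits, censoring at study end (~14% under the
  defaults); true decay times gamma with `theta = 0.02` and a target mean
  of 95 days on the log scale (the cohort mean of `mu_i` lands near 100
  days after Jensen's inequality across the configured effects); factor
  categories drawn from probabilities matching a large field cohort's
  frequencies; true coefficients with the field-expected qualitative
  ordering (integrated < single-tree, side-branch < treetop, a strong
  non-monotone storm effect) — synthetic defaults, not estimates from any
  real dataset.

**What it does not emulate.** Lifetime rainfall (W) and storm-rate (S)
categories are assigned from probabilities rather than derived from the
simulated climate: the realized lifetime averages would depend on the
decay time being generated, a circularity real data shares but a
generator must cut. Construction-day covariates (R, T, D) *are* read from
the climate series when one is supplied, and nest heights feed A and H
through the same fixed cut-offs the coding module uses, so those paths
round-trip exactly. There is no spatial structure, no observer error in
age-class calls, and no within-group decay correlation beyond the shared
construction date.

**Observation-process bias, deliberately representable.** Weekly
discovery records age `7 * ceil(a/7)`, inflating the mean by ~3–3.5 days;
the paper's field protocol has the same property and ignores it. The
generator therefore stores, besides the continuous mean of `mu_i`, the
exact expected *observed* age `iv * sum_j S(iv * j)` per nest; recovery
checks cover the latter (the estimand the fitted model actually targets)
while both values are reported so the discovery-lag bias stays visible.
Setting the visit interval to 1 shrinks the bias to ~0.5 day for clean
oracle tests.

## Binning and coding rules

Continuous covariates are cut at fixed default boundaries (A: 13/23 m,
H: 0.8/0.95, W: 3/9 mm/day, S: 0.02/0.12 storms/day, T: 18/22 °C,
D: 4/8 °C) or at the data's mean ± 1 sample SD (n−1). Boundary ties go
to the extreme categories (Low is `x ≤ low`, High is `x ≥ high`); Medium
is open on both sides — the printed ranges of the field protocol overlap
at the boundary, and this rule resolves the overlap deterministically.
Species ranking ties break by count then alphabetically. The mean±SD mode
uses all nests including censored ones by default.

## Problem sizes

The test and acceptance workloads were sized to exercise the estimators
at the study's own scale while staying comfortably interactive: the
recovery check fits ~1,500 nests with 2 × 4,000 iterations (about 40 s);
the LOO oracle uses ~30 nests × ~30 refits; the survival-curve oracle
2,000 uncensored nests against lifelines' Kaplan–Meier estimator; the
subsampling law 10 repetitions of 10 draws at two fractions; smaller unit
fixtures use 300–400 nests with shorter chains.

## Known limitations

* The model treats recorded ages as exact; interval censoring from the
  weekly visit schedule is represented in the generator but not modelled
  in the likelihood (by design, matching the field protocol's convention).
* Category decay summaries are cohort-composition dependent (empirical
  marginal); they are not causal per-category predictions.
* The retrospective estimator inherits a survivorship bias from dropping
  nests censored before their revisit; with short marking windows and low
  censoring this is small, with long windows it is not.
* No frailty/random effects per nest group, no time-varying covariates,
  no alternative lifetime distributions (Weibull, log-normal).
* The mean-decay target of the logistic method differs from the gamma
  model's by the logistic curve's functional-form mismatch with a gamma
  survival function; agreement is expected within interval noise, not
  exactly.
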