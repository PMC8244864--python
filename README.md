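# nestdecay

Great apes build a fresh sleeping nest almost every night, and most ape
population surveys count those nests rather than the apes. Converting a
nest count into an ape count requires the **nest decay time** — the mean
number of days from a nest's construction to the day before it is no
longer recognizable — and using a decay time from the wrong site, year or
climate regime silently corrupts the density estimate. `nestdecay` is an
analysis pipeline for estimating decay time from longitudinal
nest-monitoring data, for attributing it to climate and nest-construction
factors, and for stress-testing the cheap single-revisit shortcut that
field teams use when continuous monitoring is infeasible.

It is aimed at biomonitoring practitioners and quantitative ecologists
working with marked-nest studies (one row per nest: construction date,
habitat and construction covariates, date found decayed or censoring
date) plus daily rain-gauge and thermometer records.

## The models

**Censored gamma survival regression.** For nest *i* with observed age
`D_i` (whole days):

    decayed:   D_i ~ Gamma(k_i, theta),   k_i = mu_i * theta  (rate theta)
    censored:  P(T > D_i) = 1 - GammaCDF(D_i; k_i, theta)
    mu_i = exp( Σ_f coef_f[cat_f(i)] )

so `E[D_i] = mu_i` is the mean decomposition time, log-linked to
categorical factors: forest type, exposure, position, construction type,
nest height, lifetime rainfall, lifetime storm rate, construction-day
weather, and tree species. Priors are `Normal(0, 5)` on coefficients and
`Gamma(0.1, 0.1)` on `theta`. The model is deliberately over-parameterized
(no reference categories); only identified quantities are reported.
Posterior sampling uses Laplace preconditioning plus an independence
Metropolis–Hastings chain, with rank-normalized split-Rhat ≤ 1.01 required
on identified quantities. Model comparison and covariate ranking use
PSIS-LOO cross-validation (ELPD, Pareto-k diagnostics, leave-one-factor-out
ablation).

**Retrospective logistic estimator.** A marked nest revisited once is
Alive/Decayed; logistic regression of status on age at revisit gives
`P(alive at t) = logistic(a + bt)` and the mean decay time
`∫₀^∞ P(alive at t) dt = log(1 + e^a)/(-b)`. The pipeline builds the
revisit-timing scenarios (fixed offsets, per-group random 7–360 days),
bootstraps CIs over nest groups, and runs group-subsampling experiments to
find the sample size below which the estimate destabilises.

**A storm** is ≥ 20 mm of rain concentrated in a single evening or night
gauge interval of an otherwise rain-free day — short violent rain, which
turns out to matter more for nest decay than rainfall totals.

Because the original field data are not public, the package ships a
first-class synthetic-data generator (`nestdecay.simulate`) producing
complete studies — seasonal equatorial climate with planted storms, nest
cohorts with known gamma decay times, weekly monitoring visits, censoring
at study end — so every estimator can be checked against planted truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (results land under `results/`):

```
python analysis/01_simulate_study.py
python analysis/04_fit_survival.py
```

prints, among other things:

```
  1471 nests in 182 groups; true mean decay 99.8 days (expected observed 103.4); 13.9% censored
overall mean decay 102.0 days (95% CI 98.4-105.9)
theta 0.0219; split-Rhat: mean decay 1.0000, theta 1.0010; acceptance 0.63
contrast C[1]-C[2]: +19.8 days (+11.5, +27.5) *
contrast S[1]-S[2]: -63.6 days (-70.7, -56.6) *
```

Reading: the fitted cohort mean decay (102.0 days) recovers the
generator's expected observed age (103.4 days — the continuous mean of
99.8 days plus the ~3.5-day weekly-discovery lag) within its credible
interval; nests built in a single tree outlast integrated nests by ~20
days; nests that saw few storms decay ~64 days faster than those exposed
to an intermediate storm rate (both contrasts exclude zero, `*`). The
other scripts add climate trends (02), censoring bookkeeping (03),
PSIS-LOO model selection and covariate ablation (05), and the
revisit-scenario / subsampling experiments for the logistic method (06).

A `nestdecay` command-line interface wraps the same library for file-based
use (`nestdecay simulate`, `fit`, `loo`, `logistic`, `pipeline`, ...); see
`nestdecay --help`.

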