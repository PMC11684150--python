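# Methods

`cpfextrap` implements a pooled trial + real-world predictive-modelling
pipeline for complex Crohn's perianal fistula (CPF): covariate-adjusted
parametric time-to-event models for remission and relapse, extrapolated
through a semi-Markov relapsing–remitting cohort model to long-term
CPC-remission occupancy. This note records the models, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data tests
do and do not establish.

## Outcomes

Four first-event outcomes are derived from visit-level data, all in weeks:

* **clinical remission** — first visit at which all external openings (EOs)
  that were draining at baseline are closed; time at risk starts at
  treatment initiation (week 0);
* **CPC remission** (clinical plus patient-centric) — closure as above AND
  PDAI pain = 0 AND PDAI discharge = 0 at the same visit;
* **clinical relapse from CPC remission** — first loss of closure after the
  first CPC remission; the clock restarts at the CPC-remission visit;
* **CPC relapse from CPC remission** — loss of closure OR pain > 0 OR
  discharge > 0 after CPC remission.

Patients are removed after their first event; censoring is the earlier of
loss to follow-up, proctectomy, or death, else the last visit. Event timing
uses the visit week at which the state is first observed — observation is
interval censored by the visit schedule, and we deliberately do not apply a
midpoint correction because downstream comparisons are between arms under
the same observation process. Event and censoring at the same week resolve
to the event. A patient whose CPC remission is the final observation still
contributes a relapse sample (censored at 1e-3 weeks) so that relapse
samples partition CPC-remission events exactly.

## Parametric survival model

For event time T with censoring indicator d, each of five families —
Weibull, Gompertz, generalized gamma, log-logistic, log-normal — is fitted
by maximizing the exact log-likelihood

    sum_i [ d_i log h(t_i; mu_i, alpha_i) + log S(t_i; mu_i, alpha_i) ]

with a per-subject location parameter mu_i = x_i' beta and a per-subject
ancillary (shape) parameter alpha_i = link^{-1}(z_i' gamma). Links: log for
every positive shape/scale parameter, identity for the Gompertz shape
(legitimately negative — a decreasing hazard with a cure-like plateau) and
for the generalized-gamma Q. Parameterizations follow the flexsurv
conventions (Weibull AFT scale exp(mu); Gompertz rate exp(mu); log-logistic
scale exp(mu); log-normal mu on log-time; generalized gamma in the Prentice
(mu, sigma, Q) form with its Weibull (Q = 1) and log-normal (Q -> 0)
nestings). The generalized gamma has two ancillary parameters; shape
covariates act on log sigma, and Q is a scalar intercept — a package
choice, since a covariate-dependent Q is rarely identifiable at these
sample sizes.

Estimation is multi-start quasi-Newton (BFGS with a Nelder–Mead polish) on
the unconstrained coefficient scale; the generalized-gamma start set
includes its nested Weibull and near-log-normal solutions to tame the known
likelihood ridge. The variance–covariance matrix is the inverse numerical
Hessian (central differences, step 1e-4). Estimation is fully
deterministic. Non-convergence yields a flagged result, not an exception;
with `auto_drop_shape=True` shape covariates that prevent convergence are
dropped greedily and logged. Model comparison uses AIC = -2 loglik + 2k and
BIC = -2 loglik + k ln n on identical samples. MLE is the only estimation
mode: AIC/BIC are then unambiguous, and the hierarchical-Bayes machinery in
the package is confined to imputation where it is load-bearing.

**Lead-in.** All fits apply a 4-week lead-in by default: remission events
are structurally absent in the first post-treatment window, so fitted times
are t' = max(t - 4, 1e-3) and reported curves satisfy S(t) = 1 for t < 4.
Events at or before the lead-in boundary are counted and logged — they
contradict the lead-in assumption and in practice only occur for relapse
outcomes, whose clocks have no structural quiet period.

**Pooling assumption.** Study-indicator covariates are excluded from the
default covariate sets: long-term behaviour is assumed exchangeable across
studies given covariates, which is what lets the chart-review data inform
the trial arms' long-term shape. Adding a study indicator is possible but
off by default.

## Semi-Markov cohort model

Two health states: chronic symptomatic fistula (CSF; entry state) and CPC
remission. Sojourn distributions are the fitted time-to-CPC-remission and
time-to-CPC-relapse models with the clock reset at every state entry.
Death and proctectomy are not model states; they inform fitting only
through censoring. Re-entry sojourns reuse the first-event fitted
distributions — the data identify first events only, and this is the one
self-consistent way to run a relapsing–remitting model from first-event
fits; treat occupancy beyond the first cycle as model-based extrapolation,
not an empirical quantity. The lead-in is applied to the first CSF sojourn
only (it reflects a one-time post-treatment assessment gap); a switch
(`lead_in_on_reentry`) applies it to every CSF re-entry.

Two engines cross-check each other: a seeded vectorized microsimulation
(default n_sim 20,000 in the pipeline; 50,000 in the oracle checks) and a
deterministic alternating-renewal solver using discrete convolution with
bin masses attributed at bin midpoints (error O(h^2); default h = 0.25
weeks). In the exponential special case both reproduce the closed-form
two-state Markov occupancy 0.5(1 - e^{-0.2t}) (rates 0.1/week) to within
Monte-Carlo error and 1e-4 respectively. Months are 52/12 weeks.

Population averaging draws covariate rows from the analysis set (the
renewal solver averages per-profile solutions, subsampling large tables).
Bias adjustment between populations is entropy balancing: weights minimize
KL divergence to uniform subject to weighted covariate means matching a
reference table, solved through the convex dual. The reweighting method is
a package choice — the upstream analysis this mirrors does not name its
adjustment method.

## Imputation

Missing baseline covariates and visit-level PDAI categories are imputed
with hierarchical (study-level) models and m posterior-draw completions
(default m = 20; point estimates average over completions, and Rubin's
rules are available for coefficient reports via `rubin_pool`):

* categorical variables: per-study multinomial with Dirichlet partial
  pooling toward the pooled category proportions (empirical-Bayes global
  mean; prior strength tau = 5 — small against the observed counts, so
  pooling matters only where a stratum is data-poor);
* numeric variables: normal regression on age and gender with a
  ridge-shrunk study offset (equivalent to a study-level random intercept
  with a unit-information normal prior), coefficient and residual-variance
  posterior draws, truncation at 0 for non-negative scores (CDAI, weight,
  disease duration);
* visit-level PDAI items are fitted over the instrument categories plus an
  explicit dummy "missing-pattern" category, renormalized away at draw
  time, so extreme missingness (73.5% in the chart-review stratum) cannot
  silently distort the observed-category counts.

Everything is closed-form conjugate-style sampling: no MCMC dependency, and
the m completions are genuinely stochastic (between-imputation variance is
positive whenever missingness is). Imputation precedes fitting
(impute-then-fit); nesting imputation inside the survival fit was not
attempted. MNAR mechanisms are out of scope. The missing-PDAI decision at
an otherwise-qualifying CPC visit is resolved per completion by the imputed
category.

## Synthetic registry generator

The generator emulates the structure the analysis assumes, and its defaults
are the study conditions: a 212-patient trial (12 without a completed
post-index assessment; 101 DVS / 99 SoC among the assessed, assigned as an
exact randomized block so the published disposition is reproduced exactly,
which a Bernoulli assignment cannot do) and a 386-patient SoC-only chart
review (73 without an assessment); baseline covariate marginals matched to
the published baseline table (normal for age/weight; gamma matched to
mean/SD for the right-skewed non-negative disease duration and CDAI;
category probabilities for the rest); per-variable missingness rates read
off the same table's per-variable Ns (e.g. smoking recorded for 39/200
trial patients; 73.5% visit-level PDAI missingness in the chart review vs
0.5% in the trial); a fixed trial visit grid versus log-normal routine-care
visit gaps (median 10 weeks — an assumption, the source never states the
chart-review visit frequency); and exponential censoring for loss to
follow-up, proctectomy and death. For assessed patients the censoring clock
starts at the first completed assessment (memoryless rates make this a
clean conditioning), which is what keeps "lacks a completed assessment" and
"was censored very early" distinct strata.

Latent event structure: the CPC-remission and CPC-relapse times follow the
configured true families exactly, with location/shape linear predictors on
the encoded covariates; clinical remission is min(own draw, CPC draw) and
clinical relapse is max(own draw, CPC-relapse draw). Four outcomes under
deterministic order constraints cannot all follow arbitrary independent
families jointly; this construction privileges the two outcomes that drive
the extrapolation model and enforces the orderings by construction. Relapse
clocks start at the latent CPC-remission time (semi-Markov clock reset by
construction). Remission latent times are shifted by the lead-in, so the
generated trial reproduces the event-free early window. Observation is the
latent process sampled at the visit schedule (right-aligned interval
observation); `keep_latent=True` retains exact latent times for oracle
tests. Missingness is MCAR by default with a MAR option (masking tilted by
luminal disease activity).

Default true event models are Weibull with scales (weeks) 25/45
(clinical remission, DVS/SoC), 32/60 (CPC remission), 150/75 (clinical
relapse), 110/55 (CPC relapse), shape 1.2 for remission and 0.9 for
relapse, a penalty on remission for active luminal disease and a mild age
effect, and faster relapse after prior biologic exposure. These are
realistic-by-construction choices pinned before any downstream check: the
source prints no fitted coefficients to copy, so recovery of generating
parameters — not reproduction of published coefficients — is the
validation standard throughout.

**What passing tests show.** The synthetic registry reproduces the
analysis-relevant structure (two studies, arms, visit-based interval
observation, published missingness levels and patient flow), not the real
joint covariate distribution, real visit-process informativeness
(visits in routine care may be symptom-driven — an MNAR observation
process the generator does not emulate), nor real between-study
heterogeneity. Tests passing on this registry establish the estimators and
engines are correct, not that the published long-term percentages are
recoverable; those depend on patient-level data that are not public, and
the packaged demo reproduces only the qualitative pattern (active arm
above comparator, gap sustained to 48 months).

## Non-parametric layer

Kaplan–Meier estimation, risk tables and the two-sample tests delegate to
lifelines; Greenwood variance, the exact step-function RMST with its
area-based variance, and the median CI (inversion of the complementary
log-log pointwise band) are computed from the risk table. The two-sample
tests are the log-rank (Mantel–Haenszel) and the Gehan–Wilcoxon test with
the Peto–Peto approximation (weights equal to the left-continuous pooled
KM), both 1-df chi-square. Ties resolve events before censorings. The
default RMST horizon is the largest observed time (the pipeline never
extrapolates the non-parametric curve).

## Numerical choices and degenerate inputs

* Gompertz log-survival uses expm1 with a series branch below |a| = 1e-9;
  negative-shape sampling returns +inf beyond the survival plateau, and the
  microsimulation treats an infinite sojourn as an absorbing stay.
* Generalized-gamma evaluation switches to the log-normal branch below
  |Q| = 1e-6; shape linear predictors are clipped at +/-30 during
  optimization to keep iterates finite.
* The renewal solver stops when the remaining entry mass is below 1e-8.
* Zero event times are rejected by the likelihood with the offending sample
  named; empty KM input raises; a two-sample test with no events in either
  group returns statistic 0, p = 1.
* All randomness flows through seeded numpy Generators; the pipeline
  derives stage seeds from one config seed, and two runs with the same
  config produce byte-identical manifests.

## Problem sizes

Defaults were sized so the full test suite and the acceptance script each
run in a few minutes on one core: oracle microsimulations use 20,000–50,000
patients (MC SE below 0.25 percentage points of occupancy), recovery
studies 50 replicates of n = 2000, model selection 200 replicates of
n = 1000, calibration 2000 replicates of 200 per arm, and the demo pipeline
the full 513-patient registry with m = 3 completions. Larger values change
none of the conclusions, only the Monte-Carlo error.

## Known limitations

* First-event data cannot identify re-entry sojourn distributions; the
  semi-Markov extrapolation assumes they equal the first-event ones.
* The location-and-shape model provides flexibility, but shape covariates
  are weakly identified at small event counts (hence auto-drop).
* The imputation model is MAR-by-construction; the real missingness
  mechanism in routine care is plausibly MNAR.
* AIC/BIC averaged over imputation completions is a pragmatic summary, not
  a principled combined-likelihood criterion.
* No absorbing death state in the cohort model; occupancy is conditional on
  remaining in the two-state process.
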