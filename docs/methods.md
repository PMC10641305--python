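# Methods

## Model

The core model is an open-population Cormack–Jolly–Seber (CJS) model for
multi-species, multi-site mark–recapture data, conditioning on each
individual's first capture. Apparent survival (survival confounded with
permanent emigration; the emulated study design assumes emigration is
negligible) is modelled on the logit scale. Four model variants share one
surface:

| variant | linear predictor |
|---|---|
| `intercept_only` | `mu[j,s]` |
| `covariate` | `mu[j] + beta[j] * x_t` (per-species effect sizes; fitted per stream) |
| `random_effects` | `mu[j,s] + e1_t + e2[j,t] + e3[s,t] + e4[j,s,t]` |
| `random_effects_plus_covariate` | as above plus a single shared `beta * x_t` |

The random effects are zero-mean normal with variances `s2_t` (shared by
all species and streams), `s2_j` (one per species), `s2_s` (one per
stream) and `s2_js` (one per combination). This is the variance
decomposition that the ICC synchrony statistic partitions.

**Interval-length scaling.** Occasions are unevenly spaced (intervals of
48–70 days). Survival is standardized to a 60-day basis. Two conventions
are supported because the choice of which scale the linear predictor lives
on is genuinely open:

* `baseline60` (default): the inverse-logit of the predictor is 60-day
  survival; the likelihood raises it to `n_days/60`. Simulated truth and
  fitted quantity are then the same object, which makes recovery tests
  exact.
* `posthoc`: the inverse-logit is interval survival; the `60/n_days`
  exponent is applied only when reporting, replicating a literal post-hoc
  standardization.

**Likelihood.** The data-augmented Bernoulli chain over latent alive/dead
states is marginalized analytically with the chi recursion
(`chi_T = 1`, `chi_t = (1-phi_t) + phi_t (1-p_{t+1}) chi_{t+1}`). Because
survival and detection vary only by (species, stream, occasion), the
capture histories reduce without loss to m-array sufficient statistics
(releases per occasion cross-classified by next recapture occasion, plus
never-seen-again counts), and the total log-likelihood is the multinomial
log-likelihood of the m-array. The test suite verifies all three routes
agree: exhaustive latent-state enumeration (small T), the per-individual
chi recursion, and the m-array factorization (to 1e-10). Deviance is
`-2 log L`, conditional on the random effects.

Individuals first captured on the final occasion are retained in the data
model but contribute nothing to the likelihood (flagged `terminal_only`).
Probabilities inside the recursion are clipped to `[1e-12, 1-1e-12]`; all
products are accumulated in log space.

**Priors** (diffuse, configurable via `PriorSpec`): Normal(0, 10²) on
intercepts and effect sizes, Uniform(0, 1) on each detection probability,
Uniform(0, 10) on each random-effect standard deviation. The per-species
variances are independent a priori.

## Sampler

Any correct MCMC over the marginalized posterior is acceptable; the
implementation is an adaptive random-walk Metropolis-within-Gibbs written
as one compiled (numba) sweep:

* scalar Gaussian proposals for `mu`, `beta`, each random effect and each
  detection probability, with per-coordinate proposal scales adapted
  toward a 0.44 acceptance rate during burn-in (factor e^±0.1 every 50
  sweeps) and frozen afterwards, preserving detailed balance in the
  sampling phase;
* exact Gibbs draws for each random-effect variance from its truncated
  inverse-gamma full conditional (the Uniform(0, 10) sd prior makes
  `s2 | e ~ InvGamma((n-1)/2, sum(e²)/2)` truncated at 100);
* likelihood-invariant "ridge" swap moves that transfer a common increment
  between confounded location parameters (`mu <-> e4`, `e1 <-> e2`,
  `e1 <-> e3`, `e2 <-> e4`, `e3 <-> e4`, and `beta <-> e1` along
  `e1_t -= delta * x_t`), accepted on the prior ratio alone. Without an
  identifiability constraint the intercepts and random-effect means are
  confounded (as in the equivalent data-augmented JAGS formulation); these
  moves walk along that ridge cheaply and are what makes desk-scale chains
  converge.

Initialization: `mu`, `beta` at 0 (jittered per chain), detection at the
empirical per-occasion recapture fraction, sds at 0.5, random effects at 0
with small jitter; a non-finite start triggers up to two re-initializations
with more dispersed jitter.

**Run lengths.** Defaults are desk-scale: 3 chains × 4,000 iterations,
1,000 burn-in, thin 2 for the covariate/intercept models, and
`MCMCSettings.synchrony_default()` = 3 × 20,000, 5,000 burn-in, thin 5 for
the hierarchical synchrony models, whose random effects mix more slowly —
the same reason the field analyses of this design run their synchrony
models longer (study-scale settings of 250k–600k iterations remain
available through the same dataclass). Convergence is assessed with the
split-chain Gelman–Rubin statistic per scalar (pass mark R-hat < 1.1;
zero-variance chains are reported as 1 with a degeneracy flag). The
implementation is cross-checked against arviz's split R-hat in the tests.

**DIC.** `DIC = Dbar + pD` with `pD = var(deviance)/2` by default (the
estimator of the BUGS/JAGS software lineage); `pD = Dbar - D(posterior
mean)` is selectable, and the two are compared in the tests. Deviance is
conditional on the random effects, so DIC comparisons across variants use
the same focus.

## Covariates

Daily logger series are summarized per inter-occasion interval into five
candidates: mean/max temperature and mean/max/min water level. Interval
membership is half-open — a day belongs to interval t when
`occasion_date[t] < day <= occasion_date[t+1]` — so every day between the
first and last occasion is counted exactly once; missing days are a hard
error. Standardization is `(x - mean) / sd` with the sample (n−1) sd
(configurable divisor).

The collinearity screen visits covariates in priority order (means before
extremes) and drops any candidate whose correlation with an
already-retained one exceeds the threshold (default 0.5) **in absolute
value** — negative collinearity is as harmful as positive, so |r| is
compared even though the screen is often quoted as "r > .5"; signed
comparison is available as an option.

Per-stream model fits use the stream's own standardized covariate. The
joint synchrony model uses a single `x_t`: the raw covariate is averaged
across streams first and the average is then standardized, so `x_t`
enters the joint model with mean 0 / sd 1.

## Synchrony statistics

* **ICC** is computed per posterior draw and summarized by the mean and
  percentile 95% CRI (a credible interval on a ratio requires per-draw
  computation); the plug-in ICC of the posterior-mean variances is also
  reported for comparison with point-estimate arithmetic. A draw with zero
  total variance is assigned ICC 1 with a warning.
* **Covariate contribution**: `s2_cov` is the per-draw sample (n−1)
  variance of `beta * x_t` over intervals; the proportion is the per-draw
  `s2_cov / (s2_cov + s2_t)`. Two open choices are surfaced rather than
  guessed: the report carries both the per-draw posterior mean of `s2_cov`
  and the plug-in variance of the posterior-mean product, and the
  proportion is computed both with `s2_t` from the same
  covariate-plus-random-effects fit (default, labeled) and with `s2_t`
  from the covariate-free random-effects fit.
* **Pairwise correlations** use the posterior-mean survival series (the
  natural analogue of plotted point estimates); p-values are two-sided
  t-distribution values with n−2 degrees of freedom, verified against a
  10,000-draw permutation oracle within 0.02 at n = 14. Per-draw
  correlation distributions can be derived from `survival60_draws` as a
  diagnostic.

The report flags the structural CJS confound between the final interval's
survival and final-occasion detection; the last interval is estimated but
should be read with caution.

## Synthetic-data generator

The generator emulates the study conditions end-to-end: 3 species × 2
streams × 15 occasions with integer-uniform 48–70-day intervals; daily
temperature as a sinusoid (mean 15.5 °C, amplitude 12.5 °C, minimum
mid-January) plus AR(1) noise, with a +2 °C offset in the second stream
during the first full summer; water level as a stream-specific baseline
(0.17 / 0.26 m) plus exponentially decaying flow events concentrated in
winter but present year-round; staggered entry with 40% of each group's
total first tagged at occasion 1 and the rest spread over occasions
2..T−1 (deterministic counts — the CJS likelihood conditions on first
capture, so recruitment realism is unnecessary); detection drawn uniform
0.18–0.53 per species × stream × occasion; and survival generated from the
full linear predictor, with the temperature covariate taken as the
standardized cross-stream-averaged interval mean of the generated daily
series, closing the loop with the covariate-processing path. Default
variance components are the emulated study's reported point estimates
(`s2_t = 0.60`, `s2_j = (0.42, 0.44, 0.80)`, `s2_s = (0.64, 1.08)`,
`s2_js` as reported per combination).

Default tagged totals are scaled to ~10% of the field study (578 fish)
so that a complete synchrony analysis runs in minutes on one CPU;
`full_size=True` restores the field totals. Problem sizes used by the
shipped tests: 2,000 individuals for effect-size recovery, the 578-fish
default scenario for variance-component recovery and the end-to-end run,
600 for the DIC-ordering replicates.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about field data: tag loss, mortality from
tagging, emigration (all assumed negligible in the emulated design),
within-occasion sampling over multiple days (median dates are generated
directly), individual heterogeneity in survival or detection (no
size/condition effects), density dependence, and any misspecification
between the fitted and generating model — the generator draws from
exactly the model family being fitted, so recovery tests validate the
estimation machinery, not the model's adequacy for real streams.

## Numerical and design choices

* Occasions are 1-based in all public interfaces; species/stream order
  comes from an explicit index declaration, never from file order.
* The m-array reduction is an internal evaluation strategy; the
  per-individual chi recursion is the reference implementation and the
  exhaustive enumeration oracle lives only in the tests.
* Detection is indexed species × stream × occasion in the joint models
  (per-stream fits recover the species × occasion structure with one
  stream).
* Variance Gibbs truncation failures (50 rejected draws) keep the current
  value; sums of squares are floored at 1e-12.
* Reported survival series are always on the 60-day scale regardless of
  `scaling_mode`.
* Individuals that grow past the tagging size threshold mid-study simply
  enter at their first tagging occasion; the data model has no concept of
  pre-tagging existence.

## Limitations

* ICC credible intervals are intrinsically wide at T = 15 (14 informative
  intervals); the recovery tests assert coverage, not precision.
* The intercept/random-effect confound makes `mu` and the e-means only
  jointly identified; the swap moves handle mixing, but individual `mu`
  posteriors are diffuse in the hierarchical variants.
* DIC with random effects depends on the focus (conditional deviance
  here); comparisons with marginal-deviance DICs from other software are
  not meaningful.
* No multi-state, robust-design or spatially explicit extensions, no
  individual covariates, and no abundance estimation — the scope is the
  survival-synchrony analysis.
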