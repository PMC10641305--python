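# streamsync

Bayesian Cormack–Jolly–Seber (CJS) survival modelling with a temporal
random-effects variance decomposition, for quantifying **interspecific**
(among co-occurring species) and **spatial** (among sites) synchrony in
survival from mark–recapture data — the kind of bi-monthly PIT-tag
electrofishing study run on small-stream fish communities, where warm
summers or flow events can move the whole community's survival at once.

It is written for population ecologists who have long-format encounter
records plus temperature/water-level logger series and want to know (1)
which environmental covariates drive survival, (2) how synchronous each
species is with its community and with conspecific populations at other
sites, and (3) how much of the shared temporal variation a covariate
explains.

## The model

Capture histories `y[i,t]` condition on first capture. The latent
alive/dead chain and observation process are

    z[i,t+1] | z[i,t] ~ Bernoulli(z[i,t] * Phi[i,t])
    y[i,t]   | z[i,t] ~ Bernoulli(z[i,t] * p[i,t])

with apparent survival logit-linear in an intercept, an optional
standardized environmental covariate, and four temporal random effects:

    logit(Phi60[i,t]) = mu[j(i),s(i)] + beta * x_t
                        + e1_t + e2_{j,t} + e3_{s,t} + e4_{j,s,t}

where `e1 ~ N(0, s2_t)` is shared by everyone, `e2 ~ N(0, s2_j)` is
species-specific, `e3 ~ N(0, s2_s)` stream-specific and `e4 ~ N(0, s2_js)`
specific to a species-by-stream combination. Unequal sampling intervals
are handled by standardizing survival to a 60-day basis,
`Phi = Phi60 ** (n_days/60)`. Detection `p` varies by species, stream and
occasion. The likelihood is marginalized over `z` with the chi recursion
(chi_t = probability of never being seen after t given alive at t) and
evaluated from m-array sufficient statistics, so fits cost the same for 500
or 50,000 fish.

Synchrony statistics built on the fit:

* **ICC** per species-by-stream combination:
  `(s2_t + s2_j + s2_s) / (s2_t + s2_j + s2_s + s2_js)` — the share of its
  temporal variance that is community-shared (1 = fully synchronous),
  computed per posterior draw and summarized with a 95% credible interval.
* **Covariate contribution**: `s2_cov = var_t(beta * x_t)` and its share of
  synchronous variation `s2_cov / (s2_cov + s2_t)`.
* **Pairwise Pearson correlations** of posterior-mean survival series,
  within streams (interspecific) and between streams (conspecific).
* **DIC** (mean deviance + pD, default pD = var(deviance)/2) ranks the
  intercept-only, covariate and random-effects model variants.

Because real study data of this kind are typically not public, the package
ships a first-class synthetic-data generator (`streamsync.simulate`) that
emulates the full design — seasonal temperature with a stream-specific
summer offset, winter-peaking water levels, staggered tagging entry,
detection 0.18–0.53 — and records the exact truth for recovery testing.

## Worked example

`examples/03_fit_covariate_model.py` simulates ~2000 tagged fish in one
stream with a true temperature effect of −0.5 and refits it:

```
true beta        : -0.5
posterior mean   : -0.562
95% CRI          : (-0.696, -0.437)  significant: True
R-hat pass       : True
DIC              : 9564.2
```

The posterior mean recovers the simulated effect (the CRI covers −0.5 and
excludes 0, so the covariate would be ranked significant), and all
Gelman–Rubin split-chain R-hat values are below 1.1.

The other examples walk the remaining capabilities: `01` simulates and
inspects a full two-stream dataset, `02` runs the collinearity screen
(mean and max temperature correlate at r ≈ 0.98, so only the means
survive), `04` runs the complete synchrony analysis and prints the report
bundle (ICC table, correlation table, covariate contribution, DIC
ranking), `05` shows the ICC arithmetic — e.g. creek chub in Indian Creek:
(0.60 + 0.44 + 0.64) / (0.60 + 0.44 + 0.64 + 0.60) = 0.74.

An equivalent shell workflow is available via the `streamsync` CLI
(`simulate | screen | fit | synchrony | report`).

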