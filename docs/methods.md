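# Methods

## The model

Each city contributes one observation per outcome: its annual share of
kilometers traveled by walking, and separately by cycling, on a
denominator that excludes public transit (walk + cycle + private motor
vehicle km). Shares live on (0, 1), so each outcome is modeled with a
beta likelihood in the mean–precision parameterization,

    y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi),

with a logistic link for the mean. For city *i* in country *j*:

    logit(mu_i) = alpha_j + sum_k beta_jk x_ik + sum_m delta_m z_jm

* `x_ik` — standardized city covariates: ln population density, bikeway
  provision B (km of bicycle facility per 100 km of road), terrain
  ruggedness, coldest-month temperature (linear and squared), hottest-month
  temperature, annual precipitation;
* `z_jm` — standardized country covariates: gasoline price (USD/l),
  ln GDP per capita, dependency ratio;
* `alpha_j ~ Normal(a, sigma_alpha^2)` — country intercepts around a
  global level;
* `beta_jk ~ Normal(gamma0_k + gamma1_k * z_gdp_j, tau_k^2)` — country
  slopes whose expected value shifts with national income: the
  cross-level interaction that lets, say, density matter more in richer
  countries;
* `phi` — a single global precision (no evidence for country-specific
  dispersion was worth the extra parameters).

The walk and cycle models are fully separate; nothing is shared between
them except the design matrix.

Priors are weakly informative on the logit scale and overridable through
`ModelSpec`: Normal(0, 2) on the global intercept and the country-covariate
coefficients `delta`, Normal(0, 1) on `gamma0` and `gamma1`, half-Normal(0, 1)
on `tau` and `sigma_alpha`, Exponential(rate 0.1) on `phi`. Only ln GDP per
capita moderates city slopes by default; other moderators can be listed in
`ModelSpec.moderators`.

## Data conventions

* **In/out-bound travel.** Trips crossing the city boundary count at 50%
  of their distance, per greenhouse-gas reporting convention. Cities
  without in/out-bound data are a legal state, handled by simply using the
  within-boundary volumes.
* **Two denominators.** The regression outcome excludes transit (the
  substitution of policy interest is active vs private motorized travel);
  descriptive summaries include it. Pooled descriptives weight cities by
  km traveled (summed volumes), never by averaging city shares.
* **Standardization.** City covariates are standardized against the
  pooled city sample (one worldwide SD per covariate), so "one-SD" effects
  are comparable across countries. Country covariates are standardized
  across countries, each counted once — a country-level SD is the natural
  unit for a country-level variable. Population SD (ddof 0) is used.
  The squared-temperature column is squared on the raw °C scale *before*
  standardization; squaring a standardized column would relocate the
  curvature.
* **Boundary shares.** Exact 0/1 shares are compressed with
  y' = (y(n−1) + 0.5)/n (n = modeled cities) before fitting; interior
  values are untouched. The beta likelihood has open support.
* **Exclusions.** Cities with road_km = 0 (B undefined) or an all-zero
  regression denominator are excluded from fitting, with logged counts;
  they remain in descriptive outputs.

## Posterior computation

No probabilistic-programming backend is part of this package's
dependency set; the sampler is purpose-built for this model family and
lives in `activetravel.model`:

* country intercepts and slopes update by vectorized random-walk
  Metropolis — countries are conditionally independent given the
  hyperparameters, so all countries step at once;
* `gamma0`/`gamma1` and the global intercept have exact conjugate Normal
  updates given the slopes; scale parameters (`tau`, `sigma_alpha`) use
  univariate slice sampling; `delta` and `log phi` use adaptive
  random-walk Metropolis;
* the centered parameterization above mixes poorly when `tau` or
  `sigma_alpha` is small (the hierarchical funnel: slopes pin to the
  hyper-mean and the scale freezes). Each sweep therefore also performs
  non-centered *interweaving* moves: holding the standardized residuals
  u = (beta − mean)/tau fixed, the hyper-means, moderation coefficients
  and scales are updated through the likelihood, which moves the whole
  block and mixes precisely in the small-scale regime. A further exact
  interweaving step resamples `delta` holding alpha_j + (Z delta)_j fixed,
  breaking the near-nonidentified direction between country intercepts
  and country-covariate effects;
* proposal scales adapt toward standard acceptance targets during warmup
  only, so kept draws form a valid Markov chain;
* split-chain R-hat and bulk effective sample size (computed with arviz
  over every parameter) gate the fit: the defaults demand R-hat ≤ 1.05
  and ESS ≥ 100, and `fit` raises otherwise. Defaults are 2 chains,
  1,000 warmup and 2,000 kept draws per chain, which passes the gate
  comfortably on the bundled dataset sizes.

Numerical details: proposals that push `mu*phi` or `(1-mu)*phi` to zero
get −inf likelihood and are rejected; `tau` is floored at 1e-8 inside
conjugate updates; initialization uses empirical logits (per-country
means) and a method-of-moments precision.

## Effect summaries

A one-SD effect is reported in percentage points: the change in the
predicted share when one covariate rises one SD from the reference
profile (all standardized covariates at 0, the country's own intercept).
For the minimum-temperature effect, raw tmin is perturbed by +1 SD and
both the linear and squared standardized columns move coherently. The
"median-country" effect takes the median over countries within each
posterior draw, then summarizes across draws; country-covariate effects
(one shared coefficient) are evaluated at the same median-country
baseline. The moderation summary reports both the model's own `gamma1`
posterior and a descriptive unweighted OLS of posterior-mean country
effects on standardized ln GDP (flagged degenerate below three
countries). Effects are *not* averaged over observed covariate profiles;
the reference-profile choice is deliberate and documented here because
the two conventions differ under a curved link.

## Counterfactual scenario engine

For each floor B* in the grid (default 1…50, with a Copenhagen preset at
B* = 44.3 and a 95th-percentile preset):

1. every city's B becomes max(B, B*) — a minimum, never a reduction;
2. the standardized B column is recomputed with the *factual* registry
   (coefficients were estimated on that scale; re-standardizing under the
   counterfactual would silently rescale them);
3. share changes are predicted per posterior draw and converted to km
   against each city's fixed baseline non-transit volume (total travel is
   conserved; mode shifts reallocate it);
4. added active km displace motorized km at configurable ratios
   (central 1 : 1; literature ranges 1.0–3.1 for walking, 0.8–2.1 for
   cycling), split between private vehicles and transit in proportion to
   baseline km; displacement above a city's baseline motorized km is
   capped, with a logged count;
5. only the private-vehicle portion counts toward CO2: the percent
   reduction is relative to baseline private-vehicle emissions and is
   invariant to the (single, global) emission factor, which matters only
   for absolute tonnage. The walk-vs-cycle attribution of savings is
   tracked separately;
6. health benefits multiply added walking and cycling km by per-km dollar
   values. The shipped defaults ($0.50/walk-km, $0.25/cycle-km) are
   placeholders to be replaced with values from a health-impact
   assessment source appropriate to the study region; every result
   scales linearly in them.

Uncertainty intervals are equal-tailed 2.5/97.5% quantiles across
posterior draws, propagating coefficient uncertainty only (a switch
exists for adding beta observation noise). New-bikeway construction,
Σ max(0, B*/100 · road_km − bikeway_km), is deterministic in the data.

## Synthetic data

The generator draws from exactly the assumed data-generating process, so
parameter recovery is a meaningful test. Its defaults encode the study
conditions: pooled km shares near 2.0% walking / 0.9% cycling with
transit at ~23% of km; walking ≈ 6–7× the trips and ≈ 2–2.3× the km of
cycling (via mode-specific mean trip lengths of 1.2 / 3.67 / 9.5 / 11 km);
30.1% of cities reporting in/out-bound travel; right-skewed covariates
(log-normal density around 3,000 persons/km², zero-inflated-gamma bikeway
provision truncated to [0, 100], gamma precipitation, half-normal
terrain); gasoline price (mean $1.20/l, SD $0.40) correlated 0.4 with
ln GDP per capita. Walk and cycle shares are drawn independently and
redrawn (with a logged count) in the rare event walk + cycle ≥ 1.
One master seed feeds per-stage substreams, so stages regenerate
independently and fixtures are byte-stable.

What the generator does **not** emulate: differential-privacy noise,
smartphone-penetration bias, within-year seasonality, spatial correlation
between neighboring cities, or measurement error in covariates. Passing
recovery tests therefore demonstrates correctness of the estimator under
the model's own assumptions, not robustness of the substantive findings
to real-data pathologies.

Bundled presets: `tiny` (3 countries × 5 cities, smoke tests), `small`
(10 × 20, fast end-to-end runs), `recovery` (30 × 40, parameter-recovery
checks). These sizes keep a full simulate–fit–summarize cycle in minutes
on a single core while leaving enough countries to identify the
hierarchy; they are the problem sizes used throughout the test suite and
the reproduction script.

## Known limitations

* Estimates are associational; no causal identification is attempted.
* The median-country effect is the median of effects, not the effect in
  any specific country.
* With few countries (< ~5) the moderation coefficients and
  country-covariate effects are prior-dominated; the descriptive
  moderation regression is flagged degenerate at 2 countries.
* Scenario results assume instantaneous equilibrium response through the
  bikeway coefficient; no uptake dynamics, safety-in-numbers feedback, or
  induced-demand effects.
* Duplicating observations need not narrow hyper-mean intervals: tighter
  country slopes legitimately increase the between-country SD posterior.
  This is a property of hierarchical models, not a sampler defect, and
  the test suite asserts information monotonicity only where it holds
  (precision, intercept spreads).
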