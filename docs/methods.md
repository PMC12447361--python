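# Methods

`heatfeed` quantifies the short-term effect of heatwave exposure on whether
infants and young children (6–23 months) meet WHO feeding standards, using a
distributed-lag mixed-effects logistic model linked to percentile-defined
heatwave calendars. This note documents the model, its conventions and
defaults, what the synthetic-data generator emulates, and the numerical
choices behind the implementation.

## Heatwave definition and exposure matching

A heatwave at a survey cluster is a run of at least `min_duration`
consecutive days whose daily mean temperature strictly exceeds a
location-specific climatological percentile threshold. Six canonical
definitions are supported: percentiles 92.5, 95, 97.5 crossed with
durations ≥2 and ≥3 days.

Conventions, chosen where the underlying concepts leave latitude:

* **Quantile estimator.** Linear interpolation between order statistics
  (the ubiquitous "type 7" rule), computed over the full compiled
  temperature record (2000–2020 by default), all calendar days, no
  within-season restriction.
* **"Exceeding" is strict.** Days exactly at the threshold do not count.
  Both this and the all-days climatology are configurable concerns for
  users comparing against other heatwave catalogues.
* **Lag indexing.** Feeding recall covers the day before the interview, so
  lag 0 is `interview_date − 1` (the recall day) and lag k is k days before
  that. The default window is lags 0–14; the sensitivity window extends to
  lag 20.
* Calendar arithmetic is in plain dates; only daily means are used.

The per-record exposure is the binary vector h[0..L] of heatwave-day flags
over the lag window. Records lacking the required climate history are
dropped with an itemised log message, never silently.

Climate covariates: annual mean temperature is the arithmetic mean over the
365 days ending on the recall day; relative humidity uses the Magnus
saturation vapour pressure e_s(T) = 6.112·exp(17.62·T/(243.12+T)) as
RH = 100·e_s(T_dew)/e_s(T). Surface pressure, where present in inputs, is
carried through I/O but plays no role in the Magnus formula.

## Feeding indicators

The classifier implements the WHO indicator rules on 24-h recall:

* **MDD** — at least 5 of the 8 food groups (breastmilk; grains/starchy
  roots/tubers/plantains; legumes and nuts; dairy; flesh foods; eggs;
  vitamin-A-rich fruits/vegetables; other fruits/vegetables).
* **MMF** — breastfed 6–8 months: ≥2 solid/semi-solid/soft feeds; breastfed
  9–23 months: ≥3; non-breastfed: ≥4 feeds counting milk feeds, at least
  one of them solid/semi-solid/soft.
* **MAD** — breastfed: MDD and MMF; non-breastfed: ≥4 of the 6 groups
  excluding breastmilk and dairy, plus MMF, plus at least 2 milk feeds.

Two conventions worth noting. Published descriptive tables for this kind of
cohort sometimes print overlapping age bands ("12–18" and "18–23"); since
bands must partition, the implementation uses 12–17 and 18–23 and keeps the
printed labels. Percentages are half-up rounded to one decimal, which
reproduces the recomputable published cells; the one urban dietary-diversity
cell that disagrees at the last digit under unweighted division (74.5 vs a
printed 74.6) is presumably survey-weighted and is excluded from validation,
since no weighting scheme is described for it. Missing recall items are
handled by complete-case exclusion with logged counts (imputation to "not
consumed" only behind an explicit flag).

## Lag-response basis

The lag-specific log-odds contribution of exposure is a natural cubic
spline over lag 0..L with internal knots equally spaced on the log-lag
scale: knot_j = exp(j·log(L)/(K+1)), j = 1..K. With the default K = 2 and an
intercept column the basis has 4 degrees of freedom (df = K + 2 with the
intercept column, K + 1 without it); this df accounting is a convention and
both variants are constructible.

Construction follows the standard natural-spline recipe: a cubic B-spline
basis on boundary knots [0, L], projected onto the null space (via QR) of
the second-derivative constraints at both boundaries. Spanned functions are
therefore linear beyond the boundary knots; evaluation outside [0, L]
continues linearly from the boundary value and slope. Knot placement uses
log(L) scaling only — the basis itself is evaluated on the raw lag scale, so
lag 0 needs no log transform.

Because exposure is a binary event indicator rather than a temperature
dose, the cross-basis is lag-only: z_i = Bᵀh_i, the projection of each
record's exposure vector onto the basis, giving df design columns.

## Regression model

For child i in country c, with y = 1 when the standard was NOT met:

  logit P(y_ic = 1) = x_icᵀγ + z_icᵀβ + u_c,   u_c ~ N(0, σ²)

Fixed effects: child sex, age (months), length-for-age Z; maternal age and
education; residence; household wealth quintile; unordered categorical
survey year and month (earliest level as reference, dummy levels determined
after complete-case filtering so no reference level can vanish); annual mean
temperature entered linearly; and the cross-basis block. Food-group outcomes
are coded "did NOT consume group g"; the breastmilk outcome is fitted on the
currently-breastfed subset to avoid confounding by voluntary weaning.

Estimation maximises the Laplace-approximated marginal likelihood. For a
candidate σ the joint penalised log-likelihood is maximised over (γβ, u) by
penalised iteratively reweighted least squares with a Schur-complement
block solve and step-halving; the profile criterion

  ℓ(σ) = ℓ_pen(mode) − ½ Σ_c log(1 + σ² d_c),   d_c = Σ_{i∈c} w_i,

is optimised over log σ by bounded deterministic scalar search (tolerance
1e-3 on log σ, bounds σ ∈ [1e-3, 5]). The coefficient covariance is the
fixed-effect block of the inverse joint penalised Hessian at the optimum.
Starting values are zero, so refits are bit-identical. The fit agrees with
`lme4::glmer` (binomial, nAGQ = 1) to ~1e-2 on coefficients and ~1e-3 on σ
and the log-likelihood on common designs (asserted in the test suite).

With fewer than 5 groups the model falls back to plain logistic regression
with fixed country dummies (statsmodels GLM); the fallback is recorded in
the result. Quasi-complete separation (|β| > 15) aborts the fit with a
diagnostic naming the offending columns.

## Effect summaries and inference

* **Cumulative OR.** The contrast is the column sum c = Σ_k b_k of the
  basis: sustained exposure on all L+1 lag days versus none. This is the
  standard reading of a binary-exposure distributed-lag model's cumulative
  effect; a single-lag contrast is also computable (`lag_curve`). The
  choice matters for interpretation and is therefore stated prominently.
* **Delta method.** se = √(cᵀVc) from the cross-basis covariance block;
  95% CIs use the normal multiplier 1.959964. The delta-method SE is
  validated against Monte-Carlo propagation in the suite (≤5% at 10⁴
  draws).
* **Effect modification.** Strata are fitted as independent models (not
  interaction terms); the multivariate Wald statistic
  W = dᵀ(V_a+V_b)⁻¹d on the cross-basis coefficient difference is referred
  to χ²_df. A singular pooled covariance falls back to the pseudo-inverse
  with rank-adjusted df and a warning. The scalar z-test on cumulative
  log-ORs is reported alongside.
* **Sensitivity suite.** Prespecified variants re-run the primary model:
  added 24-month cumulative precipitation; each covariate removed in turn;
  lag window extended to 20 days and lag df varied; recall-day relative
  humidity added. The identity variant must reproduce the primary fit
  exactly, which the suite asserts.

## Synthetic-data generator

The generator emulates the two real inputs — reanalysis daily temperature
per cluster and survey recall records — with a known planted structure.

**Climate.** T(d) = mean + A·sin(2π(doy−phase)/365.25) + trend·years + e(d),
with AR(1) noise e(d) = φ·e(d−1) + N(0, τ²) initialised at the stationary
distribution so early days are unbiased. Defaults: cluster means drawn once
per cluster from 22–30 °C, amplitude 4 °C, φ = 0.7, τ = 1.8 °C, trend
0.2 °C/decade (matching the observed ~0.3 °C median rise over 15 years),
record 2000–2020. Dewpoint sits a gamma-distributed few degrees below the
air temperature; precipitation is occasional exponential amounts — both are
plumbing for the sensitivity variants, not climatology.

**Mode A (direct outcome).** The binary outcome is drawn from the logistic
model above with a planted lag curve, documented covariate effects, and
country intercepts (sd 0.3 by default). The default planted curve is a
geometric decay (ratio 0.7; effects immediate, fading over two weeks)
projected into the df-4 natural-spline lag family and rescaled to sum to
log 6.19 — the headline cumulative OR for not meeting MDD — so recovery
error reflects the estimator rather than basis misspecification. Covariate
distributions are simple documented defaults (sex Bernoulli(0.5), age
uniform 6–23, LAZ N(−1,1), wealth quintile uniform, urban Bernoulli(0.3),
3-level education); they exercise the adjustment machinery and do not mimic
survey marginals.

**Mode B (recall items).** Food-group flags are Bernoulli with
group-specific base rates and heat sensitivities on the logit scale,
sharing the normalised planted lag shape; cumulative sensitivities default
to the published food-group ordering (vegetables/vitamin-A-rich fruits
log 5.82 down to breastfeeding log 1.93). Meal counts are Poisson with a
heat-shifted log-mean, milk feeds Poisson, breastfeeding Bernoulli with an
age-declining rate. Indicators are never stored — downstream code must
derive them. Food groups are conditionally independent given exposure; the
real joint dependence among groups is unknown, so mode B makes no claim to
match it. Interview dates are uniform over a configurable window (default
2000–2019) with ≥21 days of prior climate guaranteed so the lag-20
sensitivity analysis is always runnable.

What passing recovery tests do and do not show: they demonstrate that the
estimator recovers effects generated under its own assumptions (correct
lag family, logistic link, Gaussian intercepts, conditionally independent
items) at survey scale. They cannot speak to violations absent from the
generator — spatial cluster displacement, survey weighting, informative
missingness, reporting error under heat stress, or dependence among recall
items.

## Validation study sizes

The suite validates at these problem sizes, chosen to make Monte-Carlo
error small relative to the quantities checked:

* detector–oracle equivalence: 100 series × 10,000 days × 6 definitions;
* indicator truth table: all 18 × 2 × 7 × 7 × 256 rule-branch combinations;
* cumulative log-OR bias: 50 replicates at n = 50,016 (6 countries × 8
  clusters × 1,042 children), 2-year interview window — bias < 0.05;
* CI coverage: 200 replicates at n = 8,016 (coverage is a property of the
  interval, not of n, so a smaller cohort buys replicates);
* Wald null calibration: 500 identical-truth stratum pairs, single-country
  strata of n ≈ 2,100 (exercising the documented few-group fallback).

`scripts/acceptance.py` re-runs the same machinery at comparable sizes and
writes the recomputed quantities as JSON.

## Known limitations

* The Laplace approximation can be biased for very small groups or extreme
  prevalences; adaptive quadrature is not implemented (the quadrature-point
  hook is the natural extension).
* NetCDF ingestion uses the scipy backend (NetCDF3); NetCDF4/HDF5 gridded
  inputs should be converted or supplied as long-format CSV.
* No survey weights or design-based variance; no apparent-temperature or
  indoor-temperature exposure models; thresholds use all calendar days.
* The "country or region" grouping is implemented as country with a region
  switch; regions must be supplied as a column.
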