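# heatfeed

Distributed-lag analysis of heatwave effects on infant and young child
feeding practices.

Child feeding in the first two years of life is measured by three WHO
indicators derived from a 24-h dietary recall: **MDD** (minimum dietary
diversity, ≥5 of 8 food groups), **MMF** (minimum meal frequency, an age-
and breastfeeding-specific feed count) and **MAD** (minimum acceptable
diet, a composite of both). `heatfeed` is a toolkit for epidemiologists
studying how short-term heat extremes disrupt these practices in
household-survey data linked to reanalysis climate: it detects
percentile-defined heatwaves, matches lagged exposure to interview dates,
classifies the indicators, and fits mixed-effects distributed-lag logistic
models with cumulative odds-ratio inference, effect-modification tests and
a prespecified sensitivity suite.

## The model

A heatwave at a survey cluster is a run of ≥2 or ≥3 consecutive days with
daily mean temperature above the location's 92.5th/95th/97.5th percentile
(six canonical definitions). For child *i* in country *c*, with exposure
vector *h<sub>i</sub>* of heatwave-day flags over lags 0–14 (lag 0 = the
recall day, the day before interview) and *y* = 1 when the standard was
**not** met:

&nbsp;&nbsp;&nbsp;&nbsp;logit P(y<sub>ic</sub> = 1) =
**x**<sub>ic</sub>ᵀγ + (**B**ᵀ**h**<sub>i</sub>)ᵀβ + u<sub>c</sub>,
&nbsp; u<sub>c</sub> ∼ N(0, σ²)

where **B** is a natural cubic spline basis over lag (4 df, two internal
knots equally spaced on the log-lag scale) and **x** holds child, maternal
and household covariates, year/month fixed effects and the cluster's
12-month mean temperature. Estimation maximises the Laplace-approximated
marginal likelihood (it matches `lme4::glmer` to ~1e-2, asserted in the
tests). The cumulative effect over the lag window is the delta-method
contrast c = Σ<sub>k</sub> b<sub>k</sub>, reported as an odds ratio with
95% CI; strata are compared with multivariate Wald tests on the
cross-basis coefficients.

Because the survey microdata and reanalysis grids require application /
bulk download, the package ships a first-class synthetic-data generator
(`heatfeed.synthetic`) that emulates both inputs with a known planted
exposure–outcome structure, so the entire pipeline is validated by
parameter recovery. See `docs/methods.md` for conventions and defaults.

## Worked example

```bash
python examples/04_dlm_parameter_recovery.py
```

```
n = 19200, method = laplace, country intercept sd = 0.247
planted cumulative OR: 6.19
estimated cumulative OR: 6.45 (95% CI 4.53-9.20)

lag-specific odds ratios (planted vs estimated):
  lag  0: planted 1.714  estimated 1.779 [1.535, 2.063]
  lag  2: planted 1.317  estimated 1.300 [1.223, 1.382]
  ...
  lag 14: planted 1.003  estimated 1.037 [0.955, 1.125]
```

A cohort of 19,200 children was simulated with a planted lag-distributed
heatwave effect whose 14-day cumulative odds ratio of not meeting the
feeding standard is 6.19; the fitted distributed-lag mixed model estimates
6.45 with a 95% CI covering the truth, and the estimated lag curve tracks
the planted immediate-then-decaying shape. The other scripts in
`examples/` walk through each capability: cohort simulation, heatwave
detection and exposure matching, indicator classification and
descriptives, effect modification and the sensitivity suite.

The same machinery is available as a thin CLI for file-based runs:

```bash
heatfeed simulate --out sim --seed 1 --mode B \
    --interview-start 2010-01-01 --interview-end 2011-12-31
heatfeed all --climate sim/climate.csv --records sim/records.csv --out run
```

which writes heatwave calendars, indicator tables, the fitted model, the
cumulative/lag-specific odds ratios and a provenance manifest under `run/`.

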