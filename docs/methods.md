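# Methods

## The problem

Tropical cyclones disrupt health care, power, transport and housing, and
the epidemiological signal of those disruptions shows up in daily
hospitalization counts in the days surrounding a storm's passage.
`stormlag` implements the standard design for estimating that signal when
the exposure is a rare, dated event: a **matched exposed/unexposed-day
design** combined with a **distributed-lag Poisson regression**, plus the
stratified analyses used to ask whether the risk differs by individual
characteristics (age, sex, dual Medicaid eligibility) or by community
characteristics (poverty, density, homeownership, ...).

Because individual-level hospitalization data are restricted, the package
ships a synthetic-data generator that is the exact forward model of the
regression being fit. Every downstream stage — exposure processing,
matching, model fitting, stratification — is tested against generated data
with known parameters.

## Exposure

A spatial unit (county or ZCTA) is storm-exposed when the modeled peak
sustained windspeed reaches **21 m/s** (strong gale; roughly the
tropical-storm threshold), a closed lower bound. County-level exposures
are downscaled to ZCTAs by assigning each ZCTA the full storm list of the
county containing the largest share of its land area; equal shares break
deterministically to the smallest county identifier (logged). Each storm
contributes one exposed day per ZCTA: the closest-approach date. Per-ZCTA
summary metrics are the storm count, mean intensity, and the intensity of
the most severe storm. Windspeed is m/s everywhere inside the pipeline;
unit conversion is an I/O concern.

## Matched day design

Each exposed day is matched, within its ZCTA, to up to 10 control index
days that (1) fall in a different calendar year, (2) lie within ±7 days of
the exposed day's day-of-year, (3) are more than 3 calendar days from
every storm day in that ZCTA, and (4) have a full −2..+7 lag window inside
the study period. Around every index day the 10-day window supplies the
observation days, so a fully matched storm-ZCTA contributes
(1 + 10) × 10 = **110 day-rows**.

Numerical conventions, where the design leaves room:

* **Leap years.** Day-of-year distance uses a fixed 365-day calendar with
  Feb 29 mapped onto Feb 28, so the ±7-day seasonal window does not drift
  across leap years; distances to other storms use true calendar-day
  differences. The brute-force oracle in the tests re-derives the same
  convention independently per day.
* **The 3-day exclusion** is inclusive (|d − storm| ≤ 3 excluded) and
  applies to the candidate index day only, not to its whole window.
  Control windows may therefore overlap each other or contain another
  storm's lagged days; only index-day eligibility is enforced.
* **Deficits.** When fewer than 10 candidates exist, all of them are used
  and the deficit logged (a `require_full` switch drops short sets
  instead). Sets with zero candidates are dropped, logged.
* Control days are sampled uniformly without replacement from the sorted
  candidate list with a single seeded generator recorded in the run
  manifest; reruns are bit-identical.

A consequence of overlapping windows is that the same (zcta, date)
observation can appear in several rows of the model table. At an 18-year
study length roughly 15% of rows are such duplicates; they understate
standard errors slightly (observed z-score SD ≈ 1.03 under the null).
This is inherent to the design being implemented, not an artifact of this
implementation, and is visible in the calibration results below.

## The model

For the daily count in ZCTA *z* on day *t*:

log E[Y_tz] = α + α_z + Σ_{l=−2..7} β_l x_{t+l,z} + log n_z(T)
            + δ′DOW_t + γ′Year_t,   α_z ~ N(0, σ²)

`x` are the lag indicators (1 only on exposed-window rows at their own
lag), the offset is the log beneficiary denominator for the row's
ZCTA-year, day-of-week is categorical with Monday as reference, year is
categorical with the first year as reference. exp(β_l) is the lag-l
relative risk; exp(Σβ_l) is the cumulative 10-day RR, with a delta-method
SE √(1′V1) over the lag block of the covariance.

**Fitting.** Random intercepts are independent across ZCTAs, so the
marginal likelihood factors by cluster. For a fixed σ² the fixed effects
and cluster modes are maximized jointly by penalized IRLS (Newton steps
with step halving, guaranteeing monotone ascent); the Laplace correction
−½ Σ_z log(1 + σ² W_z), with W_z the cluster's total fitted mean, turns
the penalized maximum into an approximate marginal log-likelihood, which
an outer bounded one-dimensional search maximizes over log σ. The σ → 0
limit is the plain Poisson GLM, which is fit first (warm start) and
retained whenever the variance profile peaks at the boundary. Fixed-effect
covariance comes from the joint (β, b) Hessian at the optimum.
Convergence: relative log-likelihood change ≤ 1e−8, at most 200 inner
iterations; non-convergence is an explicit status and RR extraction
refuses such fits. If the GLMM path fails outright, a documented fallback
refits with fixed ZCTA indicator terms (`method="glm_fixed_zcta"`).

**Separation.** A lag whose indicator never appears, or appears only with
zero counts, is dropped from the design and reported with β = −∞ and
infinite SE; the cumulative RR is then flagged unavailable rather than
computed from a divergent sum.

**Intervals** are Wald, 95% by default. No overdispersion correction is
applied (the model is Poisson by construction and by the generator).

## Stratified analyses

*Community*: the model table is partitioned by a ZCTA-level
above/below-median label and the model is refit per stratum.
*Individual*: the same matched windows are reused with subgroup-specific
counts and offsets. Strata are compared with a two-sample z test on
log-RRs, z = (logRR_a − logRR_b)/√(se_a² + se_b²), valid because strata
are fit on disjoint data. No multiplicity adjustment is applied across
the ten community stratifiers; a Bonferroni column is emitted alongside
for transparency.

## Community covariates

Ten covariates per ZCTA (education, poverty, income, percent non-English,
household density, housing value, population density, percent urban,
percent Black, percent owner-occupied) are collapsed to fixed period
values: area-weighted interpolation across boundary vintages (new value =
Σ w·old / Σ w; zero-weight units flagged missing), then time-weighted
averaging over census observations. The above/below split uses the
state-wide median; **ties at the median are labeled "below"** — an
arbitrary but deterministic rule. Stability of the binary labels is
checked via Pearson's r between period start and end and the fraction of
units crossing the period median (period value = mean of start and end);
defaults demand r ≥ 0.85 and ≥ 92% staying on one side. Note the two are
linked: for jointly normal start/end values the expected crossing
fraction is arccos(r)/π, so <8% crossing requires r ≳ 0.97 — a median
split is only trustworthy for strongly persistent covariates. Storm
metrics are compared across strata with Welch's t by default (a pooled
option exists).

## The synthetic generator

The generator draws, in fixed seeded order: (1) ten community covariates
from a Gaussian copula with a realistic correlation structure (income ↔
housing value 0.7, income ↔ poverty −0.55, density cluster 0.5–0.75, ...),
mapped to plausible marginal scales; (2) a storm calendar — each ZCTA
gets Poisson(rate × years) storms, dated uniformly in June–November,
windspeeds from a normal truncated at 21 m/s; (3) annual beneficiary
denominators per ZCTA-year; (4) Poisson counts for **every** ZCTA-day
from the model equation above, at the resolution of 12 age × sex × dual
subgroups by multinomial thinning of the ZCTA-day total (so subgroup
counts sum exactly to totals). Effect modification is simulated by adding
a log-RR (e.g. ln 2) to chosen lags in ZCTAs above the median of a chosen
covariate.

Default calibration targets an 18-year coastal-state Medicare setting:
0.226 storms per ZCTA-year (≈ 4.1 storms per ZCTA over 18 years),
truncated-normal windspeed with mean ≈ 27.6 m/s, denominators 2 000–10 000
with baseline log rate −9.4 (≈ 0.5 events per ZCTA-day), random-intercept
SD 0.15, small day-of-week effects. The packaged `configs/recovery.yaml`
uses a respiratory-like lag profile whose cumulative RR is 4.37.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: storms are independent across ZCTAs (no
shared wind field), counts have no overdispersion beyond the random
intercept, no day-to-day autocorrelation within a ZCTA, no seasonality
beyond what matching absorbs, denominators are exact rather than
enrollment estimates, and covariates are error-free. Recovery and
calibration results certify the estimator under its own assumptions, not
robustness to their violation.

## Problem sizes and replicate budgets

Replicated checks use scenarios sized so that each lag carries enough
events for Wald asymptotics to hold: with E events at a lag, the
log-link's finite-sample bias (≈ −1/(2E) per lag) shifts the cumulative
z-score by ≈ 1.6/√E, so scenarios around 1 event per ZCTA-day and ≥150
matched sets keep that shift below ~0.15. The null-calibration suite runs
500 replicates of a 40-ZCTA scenario (coverage band 93–97%); the
effect-modification suite runs 200 replicates of the ln-2 lag-0 doubling
scenario; parameter recovery runs one full-size 100-ZCTA, 18-year fit.
All replicate seeds are derived arithmetically from documented bases.

## Known limitations

* The Laplace approximation profiles σ² and conditions the fixed-effect
  covariance on σ̂²; with very few clusters (≲10) the variance itself is
  poorly determined (its estimate is reported, not its uncertainty).
* Duplicated window days (above) bias SEs slightly downward; the effect
  shrinks with study length because same-year control collisions get
  rarer.
* Quasi-Poisson scaling is available as an option but off by default;
  real claims data may be overdispersed beyond the random intercept.
* The exposure module takes modeled windspeeds as given; no wind-field
  modeling, proximity computation, or rainfall/flood metrics.
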