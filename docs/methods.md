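# Methods

## Scientific setting

Short-term exposure to fine particulate matter (PM2.5) raises daily
mortality, and because the deaths it advances occur at specific ages, it
also costs years of life. This package implements a two-stage time-series
analysis that quantifies that cost and translates it into policy-relevant
counterfactuals: how many years of life lost (YLL) would be avoided — and
how much life expectancy gained per death — if daily PM2.5 never exceeded a
given air-quality standard.

The intended data are per-city daily death registries with age and sex,
daily city-mean pollutant concentrations, and daily weather, across many
cities grouped into seven administrative regions. Such registry data are
not redistributable, so the package ships a synthetic multi-city generator
with known ground truth; every statistical claim the test suite makes is a
claim about recovery of that ground truth.

## Years of life lost

Each death contributes the remaining life expectancy e_x at the decedent's
exact age and sex, read from a sex-specific abridged life table (ages
0, 1, 5, ..., 85). Within abridged bands e_x is linearly interpolated;
this is the simplest rule that is exact at band bounds, and the table does
not record curvature within bands anyway. Ages at or beyond the open-ended
top band use the top band's e_x, matching the convention of abridged
national tables that end at 85+. Daily city YLL is the sum of e_x over that
day's deaths; days with no deaths carry zero. No discounting or
age-weighting is applied.

The packaged life-table generator is a synthetic stand-in for a national
life table: a Gompertz force of mortality mu(x) = a*exp(0.085x) with the
sex-specific level a calibrated by root-finding so that life expectancy at
birth is about 78.7 (female) and 73.8 (male) years — sex-averaged ~76.25,
the national value the analysis is benchmarked against. A small
seed-dependent common shift (±0.3 years) varies tables across seeds without
breaking monotonicity or the female ≥ male ordering.

## First stage: city-specific regression

Daily YLL is continuous and approximately Gaussian at realistic death
counts, so the outcome model is a Gaussian-likelihood additive regression:

    YLL_t = beta * PM25_t(lag) + s(t) + s(temp_lag03) + s(rh)
            + dow + holiday + alpha + eps_t

* **Exposure term**: linear in the lagged PM2.5, entered on the per-10
  ug/m3 scale so `beta` is directly the effect per 10 ug/m3. Lag
  structures: single lags 0–3 and moving averages lag01/lag02/lag03
  (current day plus previous 1/2/3 days); lag02 is the default and the
  basis of the counterfactual layer. Days with an incomplete lag window
  are dropped.
* **Smooth terms**: fixed-df natural cubic regression splines with knots at
  equally spaced quantiles — time trend at 6 df per year (total
  `round(6 * n_days / 365.25)`, floored at 4), the lag03 moving-average
  temperature at 6 df, same-day relative humidity at 3 df. The raw
  cubic-regression-spline basis spans the constant, so each basis is
  centered and reduced by pivoted QR to df columns orthogonal to the
  intercept (the `ns()` convention). Fixing df a priori makes the fit a
  deterministic least-squares problem with the intended effective
  dimension; it forgoes data-driven smoothness estimation, a documented
  stand-in for penalized smoothers rather than a claim of equivalence.
* **Categorical terms**: six day-of-week indicators (Monday reference) and
  a public-holiday indicator (omitted automatically when no holiday falls
  in the estimation window, where it would be an all-zero column).
* **Two-pollutant models** add one co-pollutant (SO2, NO2 or O3) linearly
  at the same lag structure as PM2.5 — the least arbitrary choice since
  nothing pins down a different co-pollutant lag.

Rows with any missing covariate are dropped (never imputed); at least 365
usable days are required. Rank deficiency is detected before fitting and
reported with the offending columns. The 95% CI is beta ± 1.96 se.
Diagnostics per fit: residuals, partial autocorrelation at lags 1–30
(Yule–Walker), and Gaussian Q-Q pairs.

## Second stage: random-effects pooling

City coefficients are pooled per region and nationally with the
DerSimonian–Laird method-of-moments estimator (fixed-effect weights
1/se², Cochran's Q, tau² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), random-effect
weights 1/(se²+tau²), I² = max(0,(Q−(k−1))/Q)·100). DL is the classical
default of the meta-analysis software this literature uses; REML is out of
scope. The national estimate pools all city effects directly rather than
pooling the regional pools — which is why the national counterfactual
burden is not the sum of the regional rows: each level applies its own
pooled coefficient.

Meta-regression fits weighted least squares of the city coefficients on one
IQR-scaled city-level covariate at a time (GDP, population density, annual
mean PM2.5, ...), with weights 1/(se²+tau²) using tau² from the
intercept-only model and the classical known-weights covariance (X'WX)⁻¹.
The annual-PM2.5 × GDP interaction model includes both scaled main effects
and their product and reports the product term's p-value. One-stage
sensitivity fits stack all city-days into a single regression, with either
per-city fixed intercepts (a fixed-effect approximation of a random city
term) or 3-df longitude and latitude smooths; in the spatial mode the
city-level design is limited to k−1 columns, so it needs enough distinct
city locations (≥ 8 in practice).

## Counterfactual layer

For a standard with threshold C (WHO AQG 25, IT-3 37.5, IT-2 50,
IT-1/NAAQS 75 ug/m3):

    avoidable YLL = (beta/10) * sum over city-days of max(0, xbar_t − C)
    PGLE = avoidable YLL / total deaths
    AF   = avoidable YLL / total YLL

with xbar_t the lag02 exposure, matching the lag of the pooled coefficient.
CI bounds substitute the beta CI endpoints (linear plug-in), which
reproduces the symmetric intervals this type of analysis reports. Days
with an incomplete lag window are excluded from the exceedance sum *and*
from the totals, keeping numerator and denominators on the same day set;
because of that convention, indicators are exactly additive across cities,
and additive across a mid-series split only up to the lag-window days lost
at the split boundary. Negative coefficients (or CI bounds) are floored at
zero with a warning — benefit from dirtier air is not modelled.

## Synthetic data generator

The generator's daily mean is exactly the additive form the first stage
assumes, so the estimator is correctly specified up to the spline
approximation of the seasonal terms:

* **Deaths**: Poisson with a constant city rate; regional default rates
  (5.32–12.89 deaths/day) follow the descriptive table of the 72-city
  study the package targets. Each death draws age from a truncated Normal
  (mean 71.72, SD 16.74 on [0, 110]) and sex (44% female), and contributes
  its life-table e_x.
* **Exposure**: regional seasonal mean (winter peak, fractional amplitude
  0.30) plus AR(1) anomalies (coefficient 0.6, innovation SD 40% of the
  regional mean), truncated at 0. Regional PM2.5 levels default to the
  study's descriptive values (49.29 Northwest ... 95.90 North ug/m3);
  per-city levels jitter log-normally (SD 0.15). Co-pollutants share part
  of the PM anomaly so the pooled Spearman correlations are plausible
  (NO2 strongest, ~0.5); O3 peaks in summer.
* **Outcome**: daily YLL = death-based YLL + (beta/10)·(lag02 PM2.5 −
  regional mean) + seasonal winter-excess term (amplitude 10 years) +
  a mild U-shaped same-day temperature term + Gaussian noise (SD 10
  years). The effect term is centred on the *fixed* regional mean, so
  shifting the whole exposure series by d shifts mean YLL by beta·d/10
  exactly. The true effect defaults to 0.43 years per 10 ug/m3 — the
  benchmark value for recovery tests. On the rare zero-death days the
  series is forced to zero YLL to keep the data-model invariant; this
  perturbs the additive mean negligibly (P(0 deaths) < 0.005 at the
  default rates).
* **Streams and determinism**: exposure, weather, deaths and noise use
  independently spawned RNG streams from one seed; outputs are
  byte-identical across runs, and injecting a custom exposure series
  leaves the simulated deaths unchanged. `mean_only=True` replaces the
  stochastic components by their expectations, producing the exact
  generative mean used by noiseless-identifiability tests.

What the generator does **not** emulate: spatially correlated exposure
fields across cities, mortality displacement/harvesting dynamics, seasonal
death-rate variation beyond the smooth YLL term, co-pollutant confounding
of the true effect (the generative outcome depends only on PM2.5), and
measurement error in exposure. Passing recovery tests therefore shows the
estimator is correct for a well-specified additive world, not that the
real-data coefficient is unbiased.

The default study configuration matches the target analysis: 7 regions
with 8/6/7/8/24/11/8 cities (72 total) and 1444 daily observations
(2013-01-18 to 2016-12-31). At these sizes the national pooled standard
error comes out near 0.07 years per 10 ug/m3, essentially the precision
the real 72-city analysis reports — individual-seed national estimates
therefore scatter around the true 0.43 with that spread, and the designed
check is CI coverage rather than point equality. The replicated
calibration experiments use 12 cities × 730 days × 200 replicates, sized
to give stable coverage/type-I estimates in a few minutes of CPU.

## Numerical choices and edge cases

* CI multiplier fixed at 1.96 everywhere (normal approximation).
* tau² and I² are floored at 0; I² is defined as 0 when Q = 0; k = 1 pools
  to the single effect with tau² = Q = 0.
* Spearman correlations pool all city-days pairwise-complete; a constant
  variable yields an undefined (NaN) correlation.
* PACF values are clipped to [−1, 1]; a degenerate perfect fit reports
  zero PACF.
* Dates are ISO-8601 in files; the daily grid is closed on both ends;
  CSV round-trips preserve floats to full double precision (%.17g).
* Day-of-week reference level is Monday; the holiday calendar is supplied
  by file and empty by default.

## Known limitations

Fixed-df regression splines are not penalized smoothers; effects are
linear in exposure (no distributed-lag non-linear structure); the
one-stage "mixed" fit approximates the random city term by fixed
intercepts; meta-regressions are univariable by design except the stated
interaction model; uncertainty in the counterfactual layer reflects only
the pooled coefficient, not exposure measurement error or life-table
uncertainty.
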