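# pm25yll

Two-stage health impact assessment of short-term fine-particulate pollution
(PM2.5) on **years of life lost (YLL)**, with counterfactual burden
indicators under air-quality standards.

The package is aimed at environmental epidemiologists working with
multi-city daily time series: death registry records (date, age, sex),
daily city-mean pollutant concentrations, and weather. It implements:

1. **YLL engine** — each death contributes its remaining life expectancy
   e_x (sex-specific abridged life table, linear interpolation within age
   bands); daily city YLL is the sum over that day's deaths.
2. **First stage** — a city-specific Gaussian additive regression

       YLL_t = β·PM2.5_t(lag02) + s(t, 6 df/yr) + s(temp_lag03, 6 df)
               + s(rh, 3 df) + day-of-week + holiday + α

   with fixed-df natural cubic regression splines, reported per
   10 μg/m³; single-lag (lag0–lag3) and moving-average (lag01–lag03)
   structures and two-pollutant models are supported.
3. **Second stage** — DerSimonian–Laird random-effects meta-analysis
   pooling city coefficients to regional and national levels (τ², Q, I²),
   meta-regression on IQR-scaled city covariates (incl. a PM×GDP
   interaction), and one-stage pooled sensitivity fits.
4. **Counterfactual layer** — avoidable YLL under a standard with
   threshold C,

       avoidable YLL = (β/10) · Σ_city-days max(0, x̄_t − C)
       PGLE = avoidable YLL / total deaths      (years gained per death)
       AF   = avoidable YLL / total YLL         (attributable fraction)

   at the WHO guideline (25 μg/m³) and its interim targets
   (37.5 / 50 / 75 μg/m³; 75 is also the Chinese national standard).
5. **Synthetic generator** — because city-level death registries are not
   redistributable, a deterministic multi-city generator with known ground
   truth (default true effect 0.43 years per 10 μg/m³, 72 cities,
   1444 days) backs all testing and examples.

See `docs/methods.md` for the model, assumptions, and design choices.

## Worked example

```python
from pm25yll import (SyntheticTruth, generate_study, fit_city_gam,
                     pool_random_effects, impact_table, STANDARDS)

# a small five-city study, 600 days, true effect 0.43 per 10 ug/m3
dataset, truth = generate_study({"East": 3, "North": 2},
                                SyntheticTruth(seed=5), n_days=600, seed=5)
effects = [fit_city_gam(s)[0] for s in dataset.series]
pooled = pool_random_effects(effects)
print(f"pooled beta {pooled.beta_per10:.3f} "
      f"(95% CI {pooled.ci95[0]:.3f}..{pooled.ci95[1]:.3f}), "
      f"tau2 {pooled.tau2:.3f}, I2 {pooled.I2:.1f}%")

rows = impact_table({"National": dataset.series}, {"National": pooled}, STANDARDS)
r = rows[0]  # WHO guideline, 25 ug/m3
print(f"{r.standard.name}: avoidable YLL {r.avoidable_yll:,.0f} "
      f"PGLE {r.pgle:.3f} AF {100 * r.af:.2f}%")
```

prints

```
pooled beta 0.469 (95% CI -0.254..1.193), tau2 0.000, I2 0.0%
AQG: avoidable YLL 7,329 PGLE 0.226 AF 1.46%
```

i.e. the five-city pooled estimate 0.469 brackets the generator's true
0.43 (with only five short series the CI is wide and its lower bound is
floored at zero in the counterfactual, with a warning); capping every
day's three-day-average PM2.5 at 25 μg/m³ would have averted ~7.3k years
of life lost, about 0.23 years per death, 1.5% of this small study's YLL
burden.

The same analysis runs from a shell via the `hia` CLI:

```sh
hia simulate --config cfg.yaml   # write deaths/exposure/weather CSVs + truth.json
hia run      --config cfg.yaml   # full two-stage run -> report tables + manifest
hia impact   --effects out/pooled_effects.csv --data data/ --standards 25,37.5,50,75
```

`hia run` accepts either an assembled study directory (`series.csv`) or raw
inputs (`deaths.csv`, `exposure.csv`, `weather.csv`, `lifetable.csv`,
`citymeta.csv`), in which case daily YLL is recomputed from the individual
death records and the life table.

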