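"""Synthetic multi-city study generator with known ground truth.

The real 72-city mortality data come from a national disease-surveillance
registry and are not redistributable, so every downstream stage is exercised
on simulated data whose generative mean has exactly the additive form of the
first-stage regression:

    YLL_t = (life-table YLL of the day's deaths)
            + (beta_per10 / 10) * (lag02 PM2.5_t - regional mean)
            + seasonal term + temperature term + Gaussian noise

Deaths are Poisson; each death draws an age from a truncated Normal
(mean 71.72, SD 16.74, on [0, 110]) and a sex (44% female), matching the
descriptive statistics of the study population the pipeline targets.
Exposures are seasonal means plus AR(1) noise, truncated at zero, with
regional levels defaulting to the study's descriptive table. The exposure,
death and noise random streams are spawned independently from the one seed,
so injecting a custom exposure series leaves the simulated deaths unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .datamodel import (
    REGIONS,
    CityDailySeries,
    CityMeta,
    DeathRecord,
    LifeTable,
    StudyDataset,
    daily_grid,
)
from .yll import remaining_life_expectancy

__all__ = [
    "SyntheticTruth",
    "generate_life_table",
    "generate_city_series",
    "generate_study",
    "DEFAULT_CITIES_PER_REGION",
    "DEFAULT_START",
    "DEFAULT_N_DAYS",
]

# Study window of the target analysis: 2013-01-18 .. 2016-12-31, 1444 days.
DEFAULT_START = Date(2013, 1, 18)
DEFAULT_N_DAYS = 1444

#: City counts per region in the default configuration (total 72).
DEFAULT_CITIES_PER_REGION: dict[str, int] = {
    "Northwest": 8,
    "North": 6,
    "Northeast": 7,
    "Central": 8,
    "East": 24,
    "Southwest": 11,
    "South": 8,
}

# Regional daily means (pollutants ug/m3, temp degC, rh %, deaths/day) used
# as generator defaults so synthetic descriptive tables are face-valid.
REGIONAL_MEANS: dict[str, dict[str, float]] = {
    "Northwest": dict(pm25=49.29, so2=34.20, no2=26.80, o3=77.72, temp=10.39, rh=49.31, deaths=5.32),
    "North": dict(pm25=95.90, so2=53.94, no2=48.99, o3=100.69, temp=13.33, rh=56.31, deaths=9.68),
    "Northeast": dict(pm25=64.47, so2=45.82, no2=39.96, o3=87.33, temp=7.35, rh=62.91, deaths=10.20),
    "Central": dict(pm25=71.27, so2=31.50, no2=34.99, o3=66.75, temp=16.85, rh=72.95, deaths=9.77),
    "East": dict(pm25=71.05, so2=41.60, no2=37.24, o3=92.76, temp=15.93, rh=71.19, deaths=12.39),
    "Southwest": dict(pm25=52.82, so2=28.76, no2=29.73, o3=72.28, temp=15.40, rh=65.11, deaths=8.06),
    "South": dict(pm25=51.94, so2=27.15, no2=32.02, o3=76.04, temp=21.84, rh=77.79, deaths=12.89),
}

# Rough bounding boxes (lon_min, lon_max, lat_min, lat_max) per region for
# drawing plausible city coordinates.
_REGION_BBOX = {
    "Northwest": (85.0, 107.0, 34.0, 45.0),
    "North": (110.0, 119.0, 36.0, 42.0),
    "Northeast": (121.0, 130.0, 41.0, 48.0),
    "Central": (109.0, 116.0, 28.0, 34.0),
    "East": (115.0, 122.0, 27.0, 35.0),
    "Southwest": (98.0, 108.0, 23.0, 31.0),
    "South": (106.0, 117.0, 20.0, 25.5),
}

_REGION_CODE = {
    "Northwest": "NW",
    "North": "NO",
    "Northeast": "NE",
    "Central": "CE",
    "East": "EA",
    "Southwest": "SW",
    "South": "SO",
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of the synthetic study.

    ``beta_per10`` is the true short-term effect: years of daily YLL added
    per 10 ug/m3 increase in lag02 PM2.5. ``trend_amplitude`` is the peak
    amplitude (years) of the smooth winter-excess seasonal term in daily YLL.
    """

    beta_per10: float = 0.43
    trend_amplitude: float = 10.0
    seasonal_period: float = 365.25
    temp_effect_amplitude: float = 3.0  # years per ((temp-optimum)/10)^2
    temp_optimum: float = 18.0  # degC
    yll_noise_sd: float = 10.0  # years/day, on top of death-count variation
    age_mean: float = 71.72
    age_sd: float = 16.74
    female_fraction: float = 0.44
    exposure_ar1: float = 0.6
    exposure_innovation_cv: float = 0.40  # innovation SD as fraction of mean
    exposure_seasonal_amplitude: float = 0.30  # fractional winter swing
    beta_city_sd: float = 0.0  # between-city SD of the true effect
    regional_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: REGIONAL_MEANS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.female_fraction <= 1):
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

_ABRIDGED_AGES = np.array([0, 1] + list(range(5, 90, 5)), dtype=float)  # 0,1,5..85
_GOMPERTZ_B = 0.085


def _gompertz_e0(a: float, b: float = _GOMPERTZ_B) -> float:
    x = np.linspace(0, 120, 4801)
    surv = np.exp(-a / b * (np.exp(b * x) - 1.0))
    return float(np.trapezoid(surv, x))


def _gompertz_ex(a: float, ages: np.ndarray, b: float = _GOMPERTZ_B) -> np.ndarray:
    x = np.linspace(0, 130, 5201)
    surv = np.exp(-a / b * (np.exp(b * x) - 1.0))
    # e_x = int_x^inf S(t) dt / S(x), evaluated by cumulative trapezoid
    dx = x[1] - x[0]
    tail = np.concatenate([np.cumsum((surv[::-1][:-1] + surv[::-1][1:]) / 2 * dx)[::-1], [0.0]])
    return np.interp(ages, x, tail / np.maximum(surv, 1e-300))


def generate_life_table(seed: int = 0, year: int = 2016) -> LifeTable:
    """A synthetic abridged life table (ages 0, 1, 5, ..., 85) for both sexes.

    Remaining life expectancies follow a Gompertz mortality schedule with
    sex-specific level calibrated so that the sex-averaged life expectancy at
    birth is near 76.25 years (female above male at every age). A small
    seed-dependent common shift (within +/-0.3 years at birth) varies the
    table across seeds without breaking its ordering invariants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11FE]))
    shift = float(rng.uniform(-0.3, 0.3))
    targets = {"female": 78.70 + shift, "male": 73.80 + shift}
    entries: dict[tuple[str, float], float] = {}
    for sex, e0 in targets.items():
        a = brentq(lambda a_: _gompertz_e0(a_) - e0, 1e-6, 1e-2, xtol=1e-12)
        ex = _gompertz_ex(a, _ABRIDGED_AGES)
        for age, e in zip(_ABRIDGED_AGES, ex):
            entries[(sex, float(age))] = float(e)
    return LifeTable(entries=entries, year=year)


def _mean_ex(lt: LifeTable, truth: SyntheticTruth) -> float:
    """Expected e_x of one death under the truncated-Normal age distribution."""
    from scipy.stats import truncnorm

    lo, hi = 0.0, 110.0
    a = (lo - truth.age_mean) / truth.age_sd
    b = (hi - truth.age_mean) / truth.age_sd
    grid = np.linspace(lo, hi, 1101)
    pdf = truncnorm.pdf(grid, a, b, loc=truth.age_mean, scale=truth.age_sd)
    out = 0.0
    for sex, w in (("female", truth.female_fraction), ("male", 1 - truth.female_fraction)):
        ex = np.interp(grid, lt.ages(sex), lt.ex(sex))
        out += w * float(np.trapezoid(ex * pdf, grid))
    return out


# ---------------------------------------------------------------------------
# City series
# ---------------------------------------------------------------------------

def _day_of_year(dates: np.ndarray) -> np.ndarray:
    years = dates.astype("datetime64[Y]")
    return (dates - years.astype("datetime64[D]")).astype(int) + 1.0


def _seasonal(doy: np.ndarray, period: float, peak_doy: float) -> np.ndarray:
    return np.cos(2 * np.pi * (doy - peak_doy) / period)


def _ar1(rng: np.random.Generator, n: int, phi: float, innov_sd: float) -> np.ndarray:
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    # start at stationary marginal variance
    x[0] = e[0] / np.sqrt(max(1.0 - phi**2, 1e-12))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def _partial_ma(x: np.ndarray, nback: int) -> np.ndarray:
    """Moving average of current + previous ``nback`` days, partial at start."""
    out = np.empty_like(x, dtype=float)
    for t in range(len(x)):
        lo = max(0, t - nback)
        out[t] = x[lo : t + 1].mean()
    return out


def _sample_ages(rng: np.random.Generator, n: int, truth: SyntheticTruth) -> np.ndarray:
    ages = rng.normal(truth.age_mean, truth.age_sd, size=n)
    bad = (ages < 0) | (ages > 110)
    while bad.any():
        ages[bad] = rng.normal(truth.age_mean, truth.age_sd, size=int(bad.sum()))
        bad = (ages < 0) | (ages > 110)
    return ages


def generate_city_series(
    truth: SyntheticTruth,
    meta: CityMeta,
    n_days: int,
    seed: int,
    life_table: LifeTable | None = None,
    start: Date = DEFAULT_START,
    pm25: np.ndarray | None = None,
    pm25_mean: float | None = None,
    deaths_per_day: float | None = None,
    mean_only: bool = False,
) -> tuple[CityDailySeries, list[DeathRecord]]:
    """Simulate one city's daily series and its individual death records.

    ``pm25`` injects a custom exposure series (same length as the window);
    the death/noise random streams are independent of the exposure stream, so
    two calls with the same seed and different exposures share their deaths.
    With ``mean_only=True`` the stochastic components are replaced by their
    expectations: the daily series is exactly the additive generative mean
    (constant baseline, effect, seasonal and temperature terms; no noise) and
    no death records are returned.
    """
    if n_days < 30:
        raise ValueError(f"n_days must be >= 30, got {n_days}")
    if life_table is None:
        life_table = generate_life_table(truth.seed)
    reg = truth.regional_means[meta.region]
    pm_mean = float(pm25_mean if pm25_mean is not None else reg["pm25"])
    lam = float(deaths_per_day if deaths_per_day is not None else reg["deaths"])

    ss = np.random.SeedSequence([int(seed), 0xC17F])
    rng_expo, rng_wx, rng_deaths, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    grid = daily_grid((start, start + timedelta(days=n_days - 1)))
    doy = _day_of_year(grid)
    period = truth.seasonal_period
    winter = _seasonal(doy, period, 15.0)  # peaks mid-January
    summer = _seasonal(doy, period, 196.0)  # peaks mid-July

    # Exposures: seasonal mean + AR(1) anomaly, truncated at 0. Co-pollutants
    # share part of the PM anomaly so cross-correlations are plausible.
    pm_anom = _ar1(rng_expo, n_days, truth.exposure_ar1, truth.exposure_innovation_cv * pm_mean)
    if pm25 is None:
        pm = np.maximum(0.0, pm_mean * (1 + truth.exposure_seasonal_amplitude * winter) + pm_anom)
    else:
        pm = np.asarray(pm25, dtype=float)
        if len(pm) != n_days:
            raise ValueError("injected pm25 series has wrong length")
    z = pm_anom / max(pm_anom.std(), 1e-12)

    def _copoll(mean: float, coupling: float, season: np.ndarray, amp: float, r: np.random.Generator):
        own = _ar1(r, n_days, 0.5, 0.30 * mean)
        return np.maximum(0.0, mean * (1 + amp * season) + coupling * mean * z + own)

    so2 = _copoll(reg["so2"], 0.12, winter, 0.30, rng_expo)
    no2 = _copoll(reg["no2"], 0.25, winter, 0.20, rng_expo)
    o3 = _copoll(reg["o3"], 0.12, summer, 0.35, rng_expo)
    temp = reg["temp"] + 11.0 * summer + rng_wx.normal(0, 2.5, n_days)
    rh = np.clip(reg["rh"] + 8.0 * summer + rng_wx.normal(0, 5.0, n_days), 0.0, 100.0)

    # Additive mean components. The effect term is centred on the *fixed*
    # regional mean so that shifting the whole exposure series by d shifts
    # mean YLL by beta_per10 * d / 10 exactly.
    beta = truth.beta_per10
    if truth.beta_city_sd > 0:
        beta = beta + float(
            np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE7A])).normal(
                0, truth.beta_city_sd
            )
        )
    effect = (beta / 10.0) * (_partial_ma(pm, 2) - pm_mean)
    seasonal = truth.trend_amplitude * winter
    temp_fx = truth.temp_effect_amplitude * ((temp - truth.temp_optimum) / 10.0) ** 2

    if mean_only:
        deaths = np.full(n_days, float(max(1, round(lam))))
        baseline = deaths * _mean_ex(life_table, truth)
        yll = np.maximum(0.0, baseline + effect + seasonal + temp_fx)
        series = CityDailySeries(
            city_id=meta.city_id, dates=grid, yll=yll, deaths=deaths,
            pm25=pm, so2=so2, no2=no2, o3=o3, temp=temp, rh=rh,
        )
        return series, []

    counts = rng_deaths.poisson(lam, size=n_days)
    total = int(counts.sum())
    ages = _sample_ages(rng_deaths, total, truth)
    female = rng_deaths.random(total) < truth.female_fraction
    day_idx = np.repeat(np.arange(n_days), counts)

    ex = np.empty(total)
    for sex, mask in (("female", female), ("male", ~female)):
        if mask.any():
            ex[mask] = np.interp(ages[mask], life_table.ages(sex), life_table.ex(sex))
    death_yll = np.bincount(day_idx, weights=ex, minlength=n_days)

    noise = rng_noise.normal(0.0, truth.yll_noise_sd, n_days) if truth.yll_noise_sd > 0 else 0.0
    yll = death_yll + effect + seasonal + temp_fx + noise
    yll = np.where(counts == 0, 0.0, np.maximum(0.0, yll))

    records = [
        DeathRecord(
            date=grid[i].astype(object),
            city_id=meta.city_id,
            age=float(a),
            sex="female" if f else "male",
        )
        for i, a, f in zip(day_idx, ages, female)
    ]
    series = CityDailySeries(
        city_id=meta.city_id, dates=grid, yll=yll, deaths=counts.astype(float),
        pm25=pm, so2=so2, no2=no2, o3=o3, temp=temp, rh=rh,
    )
    return series, records


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------

def _draw_city_meta(
    rng: np.random.Generator, region: str, city_id: str, pm_mean: float, lam: float,
    truth: SyntheticTruth,
) -> CityMeta:
    lon_lo, lon_hi, lat_lo, lat_hi = _REGION_BBOX[region]
    reg = truth.regional_means[region]
    gdp = float(rng.lognormal(mean=7.8, sigma=0.8))  # 100 million CNY
    pop_density = float(rng.lognormal(mean=6.2, sigma=0.7))  # persons/km2
    covs = {
        "gdp": gdp,
        "population_density": pop_density,
        "gdp_per_capita": float(rng.lognormal(mean=10.8, sigma=0.5)),
        "elevation": float(rng.uniform(5, 1500)),
        "precipitation": float(rng.uniform(300, 1800)),
        "poverty": float(rng.uniform(0.5, 15.0)),
        "education": float(rng.uniform(6, 13)),
        "annual_pm25": pm_mean,
        "annual_co": float(rng.uniform(0.6, 2.0)),
        "annual_o3": reg["o3"] * float(rng.lognormal(0, 0.10)),
        "annual_so2": reg["so2"] * float(rng.lognormal(0, 0.15)),
        "annual_no2": reg["no2"] * float(rng.lognormal(0, 0.12)),
        "air_pressure": float(rng.uniform(850, 1020)),
        "annual_temp": reg["temp"] + float(rng.normal(0, 1.5)),
        "annual_rh": float(np.clip(reg["rh"] + rng.normal(0, 4.0), 0, 100)),
        "mean_daily_deaths": lam,
    }
    return CityMeta(
        city_id=city_id,
        region=region,
        longitude=float(rng.uniform(lon_lo, lon_hi)),
        latitude=float(rng.uniform(lat_lo, lat_hi)),
        covariates=covs,
    )


def generate_study(
    n_cities_per_region: Mapping[str, int] | None = None,
    truth: SyntheticTruth | None = None,
    n_days: int = DEFAULT_N_DAYS,
    seed: int = 0,
    start: Date = DEFAULT_START,
    with_records: bool = False,
) -> tuple[StudyDataset, SyntheticTruth] | tuple[StudyDataset, SyntheticTruth, dict[str, list[DeathRecord]]]:
    """Generate a full multi-city study dataset with known ground truth.

    Defaults reproduce the target configuration: 7 regions, 72 cities,
    1444 daily observations per city. Per-city seeds are spawned
    deterministically from ``seed``; per-city exposure levels and death rates
    are log-normal jitters (SD 0.15 / 0.20 on the log scale) around the
    regional means, recorded in each city's metadata covariates.
    """
    if n_cities_per_region is None:
        n_cities_per_region = DEFAULT_CITIES_PER_REGION
    if truth is None:
        truth = SyntheticTruth(seed=seed)
    if not n_cities_per_region or sum(n_cities_per_region.values()) < 1:
        raise ValueError("need at least 1 region with >= 1 city")
    for region in n_cities_per_region:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")

    life_table = generate_life_table(seed)
    master = np.random.SeedSequence([int(seed), 0x57D7])
    rng_meta = np.random.default_rng(master.spawn(1)[0])

    series_list: list[CityDailySeries] = []
    metas: list[CityMeta] = []
    records_by_city: dict[str, list[DeathRecord]] = {}
    city_index = 0
    for region in REGIONS:
        k = n_cities_per_region.get(region, 0)
        reg = truth.regional_means[region]
        for j in range(k):
            city_id = f"{_REGION_CODE[region]}{j + 1:02d}"
            pm_mean = reg["pm25"] * float(rng_meta.lognormal(0, 0.15))
            lam = reg["deaths"] * float(rng_meta.lognormal(0, 0.20))
            meta = _draw_city_meta(rng_meta, region, city_id, pm_mean, lam, truth)
            city_seed = int(
                np.random.SeedSequence([int(seed), 0x5EED, city_index]).generate_state(1)[0]
                % 2**31
            )
            city_index += 1
            s, recs = generate_city_series(
                truth, meta, n_days, city_seed, life_table=life_table, start=start,
                pm25_mean=pm_mean, deaths_per_day=lam,
            )
            series_list.append(s)
            metas.append(meta)
            records_by_city[city_id] = recs

    dataset = StudyDataset(series=series_list, meta=metas, life_table=life_table)
    if with_records:
        return dataset, truth, records_by_city
    return dataset, truth
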