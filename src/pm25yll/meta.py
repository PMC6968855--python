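"""Second-stage pooling of city effects and meta-regression.

Regional and national effects pool the city-specific coefficients with a
DerSimonian–Laird (method-of-moments) random-effects model:

    w_i   = 1 / se_i^2                      (fixed-effect weights)
    b_F   = sum(w_i b_i) / sum(w_i)
    Q     = sum(w_i (b_i - b_F)^2)
    tau^2 = max(0, (Q - (k - 1)) / (sum(w) - sum(w^2)/sum(w)))
    w*_i  = 1 / (se_i^2 + tau^2)            (random-effect weights)
    b_R   = sum(w*_i b_i) / sum(w*_i),  se(b_R) = 1 / sqrt(sum(w*_i))
    I^2   = max(0, (Q - (k - 1)) / Q) * 100

The national estimate pools all city effects directly rather than the
regional pools, so national and regional counterfactual burdens need not
add up — each level uses its own pooled coefficient.

Meta-regression fits weighted least squares of the city coefficients on an
IQR-scaled city-level covariate with weights 1/(se_i^2 + tau^2), where tau^2
comes from the intercept-only model; coefficient covariance is the classical
(X' W X)^-1 with known weights, and p-values use the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import CityDailySeries, CityMeta
from .gam import Z95, CityEffect, GamSpec, LagSpec, _check_rank, _natural_spline, build_design

__all__ = [
    "PooledEffect",
    "MetaRegResult",
    "OneStageEffect",
    "pool_random_effects",
    "meta_regression",
    "fit_pooled_gam",
]


@dataclass(frozen=True)
class PooledEffect:
    """A pooled (regional or national) PM2.5 effect per 10 ug/m3."""

    level: str
    beta_per10: float
    se_per10: float
    ci95: tuple[float, float]
    tau2: float
    Q: float
    I2: float
    k: int

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not (0 <= self.I2 <= 100):
            raise ValueError("I2 must lie in [0, 100]")


@dataclass(frozen=True)
class MetaRegResult:
    """Meta-regression of city effects on one IQR-scaled covariate."""

    covariate: str
    iqr: float
    slope_per_iqr: float
    se: float
    p_value: float
    interaction_p: float | None = None

    def __post_init__(self) -> None:
        if not self.iqr > 0:
            raise ValueError("covariate IQR must be > 0")


@dataclass(frozen=True)
class OneStageEffect:
    """PM2.5 effect from a pooled (one-stage) fit over stacked city-days."""

    level: str
    beta_per10: float
    se_per10: float
    ci95: tuple[float, float]
    mode: str  # "spatial" | "city_intercepts"
    k: int
    n_days_used: int


# ---------------------------------------------------------------------------
# DerSimonian-Laird pooling
# ---------------------------------------------------------------------------

def pool_random_effects(
    effects: Sequence[CityEffect], level: str = "National"
) -> PooledEffect:
    """DerSimonian–Laird random-effects pooling of city coefficients."""
    k = len(effects)
    if k == 0:
        raise ValueError("cannot pool an empty set of effects")
    b = np.array([e.beta_per10 for e in effects], dtype=float)
    se = np.array([e.se_per10 for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    b_fixed = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - b_fixed) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return PooledEffect(
        level=level,
        beta_per10=beta,
        se_per10=se_pooled,
        ci95=(beta - Z95 * se_pooled, beta + Z95 * se_pooled),
        tau2=float(tau2),
        Q=Q,
        I2=float(I2),
        k=k,
    )


# ---------------------------------------------------------------------------
# Meta-regression
# ---------------------------------------------------------------------------

def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """WLS with known weights: coefficients and covariance (X'WX)^-1."""
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    cov = np.linalg.inv(xtwx)
    coef = cov @ (Xw.T @ y)
    return coef, cov


def meta_regression(
    effects: Sequence[CityEffect],
    covariate: Mapping[str, float],
    name: str,
    interaction_with: Mapping[str, float] | None = None,
    interaction_name: str | None = None,
) -> MetaRegResult:
    """Regress city coefficients on an IQR-scaled city-level covariate.

    With ``interaction_with`` given, both scaled main effects and their
    product are included and the product term's p-value is reported as
    ``interaction_p`` (the slope still refers to the first covariate).
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"meta-regression needs k >= 3 cities, got {k}")
    b = np.array([e.beta_per10 for e in effects], dtype=float)
    se = np.array([e.se_per10 for e in effects], dtype=float)
    x = np.array([float(covariate[e.city_id]) for e in effects])
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    if iqr <= 0:
        raise ValueError(f"covariate {name!r} is (near-)constant: IQR = {iqr}")
    tau2 = pool_random_effects(effects).tau2
    w = 1.0 / (se**2 + tau2)
    xs = x / iqr
    if interaction_with is None:
        X = np.column_stack([np.ones(k), xs])
        coef, cov = _wls(b, X, w)
        slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
        inter_p = None
    else:
        x2 = np.array([float(interaction_with[e.city_id]) for e in effects])
        iqr2 = float(np.percentile(x2, 75) - np.percentile(x2, 25))
        if iqr2 <= 0:
            raise ValueError(f"covariate {interaction_name!r} is (near-)constant")
        xs2 = x2 / iqr2
        X = np.column_stack([np.ones(k), xs, xs2, xs * xs2])
        coef, cov = _wls(b, X, w)
        slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
        z_int = coef[3] / np.sqrt(cov[3, 3])
        inter_p = float(2 * sps.norm.sf(abs(z_int)))
    z = slope / slope_se
    return MetaRegResult(
        covariate=name,
        iqr=iqr,
        slope_per_iqr=slope,
        se=slope_se,
        p_value=float(2 * sps.norm.sf(abs(z))),
        interaction_p=inter_p,
    )


# ---------------------------------------------------------------------------
# Pooled (one-stage) sensitivity fits
# ---------------------------------------------------------------------------

def fit_pooled_gam(
    series_list: Sequence[CityDailySeries],
    metas: Mapping[str, CityMeta],
    spec: GamSpec = GamSpec(),
    holidays: Iterable[Date] = (),
    mode: str = "city_intercepts",
    level: str = "National",
) -> OneStageEffect:
    """One Gaussian fit over all stacked city-days of a region or the nation.

    ``city_intercepts`` adds a fixed intercept per city (a fixed-effect
    approximation of a random city term); ``spatial`` instead adds natural
    cubic splines (3 df each) in city longitude and latitude.
    """
    import statsmodels.api as sm

    from .gam import lagged_exposure, time_trend_df

    if mode not in ("spatial", "city_intercepts"):
        raise ValueError(f"mode must be 'spatial' or 'city_intercepts', got {mode!r}")
    if len(series_list) < 2:
        raise ValueError("pooled fit needs at least 2 cities")

    # Stack raw per-city columns first; smooth bases are then built once on
    # the pooled values so every city shares the same spline basis.
    frames = []
    holiday_set = set(holidays)
    for s in series_list:
        pm10 = lagged_exposure(s.pm25, spec.lag) / 10.0
        temp_ma = lagged_exposure(s.temp, LagSpec("moving_average", 3))
        frame = pd.DataFrame(
            {
                "yll": s.yll,
                "pm25_per10": pm10,
                "temp_ma": temp_ma,
                "rh": s.rh,
                "tt": np.arange(len(s), dtype=float),
                "dow": pd.Series(s.dates).dt.dayofweek.to_numpy(),
                "holiday": [d.astype(object) in holiday_set for d in s.dates],
                "city_id": s.city_id,
            }
        )
        if spec.copollutant is not None:
            frame[f"{spec.copollutant}_per10"] = (
                lagged_exposure(getattr(s, spec.copollutant), spec.lag) / 10.0
            )
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    data = data.dropna().reset_index(drop=True)

    n_days = max(len(s) for s in series_list)
    tdf = time_trend_df(n_days, spec.time_df_per_year, spec.min_time_df)
    parts = [pd.DataFrame({"const": np.ones(len(data)), "pm25_per10": data["pm25_per10"]})]
    if spec.copollutant is not None:
        parts.append(data[[f"{spec.copollutant}_per10"]])
    parts.append(_natural_spline(data["tt"].to_numpy(), tdf, "time"))
    parts.append(_natural_spline(data["temp_ma"].to_numpy(), spec.temp_df, "temp"))
    parts.append(_natural_spline(data["rh"].to_numpy(), spec.rh_df, "rh"))
    dow_dummies = pd.get_dummies(
        pd.Categorical(data["dow"], categories=range(7)), prefix="dow", dtype=float
    )
    parts.append(dow_dummies.drop(columns="dow_0").reset_index(drop=True))
    holi = data["holiday"].astype(float).to_numpy()
    if np.ptp(holi) > 0:
        parts.append(pd.DataFrame({"holiday": holi}))

    if mode == "city_intercepts":
        dummies = pd.get_dummies(data["city_id"], prefix="city", dtype=float)
        parts.append(dummies.iloc[:, 1:].reset_index(drop=True))  # first city = reference
    else:
        lon = data["city_id"].map({cid: m.longitude for cid, m in metas.items()}).to_numpy(float)
        lat = data["city_id"].map({cid: m.latitude for cid, m in metas.items()}).to_numpy(float)
        if np.ptp(lon) == 0 or np.ptp(lat) == 0:
            raise ValueError("spatial mode needs cities at distinct coordinates")
        parts.append(_natural_spline(lon, 3, "lon"))
        parts.append(_natural_spline(lat, 3, "lat"))
    X = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    y = data["yll"]
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    beta = float(res.params["pm25_per10"])
    se = float(res.bse["pm25_per10"])
    return OneStageEffect(
        level=level,
        beta_per10=beta,
        se_per10=se,
        ci95=(beta - Z95 * se, beta + Z95 * se),
        mode=mode,
        k=len(series_list),
        n_days_used=len(y),
    )
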