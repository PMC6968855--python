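"""First-stage city-specific regression of daily YLL on lagged PM2.5.

The outcome is continuous daily YLL, modelled with a Gaussian likelihood.
Smooth confounder adjustment uses fixed-df natural cubic regression splines
(knots at equally spaced quantiles): a long-term/seasonal time trend at
6 df per year, a spline of the lag03 moving-average temperature (6 df) and
of same-day relative humidity (3 df), plus day-of-week indicators (Monday
reference), a public-holiday indicator and an intercept. The PM2.5 term is
entered linearly on the per-10-ug/m3 scale, so its coefficient is directly
the effect per 10 ug/m3. Two-pollutant models add one co-pollutant linearly
at the same lag structure.

Fixed-df regression splines make the fit an ordinary least-squares problem:
deterministic, fast, and with the effective dimension the analysis intends,
at the price of not estimating smoothness from the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tsa.stattools import pacf as sm_pacf

from .datamodel import CityDailySeries

__all__ = [
    "LagSpec",
    "GamSpec",
    "CityEffect",
    "DiagnosticBundle",
    "GamFit",
    "lagged_exposure",
    "fit_city_gam",
    "spearman_correlations",
    "gam_diagnostics",
]

Z95 = 1.96  # normal-approximation multiplier for 95% CIs


@dataclass(frozen=True)
class LagSpec:
    """Lag structure for the exposure term.

    ``single`` with span k uses the concentration k days before; span 0 is
    the current day. ``moving_average`` with span k averages the current day
    and the previous k days (span 2 is the lag02 three-day average).
    """

    kind: str = "moving_average"
    span: int = 2

    def __post_init__(self) -> None:
        if self.kind == "single":
            allowed = (0, 1, 2, 3)
        elif self.kind == "moving_average":
            allowed = (1, 2, 3)
        else:
            raise ValueError(f"kind must be 'single' or 'moving_average', got {self.kind!r}")
        if self.span not in allowed:
            raise ValueError(f"span {self.span} not in {allowed} for kind {self.kind!r}")

    @property
    def tag(self) -> str:
        if self.kind == "single":
            return f"lag{self.span}"
        return f"lag0{self.span}"

    @classmethod
    def from_tag(cls, tag: str) -> "LagSpec":
        t = tag.lower().removeprefix("lag")
        if len(t) == 2 and t[0] == "0" and t != "00":
            return cls("moving_average", int(t[1]))
        return cls("single", int(t))


@dataclass(frozen=True)
class GamSpec:
    """Model specification for the first-stage fit."""

    lag: LagSpec = LagSpec("moving_average", 2)
    time_df_per_year: int = 6
    temp_df: int = 6
    rh_df: int = 3
    copollutant: str | None = None  # one of so2, no2, o3
    min_time_df: int = 4  # floor on the total time-trend df

    def __post_init__(self) -> None:
        for name in ("time_df_per_year", "temp_df", "rh_df"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.copollutant not in (None, "so2", "no2", "o3"):
            raise ValueError(f"copollutant must be None/so2/no2/o3, got {self.copollutant!r}")


@dataclass(frozen=True)
class CityEffect:
    """One city's estimated PM2.5 effect on daily YLL, per 10 ug/m3."""

    city_id: str
    beta_per10: float
    se_per10: float
    ci95: tuple[float, float]
    lag: str
    n_days_used: int
    copollutant: str | None = None

    def __post_init__(self) -> None:
        if not self.se_per10 > 0:
            raise ValueError(f"se_per10 must be > 0, got {self.se_per10}")
        lo, hi = self.ci95
        if abs(lo - (self.beta_per10 - Z95 * self.se_per10)) > 1e-9 or abs(
            hi - (self.beta_per10 + Z95 * self.se_per10)
        ) > 1e-9:
            raise ValueError("ci95 must equal beta_per10 +/- 1.96 * se_per10")


@dataclass
class DiagnosticBundle:
    """Residual diagnostics of a fitted city model."""

    residuals: np.ndarray
    pacf: np.ndarray  # lags 1..30
    qq: tuple[np.ndarray, np.ndarray]  # (theoretical, empirical) quantiles


@dataclass
class GamFit:
    """Internals of a fitted first-stage model."""

    results: sm.regression.linear_model.RegressionResults
    exog_names: list[str]
    n_days_used: int
    time_df: int
    spec: GamSpec


# ---------------------------------------------------------------------------
# Lag structures
# ---------------------------------------------------------------------------

def lagged_exposure(series: np.ndarray, lag: LagSpec) -> np.ndarray:
    """Apply a lag structure; days with an incomplete window become NaN."""
    x = np.asarray(series, dtype=float)
    if len(x) <= lag.span:
        raise ValueError(f"series of length {len(x)} too short for {lag.tag}")
    out = np.full_like(x, np.nan)
    if lag.kind == "single":
        if lag.span == 0:
            return x.copy()
        out[lag.span :] = x[: -lag.span]
        return out
    w = lag.span + 1  # window: current + previous span days
    kernel = np.ones(w) / w
    out[lag.span :] = np.convolve(x, kernel, mode="valid")
    return out


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _natural_spline(x: np.ndarray, df: int, name: str) -> pd.DataFrame:
    """Natural cubic regression spline basis, df columns, knots at quantiles.

    The raw cubic-regression-spline basis spans the constant, so it is
    centered and reduced by pivoted QR to df columns orthogonal to the
    intercept (the convention of R's ns()): a model with an intercept plus
    this basis has exactly df + 1 free parameters for the smooth. df = 1
    degenerates to the raw (linear) term so the whole design reduces to
    ordinary multiple linear regression.
    """
    x = np.asarray(x, dtype=float)
    if df == 1:
        return pd.DataFrame({f"{name}_lin": x})
    from scipy.linalg import qr

    basis = np.asarray(patsy.dmatrix("cr(x, df=df) - 1", {"x": x, "df": df + 1}))
    centered = basis - basis.mean(axis=0)
    q, r, _ = qr(centered, mode="economic", pivoting=True)
    # scale orthonormal columns back to the data's magnitude for conditioning
    q = q[:, :df] * np.sqrt(len(x))
    return pd.DataFrame({f"{name}_s{i + 1}": q[:, i] for i in range(df)})


def time_trend_df(n_days: int, df_per_year: int = 6, min_df: int = 4) -> int:
    """Total df of the long-term/seasonal time spline: round(df/yr * years), min 4."""
    return max(min_df, round(df_per_year * n_days / 365.25))


def build_design(
    series: CityDailySeries,
    spec: GamSpec,
    holidays: Iterable[Date] = (),
) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Assemble (y, X, kept-row mask) for one city; drops incomplete rows."""
    n = len(series)
    pm10 = lagged_exposure(series.pm25, spec.lag) / 10.0
    temp_ma = lagged_exposure(series.temp, LagSpec("moving_average", 3))
    holi = np.array([d.astype(object) in set(holidays) for d in series.dates], dtype=float)
    dow = pd.Series(series.dates).dt.dayofweek.to_numpy()  # 0 = Monday

    cols: dict[str, np.ndarray] = {"pm25_per10": pm10}
    if spec.copollutant is not None:
        co = lagged_exposure(getattr(series, spec.copollutant), spec.lag) / 10.0
        cols[f"{spec.copollutant}_per10"] = co

    raw = pd.DataFrame(cols)
    raw["yll"] = series.yll
    raw["temp_ma"] = temp_ma
    raw["rh"] = series.rh
    keep = ~raw.isna().any(axis=1).to_numpy()
    idx = np.flatnonzero(keep)

    tdf = time_trend_df(n, spec.time_df_per_year, spec.min_time_df)
    parts = [pd.DataFrame({k: v[idx] for k, v in cols.items()})]
    parts.append(_natural_spline(idx.astype(float), tdf, "time"))
    parts.append(_natural_spline(temp_ma[idx], spec.temp_df, "temp"))
    parts.append(_natural_spline(series.rh[idx], spec.rh_df, "rh"))
    dow_dummies = pd.get_dummies(pd.Categorical(dow[idx], categories=range(7)), prefix="dow", dtype=float)
    parts.append(dow_dummies.drop(columns="dow_0").reset_index(drop=True))  # Monday reference
    if np.ptp(holi[idx]) > 0:  # omit the indicator when no holiday falls in-window
        parts.append(pd.DataFrame({"holiday": holi[idx]}))
    X = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    X.insert(0, "const", 1.0)
    y = pd.Series(series.yll[idx], name="yll")
    return y, X, keep


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # locate offending columns via pivoted QR: small trailing pivots
        from scipy.linalg import qr

        _, r, piv = qr(arr, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(d)) if d[i] < d[0] * 1e-10]
        raise ValueError(f"rank-deficient design; collinear terms: {bad or 'unknown'}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_city_gam(
    series: CityDailySeries,
    spec: GamSpec = GamSpec(),
    holidays: Iterable[Date] = (),
    min_days: int = 365,
) -> tuple[CityEffect, DiagnosticBundle, GamFit]:
    """Fit the first-stage Gaussian model for one city.

    Returns the PM2.5 effect per 10 ug/m3 with its 95% CI, residual
    diagnostics, and the fit internals. Rows with any missing covariate
    (including lag-incomplete leading days) are dropped; fewer than
    ``min_days`` usable days is an error.
    """
    y, X, keep = build_design(series, spec, holidays)
    n_used = len(y)
    if n_used < min_days:
        raise ValueError(
            f"city {series.city_id}: only {n_used} usable days after lag/missing removal "
            f"(need >= {min_days})"
        )
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    beta = float(res.params["pm25_per10"])
    se = float(res.bse["pm25_per10"])
    effect = CityEffect(
        city_id=series.city_id,
        beta_per10=beta,
        se_per10=se,
        ci95=(beta - Z95 * se, beta + Z95 * se),
        lag=spec.lag.tag,
        n_days_used=n_used,
        copollutant=spec.copollutant,
    )
    fit = GamFit(
        results=res,
        exog_names=list(X.columns),
        n_days_used=n_used,
        time_df=time_trend_df(len(series), spec.time_df_per_year, spec.min_time_df),
        spec=spec,
    )
    return effect, gam_diagnostics(fit), fit


def gam_diagnostics(fit: GamFit, nlags: int = 30) -> DiagnosticBundle:
    """Residuals, PACF at lags 1..30, and Gaussian Q-Q pairs for a fit."""
    resid = np.asarray(fit.results.resid, dtype=float)
    n = len(resid)
    nl = min(nlags, n // 2 - 1)
    if resid.std() < 1e-12:
        pac = np.zeros(nl)  # degenerate perfect fit: no autocorrelation signal
    else:
        pac = sm_pacf(resid, nlags=nl, method="ywm")[1:]
    pac = np.clip(pac, -1.0, 1.0)
    order = np.sort(resid)
    probs = (np.arange(1, n + 1) - 0.5) / n
    sd = resid.std(ddof=1) if n > 1 else 1.0
    theo = sps.norm.ppf(probs, loc=resid.mean(), scale=sd if sd > 0 else 1.0)
    return DiagnosticBundle(residuals=resid, pacf=pac, qq=(theo, order))


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def spearman_correlations(
    series_list: Sequence[CityDailySeries],
    variables: Sequence[str] = ("pm25", "so2", "no2", "o3", "temp", "rh"),
) -> pd.DataFrame:
    """Spearman rank correlations pooled over all city-days.

    Pairwise-complete observations; a constant variable yields NaN against
    the others. The matrix is symmetric with unit diagonal.
    """
    data = {v: np.concatenate([getattr(s, v) for s in series_list]) for v in variables}
    k = len(variables)
    out = np.full((k, k), np.nan)
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            a, b = data[variables[i]], data[variables[j]]
            m = np.isfinite(a) & np.isfinite(b)
            if m.sum() < 3:
                continue
            if np.ptp(a[m]) == 0 or np.ptp(b[m]) == 0:
                continue  # undefined for a constant variable
            rho = sps.spearmanr(a[m], b[m]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=list(variables), columns=list(variables))
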