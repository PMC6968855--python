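"""Counterfactual avoidable YLL, PGLE and attributable fraction (AF).

Given a pooled linear effect beta (years of daily YLL per 10 ug/m3 of lag02
PM2.5), the avoidable YLL under an air-quality standard with threshold C is
the exceedance sum over all city-days:

    avoidable = (beta / 10) * sum_{cities, days} max(0, xbar_t - C)

where xbar_t is the lagged (default lag02 moving-average) exposure. Days
with an incomplete lag window are excluded from both the exceedance sum and
the totals. Confidence bounds substitute the beta CI endpoints (linear
plug-in propagation). Derived indicators:

    PGLE = avoidable YLL / total deaths   (years gained per death)
    AF   = avoidable YLL / total YLL      (fraction of the burden)

Reference thresholds: the WHO air-quality guideline AQG (25 ug/m3) and its
interim targets IT-3 (37.5), IT-2 (50) and IT-1 (75, identical to the
Chinese national standard NAAQS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datamodel import CityDailySeries
from .gam import LagSpec
from .meta import PooledEffect

__all__ = [
    "Standard",
    "ImpactResult",
    "STANDARDS",
    "avoidable_yll",
    "compute_pgle",
    "compute_af",
    "impact_table",
]


@dataclass(frozen=True)
class Standard:
    """A daily PM2.5 air-quality standard."""

    name: str
    threshold: float  # ug/m3

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


#: WHO AQG and interim targets (IT-1 coincides with China's NAAQS).
STANDARDS: tuple[Standard, ...] = (
    Standard("AQG", 25.0),
    Standard("IT-3", 37.5),
    Standard("IT-2", 50.0),
    Standard("IT-1/NAAQS", 75.0),
)


@dataclass(frozen=True)
class ImpactResult:
    """Avoidable burden at one (aggregation level, standard) combination."""

    level: str
    standard: Standard
    avoidable_yll: float
    avoidable_ci95: tuple[float, float]
    pgle: float
    pgle_ci95: tuple[float, float]
    af: float  # fraction in [0, 1]
    af_ci95: tuple[float, float]
    total_deaths: float
    total_yll: float

    def __post_init__(self) -> None:
        if self.avoidable_yll < 0 or self.pgle < 0 or not (0 <= self.af <= 1):
            raise ValueError("impact indicators out of range")
        for lo, point, hi in (
            (*self.avoidable_ci95[:1], self.avoidable_yll, self.avoidable_ci95[1]),
            (self.pgle_ci95[0], self.pgle, self.pgle_ci95[1]),
            (self.af_ci95[0], self.af, self.af_ci95[1]),
        ):
            if not (lo <= point <= hi):
                raise ValueError("CI bounds must bracket the point estimate")


def _exceedance_sum(
    series_list: Sequence[CityDailySeries], C: float, lag: LagSpec
) -> float:
    """Sum over all city-days of max(0, lagged exposure - C), lag-complete days only."""
    from .gam import lagged_exposure

    total = 0.0
    for s in series_list:
        xbar = lagged_exposure(s.pm25, lag)
        valid = np.isfinite(xbar)
        total += float(np.maximum(0.0, xbar[valid] - C).sum())
    return total


def avoidable_yll(
    series_list: Sequence[CityDailySeries],
    beta_per10: float,
    ci95: tuple[float, float],
    standard: Standard | float,
    lag: LagSpec = LagSpec("moving_average", 2),
) -> tuple[float, tuple[float, float]]:
    """Avoidable YLL (years) and its 95% CI under one standard.

    A negative coefficient (or CI bound) is floored at zero with a warning:
    counterfactual harm from cleaner air is not modelled.
    """
    if not series_list:
        raise ValueError("series_list must be non-empty")
    if not np.isfinite(beta_per10):
        raise ValueError("beta_per10 must be finite")
    C = standard.threshold if isinstance(standard, Standard) else float(standard)
    exceed = _exceedance_sum(series_list, C, lag)
    if beta_per10 < 0 or ci95[0] < 0:
        warnings.warn(
            "negative effect (bound) floored at 0: counterfactual harm not modelled",
            stacklevel=2,
        )
    point = max(0.0, beta_per10) / 10.0 * exceed
    lo = max(0.0, ci95[0]) / 10.0 * exceed
    hi = max(0.0, ci95[1]) / 10.0 * exceed
    return point, (lo, hi)


def compute_pgle(avoidable: float, total_deaths: float) -> float:
    """Potential gain in life expectancy: avoidable YLL per death (years)."""
    if total_deaths <= 0:
        raise ValueError("total_deaths must be > 0")
    return avoidable / total_deaths


def compute_af(avoidable: float, total_yll: float) -> float:
    """Attributable fraction: avoidable YLL as a fraction of the total YLL."""
    if total_yll <= 0:
        raise ValueError("total_yll must be > 0")
    if avoidable > total_yll:
        raise ValueError(f"avoidable YLL {avoidable} exceeds total YLL {total_yll}")
    return avoidable / total_yll


def _totals(
    series_list: Sequence[CityDailySeries], lag: LagSpec
) -> tuple[float, float]:
    """Total deaths and YLL over lag-complete days (consistent with the numerator)."""
    deaths = 0.0
    yll = 0.0
    skip = lag.span  # leading days without a complete lag window
    for s in series_list:
        d = s.deaths[skip:]
        y = s.yll[skip:]
        deaths += float(np.nansum(d))
        yll += float(np.nansum(y))
    return deaths, yll


def impact_table(
    series_by_level: Mapping[str, Sequence[CityDailySeries]],
    pooled_by_level: Mapping[str, PooledEffect],
    standards: Sequence[Standard] = STANDARDS,
    lag: LagSpec = LagSpec("moving_average", 2),
) -> list[ImpactResult]:
    """One ImpactResult per (level, standard).

    Regional rows use the regional pooled coefficient over that region's
    cities; the National row uses the nationally pooled coefficient over all
    cities — so the national burden is not the sum of the regional rows
    whenever the pooled coefficients differ.
    """
    results = []
    for level, series_list in series_by_level.items():
        if level not in pooled_by_level:
            raise ValueError(f"no pooled effect available for level {level!r}")
        eff = pooled_by_level[level]
        total_deaths, total_yll = _totals(series_list, lag)
        for std in standards:
            av, (lo, hi) = avoidable_yll(series_list, eff.beta_per10, eff.ci95, std, lag)
            results.append(
                ImpactResult(
                    level=level,
                    standard=std,
                    avoidable_yll=av,
                    avoidable_ci95=(lo, hi),
                    pgle=compute_pgle(av, total_deaths),
                    pgle_ci95=(compute_pgle(lo, total_deaths), compute_pgle(hi, total_deaths)),
                    af=compute_af(av, total_yll),
                    af_ci95=(compute_af(lo, total_yll), compute_af(min(hi, total_yll), total_yll)),
                    total_deaths=total_deaths,
                    total_yll=total_yll,
                )
            )
    return results
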