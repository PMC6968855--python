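"""End-to-end two-stage run: data -> YLL -> city GAMs -> pooling -> impact.

A run is driven by a single YAML config and writes a directory of CSV report
tables (descriptives, correlations, city effects, pooled effects,
meta-regression, impact, PGLE by standard, diagnostics summary) plus a JSON
manifest carrying the seed and a hash of the resolved configuration, so a
run can be reproduced and verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    REGIONS,
    CityDailySeries,
    StudyDataset,
    assemble_city_series,
    read_city_meta,
    read_death_records,
    read_holidays,
    read_life_table,
    read_study,
    write_study,
)
from .gam import GamSpec, LagSpec, fit_city_gam, spearman_correlations
from .impact import STANDARDS, Standard, impact_table
from .meta import CityEffect, PooledEffect, meta_regression, pool_random_effects
from .simulate import DEFAULT_N_DAYS, SyntheticTruth, generate_study
from .yll import daily_yll

__all__ = ["RunConfig", "run_two_stage", "summarize_descriptives", "load_raw_study"]

log = logging.getLogger("pm25yll")

#: City-level covariates offered to the univariable meta-regressions.
META_COVARIATES = (
    "gdp",
    "population_density",
    "gdp_per_capita",
    "elevation",
    "precipitation",
    "poverty",
    "education",
    "annual_pm25",
    "annual_co",
    "annual_o3",
    "annual_so2",
    "annual_no2",
    "air_pressure",
    "annual_temp",
    "annual_rh",
)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "out"
    seed: int = 0
    inputs: str | None = None  # directory of an assembled study
    simulate: dict[str, Any] | None = None  # generator settings
    lag: str = "lag02"
    copollutant: str | None = None
    time_df_per_year: int = 6
    temp_df: int = 6
    rh_df: int = 3
    standards: Sequence[float] = (25.0, 37.5, 50.0, 75.0)
    log_level: str = "INFO"
    write_city_diagnostics: bool = False

    def __post_init__(self) -> None:
        if self.inputs is None and self.simulate is None:
            self.simulate = {}  # default synthetic study
        if self.inputs is not None and self.simulate is not None:
            raise ValueError("config must give either 'inputs' or 'simulate', not both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def gam_spec(self) -> GamSpec:
        return GamSpec(
            lag=LagSpec.from_tag(self.lag),
            time_df_per_year=self.time_df_per_year,
            temp_df=self.temp_df,
            rh_df=self.rh_df,
            copollutant=self.copollutant,
        )

    def resolved(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["standards"] = [float(s) for s in self.standards]
        return d


def build_truth(settings: Mapping[str, Any], seed: int) -> SyntheticTruth:
    fields = {f.name for f in dataclasses.fields(SyntheticTruth)}
    kwargs = {k: v for k, v in (settings.get("truth") or {}).items() if k in fields}
    kwargs.setdefault("seed", seed)
    return SyntheticTruth(**kwargs)


def load_raw_study(indir: str | Path) -> StudyDataset:
    """Assemble a StudyDataset from raw input CSVs.

    Expects deaths.csv (date,city_id,age,sex), exposure.csv, weather.csv,
    lifetable.csv and citymeta.csv (holidays.csv optional). Per-city daily
    YLL is recomputed from the individual death records and the life table;
    the study window is the span of the exposure dates.
    """
    indir = Path(indir)
    lt = read_life_table(indir / "lifetable.csv")
    metas = read_city_meta(indir / "citymeta.csv")
    records = read_death_records(indir / "deaths.csv")
    expo = pd.read_csv(indir / "exposure.csv", dtype={"city_id": str})
    wx = pd.read_csv(indir / "weather.csv", dtype={"city_id": str})
    dates = pd.to_datetime(expo["date"])
    window = (dates.min().date(), dates.max().date())
    by_city: dict[str, list] = {m.city_id: [] for m in metas}
    for r in records:
        if r.city_id not in by_city:
            raise ValueError(f"death record for unknown city {r.city_id!r}")
        by_city[r.city_id].append(r)
    series = []
    for m in metas:
        deaths_by_day = daily_yll(by_city[m.city_id], lt, window)
        series.append(
            assemble_city_series(
                m.city_id,
                deaths_by_day,
                expo[expo["city_id"] == m.city_id],
                wx[wx["city_id"] == m.city_id],
                window,
            )
        )
    holidays_path = indir / "holidays.csv"
    holidays = read_holidays(holidays_path) if holidays_path.exists() else set()
    return StudyDataset(series=series, meta=metas, life_table=lt, holidays=holidays)


def _load_dataset(config: RunConfig) -> tuple[StudyDataset, SyntheticTruth | None]:
    if config.inputs is not None:
        indir = Path(config.inputs)
        if (indir / "series.csv").exists():
            return read_study(indir), None
        return load_raw_study(indir), None
    settings = config.simulate or {}
    truth = build_truth(settings, config.seed)
    n_regions = settings.get("n_cities_per_region")
    dataset, truth = generate_study(
        n_cities_per_region=n_regions,
        truth=truth,
        n_days=int(settings.get("n_days", DEFAULT_N_DAYS)),
        seed=config.seed,
    )
    return dataset, truth


def summarize_descriptives(dataset: StudyDataset) -> pd.DataFrame:
    """Per-region and national summary: city counts and city-day means."""
    if not dataset.series:
        raise ValueError("dataset has no series")
    rows = []
    groups = [(r, dataset.region_series(r)) for r in dataset.regions]
    groups.append(("National", dataset.series))
    for level, series_list in groups:
        if not series_list:
            continue
        row: dict[str, Any] = {"level": level, "n_cities": len(series_list)}
        for var in ("pm25", "so2", "no2", "o3", "temp", "rh"):
            row[var] = float(np.nanmean(np.concatenate([getattr(s, var) for s in series_list])))
        row["daily_mortality"] = float(np.nanmean(np.concatenate([s.deaths for s in series_list])))
        row["daily_yll"] = float(np.nanmean(np.concatenate([s.yll for s in series_list])))
        rows.append(row)
    return pd.DataFrame(rows)


def _city_effects_frame(effects: Sequence[CityEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "city_id": e.city_id,
                "lag": e.lag,
                "copollutant": e.copollutant or "",
                "beta_per10": e.beta_per10,
                "se": e.se_per10,
                "lo": e.ci95[0],
                "hi": e.ci95[1],
                "n_days_used": e.n_days_used,
            }
            for e in effects
        ]
    )


def _pooled_frame(pooled: Sequence[PooledEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": p.level,
                "beta_per10": p.beta_per10,
                "se": p.se_per10,
                "lo": p.ci95[0],
                "hi": p.ci95[1],
                "tau2": p.tau2,
                "Q": p.Q,
                "I2": p.I2,
                "k": p.k,
            }
            for p in pooled
        ]
    )


@dataclass
class Report:
    """Outputs of one pipeline run."""

    outdir: Path
    files: dict[str, Path]
    pooled: dict[str, PooledEffect]
    manifest: dict[str, Any]


def run_two_stage(config: RunConfig) -> Report:
    """Execute the full two-stage analysis and write all report tables."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        files[name] = path

    stage = "load-data"
    try:
        dataset, truth = _load_dataset(config)
        spec = config.gam_spec()
        standards = [
            next((s for s in STANDARDS if s.threshold == float(c)), Standard(f"C{c}", float(c)))
            for c in config.standards
        ]

        stage = "descriptives"
        _write("descriptives.csv", summarize_descriptives(dataset))
        _write("correlations.csv", spearman_correlations(dataset.series).reset_index(names="variable"))

        stage = "first-stage"
        effects: list[CityEffect] = []
        diag_rows = []
        diag_dir = outdir / "diagnostics"
        for s in dataset.series:
            log.info("fitting city %s", s.city_id)
            try:
                eff, diag, fit = fit_city_gam(s, spec, dataset.holidays)
            except Exception as exc:
                raise RuntimeError(f"stage first-stage failed for city {s.city_id}: {exc}") from exc
            effects.append(eff)
            n = len(diag.residuals)
            diag_rows.append(
                {
                    "city_id": s.city_id,
                    "n": n,
                    "resid_mean": float(diag.residuals.mean()),
                    "resid_sd": float(diag.residuals.std(ddof=1)),
                    "max_abs_pacf": float(np.max(np.abs(diag.pacf))),
                    "frac_pacf_in_band": float(np.mean(np.abs(diag.pacf) < 2 / np.sqrt(n))),
                }
            )
            if config.write_city_diagnostics:
                diag_dir.mkdir(exist_ok=True)
                pd.DataFrame({"residual": diag.residuals}).to_csv(
                    diag_dir / f"{s.city_id}_residuals.csv", index=False
                )
                pd.DataFrame(
                    {"lag": np.arange(1, len(diag.pacf) + 1), "pacf": diag.pacf}
                ).to_csv(diag_dir / f"{s.city_id}_pacf.csv", index=False)
        _write("city_effects.csv", _city_effects_frame(effects))
        _write("diagnostics.csv", pd.DataFrame(diag_rows))

        stage = "second-stage"
        by_id = dataset.meta_by_id
        pooled: dict[str, PooledEffect] = {}
        for region in dataset.regions:
            sub = [e for e in effects if by_id[e.city_id].region == region]
            if sub:
                pooled[region] = pool_random_effects(sub, level=region)
        pooled["National"] = pool_random_effects(effects, level="National")
        _write("pooled_effects.csv", _pooled_frame(list(pooled.values())))

        stage = "meta-regression"
        mr_rows = []
        if len(effects) >= 3:
            for cov in META_COVARIATES:
                values = {m.city_id: m.covariates.get(cov) for m in dataset.meta}
                if any(v is None for v in values.values()):
                    continue
                try:
                    r = meta_regression(effects, values, cov)
                except ValueError as exc:
                    log.warning("meta-regression for %s skipped: %s", cov, exc)
                    continue
                mr_rows.append(
                    {
                        "covariate": cov,
                        "iqr": r.iqr,
                        "slope_per_iqr": r.slope_per_iqr,
                        "se": r.se,
                        "p": r.p_value,
                        "interaction_p": "",
                    }
                )
            pm = {m.city_id: m.covariates.get("annual_pm25") for m in dataset.meta}
            gdp = {m.city_id: m.covariates.get("gdp") for m in dataset.meta}
            if all(v is not None for v in pm.values()) and all(v is not None for v in gdp.values()):
                r = meta_regression(
                    effects, pm, "annual_pm25", interaction_with=gdp, interaction_name="gdp"
                )
                mr_rows.append(
                    {
                        "covariate": "annual_pm25:gdp",
                        "iqr": r.iqr,
                        "slope_per_iqr": r.slope_per_iqr,
                        "se": r.se,
                        "p": r.p_value,
                        "interaction_p": r.interaction_p,
                    }
                )
        _write("metareg.csv", pd.DataFrame(mr_rows))

        stage = "impact"
        series_by_level: dict[str, list[CityDailySeries]] = {
            r: dataset.region_series(r) for r in dataset.regions
        }
        series_by_level["National"] = list(dataset.series)
        results = impact_table(series_by_level, pooled, standards, spec.lag)
        imp = pd.DataFrame(
            [
                {
                    "level": r.level,
                    "standard_name": r.standard.name,
                    "C": r.standard.threshold,
                    "avoidable_yll": r.avoidable_yll,
                    "lo": r.avoidable_ci95[0],
                    "hi": r.avoidable_ci95[1],
                    "pgle": r.pgle,
                    "pgle_lo": r.pgle_ci95[0],
                    "pgle_hi": r.pgle_ci95[1],
                    "af": r.af,
                    "af_lo": r.af_ci95[0],
                    "af_hi": r.af_ci95[1],
                    "total_deaths": r.total_deaths,
                    "total_yll": r.total_yll,
                }
                for r in results
            ]
        )
        _write("impact.csv", imp)
        _write(
            "pgle_by_standard.csv",
            imp[["level", "standard_name", "C", "pgle", "pgle_lo", "pgle_hi"]],
        )
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    resolved = config.resolved()
    cfg_yaml = yaml.safe_dump(resolved, sort_keys=True)
    (outdir / "config.resolved.yaml").write_text(cfg_yaml)
    manifest = {
        "package": "pm25yll",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "outputs": sorted(files),
    }
    if truth is not None:
        manifest["truth"] = dataclasses.asdict(truth)
        manifest["truth"]["regional_means"] = {
            k: dict(v) for k, v in truth.regional_means.items()
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    files["manifest.json"] = outdir / "manifest.json"
    return Report(outdir=outdir, files=files, pooled=pooled, manifest=manifest)
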