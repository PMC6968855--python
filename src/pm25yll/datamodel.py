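"""Domain types and tabular I/O for multi-city daily mortality/exposure data.

The package works on per-city daily time series: a count of nonaccidental
deaths, the years of life lost (YLL) those deaths represent, ambient
pollutant concentrations (PM2.5, SO2, NO2, O3) and weather (mean temperature,
relative humidity), together with a sex-specific abridged life table and
city-level metadata (region, coordinates, annual covariates).

All files are plain UTF-8 CSV with a header row; dates are ISO-8601 strings.
Missing exposure/weather values are carried explicitly as NaN and never
silently imputed — regression stages drop incomplete rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "DeathRecord",
    "LifeTable",
    "CityDailySeries",
    "CityMeta",
    "StudyDataset",
    "read_death_records",
    "read_life_table",
    "read_city_meta",
    "read_holidays",
    "assemble_city_series",
    "daily_grid",
    "write_study",
    "read_study",
]

#: The seven administrative regions used to group cities.
REGIONS = ("Northwest", "North", "Northeast", "Central", "East", "Southwest", "South")

_FEMALE_CODES = {"female", "f", "2"}
_MALE_CODES = {"male", "m", "1"}

#: Exposure and weather variables carried on a daily city series.
POLLUTANTS = ("pm25", "so2", "no2", "o3")
WEATHER = ("temp", "rh")


def normalize_sex(code: object) -> str:
    """Map tolerant sex codes ({female,f,2} / {male,m,1}) to canonical labels."""
    s = str(code).strip().lower()
    if s in _FEMALE_CODES:
        return "female"
    if s in _MALE_CODES:
        return "male"
    raise ValueError(f"unknown sex code: {code!r}")


@dataclass(frozen=True)
class DeathRecord:
    """A single death: when, where, and the decedent's age and sex."""

    date: Date
    city_id: str
    age: float
    sex: str  # "female" | "male"

    def __post_init__(self) -> None:
        if not (0 <= self.age <= 120):
            raise ValueError(f"age out of range [0, 120]: {self.age}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific abridged life table of remaining life expectancy e_x.

    ``entries`` maps ``(sex, age_lower_bound)`` to remaining life expectancy
    in years at that exact age. Age bounds must be strictly increasing per
    sex and both sexes must be present.
    """

    entries: Mapping[tuple[str, float], float]
    year: int = 2016

    def __post_init__(self) -> None:
        sexes = {s for s, _ in self.entries}
        if sexes != {"female", "male"}:
            raise ValueError(f"life table must contain both sexes, found {sorted(sexes)}")
        for sex in ("female", "male"):
            ages = self.ages(sex)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"age bounds not strictly increasing for {sex}")
            for a in ages:
                ex = self.entries[(sex, a)]
                if not ex > 0:
                    raise ValueError(f"e_x must be > 0, got {ex} at ({sex}, {a})")

    def ages(self, sex: str) -> np.ndarray:
        return np.array(sorted(a for s, a in self.entries if s == sex), dtype=float)

    def ex(self, sex: str) -> np.ndarray:
        return np.array([self.entries[(sex, a)] for a in self.ages(sex)], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "age": a, "ex": self.entries[(sex, a)]}
            for sex in ("female", "male")
            for a in self.ages(sex)
        ]
        return pd.DataFrame(rows)


@dataclass
class CityDailySeries:
    """Aligned daily series for one city over the study window.

    ``yll`` is total years of life lost per day; ``deaths`` the daily death
    count. Pollutants are 24-h means (O3: max 8-h mean) in ug/m3. Missing
    exposure/weather days are NaN.
    """

    city_id: str
    dates: np.ndarray  # array of datetime64[D], strictly increasing daily
    yll: np.ndarray
    deaths: np.ndarray
    pm25: np.ndarray
    so2: np.ndarray
    no2: np.ndarray
    o3: np.ndarray
    temp: np.ndarray
    rh: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        n = len(self.dates)
        for name in ("yll", "deaths", "pm25", "so2", "no2", "o3", "temp", "rh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != dates length {n}")
            setattr(self, name, arr)
        if n > 1 and not np.all(np.diff(self.dates) == np.timedelta64(1, "D")):
            raise ValueError("dates must form a strictly increasing daily grid")
        if np.any(self.deaths[np.isfinite(self.deaths)] < 0):
            raise ValueError("deaths must be >= 0")
        if np.any(self.deaths[np.isfinite(self.deaths)] % 1 != 0):
            raise ValueError("deaths must be integer counts")
        if np.any(self.yll[np.isfinite(self.yll)] < 0):
            raise ValueError("yll must be >= 0")
        zero_days = np.isfinite(self.deaths) & (self.deaths == 0)
        if np.any(self.yll[zero_days] != 0):
            raise ValueError("yll must be 0 on days with no deaths")
        for name in POLLUTANTS:
            v = getattr(self, name)
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"{name} concentrations must be >= 0")
        rh = self.rh
        if np.any((rh[np.isfinite(rh)] < 0) | (rh[np.isfinite(rh)] > 100)):
            raise ValueError("rh must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "city_id": self.city_id,
                "yll": self.yll,
                "deaths": self.deaths,
                "pm25": self.pm25,
                "so2": self.so2,
                "no2": self.no2,
                "o3": self.o3,
                "temp": self.temp,
                "rh": self.rh,
            }
        )


@dataclass(frozen=True)
class CityMeta:
    """City metadata: region, coordinates and annual covariates (GDP etc.)."""

    city_id: str
    region: str
    longitude: float
    latitude: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not one of {REGIONS}")
        if not (-180 <= self.longitude <= 180):
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not (-90 <= self.latitude <= 90):
            raise ValueError(f"latitude out of range: {self.latitude}")


@dataclass
class StudyDataset:
    """A complete study: all city series, city metadata, life table, holidays."""

    series: list[CityDailySeries]
    meta: list[CityMeta]
    life_table: LifeTable
    holidays: set[Date] = field(default_factory=set)

    def __post_init__(self) -> None:
        meta_ids = [m.city_id for m in self.meta]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate city_id in metadata")
        meta_set = set(meta_ids)
        for s in self.series:
            if s.city_id not in meta_set:
                raise ValueError(f"series city {s.city_id!r} has no CityMeta")
        windows = {(s.dates[0], s.dates[-1]) for s in self.series}
        if len(windows) > 1:
            raise ValueError("all series must share the same study window")

    @property
    def meta_by_id(self) -> dict[str, CityMeta]:
        return {m.city_id: m for m in self.meta}

    def region_series(self, region: str) -> list[CityDailySeries]:
        by_id = self.meta_by_id
        return [s for s in self.series if by_id[s.city_id].region == region]

    @property
    def regions(self) -> list[str]:
        present = {m.region for m in self.meta}
        return [r for r in REGIONS if r in present]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_date(value: object, where: str) -> Date:
    try:
        return pd.Timestamp(str(value)).date()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date {value!r} at {where}") from exc


def read_death_records(
    source: str | Path,
    window: tuple[Date, Date] | None = None,
) -> list[DeathRecord]:
    """Read individual death records from a CSV with columns date,city_id,age,sex.

    Rows violating the record invariants (age outside [0, 120], unknown sex
    code, unparseable date, date outside ``window`` if given) raise a
    ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(source, dtype={"city_id": str})
    required = {"date", "city_id", "age", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"deaths file must have columns {sorted(required)}")
    records: list[DeathRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        where = f"row {i + 2}"  # 1-based + header
        d = _parse_date(row.date, where)
        try:
            age = float(row.age)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable age {row.age!r} at {where}") from exc
        if not (0 <= age <= 120):
            raise ValueError(f"age {age} out of range at {where} (field 'age')")
        try:
            sex = normalize_sex(row.sex)
        except ValueError as exc:
            raise ValueError(f"{exc} at {where}") from exc
        if window is not None and not (window[0] <= d <= window[1]):
            raise ValueError(f"death date {d} outside study window at {where}")
        records.append(DeathRecord(date=d, city_id=str(row.city_id), age=age, sex=sex))
    return records


def read_life_table(source: str | Path, year: int = 2016) -> LifeTable:
    """Read a life table CSV with columns sex, age, ex."""
    df = pd.read_csv(source)
    if not {"sex", "age", "ex"}.issubset(df.columns):
        raise ValueError("life table file must have columns sex, age, ex")
    entries: dict[tuple[str, float], float] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sex = normalize_sex(row.sex)
        key = (sex, float(row.age))
        if key in entries:
            raise ValueError(f"duplicate (sex, age) row at row {i + 2}: {key}")
        entries[key] = float(row.ex)
    return LifeTable(entries=entries, year=year)


def read_city_meta(source: str | Path) -> list[CityMeta]:
    """Read city metadata; columns beyond the core four become covariates."""
    df = pd.read_csv(source, dtype={"city_id": str})
    core = {"city_id", "region", "longitude", "latitude"}
    if not core.issubset(df.columns):
        raise ValueError(f"citymeta file must have columns {sorted(core)}")
    cov_cols = [c for c in df.columns if c not in core]
    metas = []
    for row in df.itertuples(index=False):
        covs = {c: float(getattr(row, c)) for c in cov_cols}
        metas.append(
            CityMeta(
                city_id=str(row.city_id),
                region=str(row.region),
                longitude=float(row.longitude),
                latitude=float(row.latitude),
                covariates=covs,
            )
        )
    return metas


def read_holidays(source: str | Path) -> set[Date]:
    df = pd.read_csv(source)
    if "date" not in df.columns:
        raise ValueError("holidays file must have a 'date' column")
    return {_parse_date(v, f"row {i + 2}") for i, v in enumerate(df["date"])}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def daily_grid(window: tuple[Date, Date]) -> np.ndarray:
    """The closed daily date grid of a study window as datetime64[D]."""
    start, end = window
    if end < start:
        raise ValueError(f"empty window: {start}..{end}")
    n = (end - start).days + 1
    return np.datetime64(start, "D") + np.arange(n)


def _align_daily(
    df: pd.DataFrame, cols: Sequence[str], grid: np.ndarray, what: str
) -> dict[str, np.ndarray]:
    """Align dated columns onto the daily grid; absent days become NaN."""
    dates = np.array([np.datetime64(_parse_date(v, what), "D") for v in df["date"]])
    if len(np.unique(dates)) != len(dates):
        raise ValueError(f"duplicate dates in {what}")
    idx = {d: i for i, d in enumerate(dates)}
    out = {}
    for c in cols:
        vals = np.full(len(grid), np.nan)
        src = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        for j, g in enumerate(grid):
            i = idx.get(g)
            if i is not None:
                vals[j] = src[i]
        out[c] = vals
    return out


def assemble_city_series(
    city_id: str,
    deaths_by_day: Mapping[Date, tuple[int, float]],
    exposure: pd.DataFrame,
    weather: pd.DataFrame,
    window: tuple[Date, Date],
) -> CityDailySeries:
    """Assemble one city's aligned daily series over the full study window.

    ``deaths_by_day`` maps date -> (death count, daily YLL); days absent from
    it get deaths = 0 and yll = 0. Exposure/weather rows are matched by date;
    days without a row are carried as NaN (explicit missing). Duplicate dates
    in any input raise.
    """
    grid = daily_grid(window)
    seen: set[Date] = set()
    for d in deaths_by_day:
        if d in seen:
            raise ValueError(f"duplicate date in deaths_by_day: {d}")
        seen.add(d)
    deaths = np.zeros(len(grid))
    yll = np.zeros(len(grid))
    pos = {g: i for i, g in enumerate(grid)}
    for d, (count, y) in deaths_by_day.items():
        i = pos.get(np.datetime64(d, "D"))
        if i is None:
            raise ValueError(f"death day {d} outside window {window[0]}..{window[1]}")
        deaths[i] = count
        yll[i] = y
    expo = _align_daily(exposure, [c for c in POLLUTANTS if c in exposure.columns], grid, "exposure")
    wx = _align_daily(weather, [c for c in WEATHER if c in weather.columns], grid, "weather")
    nan = np.full(len(grid), np.nan)
    return CityDailySeries(
        city_id=city_id,
        dates=grid,
        yll=yll,
        deaths=deaths,
        pm25=expo.get("pm25", nan.copy()),
        so2=expo.get("so2", nan.copy()),
        no2=expo.get("no2", nan.copy()),
        o3=expo.get("o3", nan.copy()),
        temp=wx.get("temp", nan.copy()),
        rh=wx.get("rh", nan.copy()),
    )


# ---------------------------------------------------------------------------
# Dataset round-trip
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full double precision for lossless CSV round-trips


def write_study(dataset: StudyDataset, outdir: str | Path) -> None:
    """Write an assembled StudyDataset to a directory of CSV files.

    Files: series.csv (daily assembled series for all cities), citymeta.csv,
    lifetable.csv, holidays.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = [s.to_frame() for s in dataset.series]
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "series.csv", index=False, float_format=_FLOAT_FMT,
        date_format="%Y-%m-%d",
    )
    meta_rows = []
    for m in dataset.meta:
        row = {
            "city_id": m.city_id,
            "region": m.region,
            "longitude": m.longitude,
            "latitude": m.latitude,
        }
        row.update(m.covariates)
        meta_rows.append(row)
    pd.DataFrame(meta_rows).to_csv(outdir / "citymeta.csv", index=False, float_format=_FLOAT_FMT)
    dataset.life_table.to_frame().to_csv(
        outdir / "lifetable.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame({"date": sorted(str(d) for d in dataset.holidays)}).to_csv(
        outdir / "holidays.csv", index=False
    )


def read_study(indir: str | Path) -> StudyDataset:
    """Read back a StudyDataset written by :func:`write_study`."""
    indir = Path(indir)
    df = pd.read_csv(indir / "series.csv", dtype={"city_id": str})
    series = []
    for city_id, g in df.groupby("city_id", sort=True):
        g = g.sort_values("date")
        series.append(
            CityDailySeries(
                city_id=str(city_id),
                dates=g["date"].to_numpy(dtype="datetime64[D]"),
                yll=g["yll"].to_numpy(float),
                deaths=g["deaths"].to_numpy(float),
                pm25=g["pm25"].to_numpy(float),
                so2=g["so2"].to_numpy(float),
                no2=g["no2"].to_numpy(float),
                o3=g["o3"].to_numpy(float),
                temp=g["temp"].to_numpy(float),
                rh=g["rh"].to_numpy(float),
            )
        )
    meta = read_city_meta(indir / "citymeta.csv")
    lt = read_life_table(indir / "lifetable.csv")
    holidays_path = indir / "holidays.csv"
    holidays = read_holidays(holidays_path) if holidays_path.exists() else set()
    return StudyDataset(series=series, meta=meta, life_table=lt, holidays=holidays)
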