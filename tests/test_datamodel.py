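from datetime import date

import numpy as np
import pandas as pd
import pytest

from pm25yll import (
    CityDailySeries,
    CityMeta,
    StudyDataset,
    assemble_city_series,
    generate_study,
    read_death_records,
    read_life_table,
    read_study,
    write_study,
)
from pm25yll.datamodel import daily_grid, normalize_sex


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDeathRecords:
    def test_empty_table_gives_empty_sequence(self, tmp_path):
        p = _write(tmp_path, "d.csv", "date,city_id,age,sex\n")
        assert read_death_records(p) == []

    def test_valid_rows_parse_to_records(self, tmp_path):
        p = _write(
            tmp_path,
            "d.csv",
            "date,city_id,age,sex\n"
            "2013-01-18,c1,70,male\n"
            "2013-01-19,c1,82.5,f\n"
            "2013-01-20,c2,64,2\n",
        )
        recs = read_death_records(p)
        assert len(recs) == 3
        assert recs[0].date == date(2013, 1, 18)
        assert recs[0].city_id == "c1" and recs[0].age == 70 and recs[0].sex == "male"
        assert recs[1].sex == "female" and recs[1].age == 82.5
        assert recs[2].sex == "female"  # numeric code 2

    def test_negative_age_names_row_and_field(self, tmp_path):
        p = _write(tmp_path, "d.csv", "date,city_id,age,sex\n2013-01-18,c1,-5,male\n")
        with pytest.raises(ValueError, match="row 2.*age|age.*row 2"):
            read_death_records(p)

    @pytest.mark.parametrize(
        "row", ["not-a-date,c1,70,male", "2013-01-18,c1,seventy,male", "2013-01-18,c1,70,x"]
    )
    def test_bad_values_are_hard_errors(self, tmp_path, row):
        p = _write(tmp_path, "d.csv", f"date,city_id,age,sex\n{row}\n")
        with pytest.raises(ValueError):
            read_death_records(p)

    def test_window_enforced(self, tmp_path):
        p = _write(tmp_path, "d.csv", "date,city_id,age,sex\n2012-01-01,c1,70,male\n")
        with pytest.raises(ValueError, match="outside"):
            read_death_records(p, window=(date(2013, 1, 18), date(2016, 12, 31)))


class TestSexCodes:
    @pytest.mark.parametrize(
        "code,expected",
        [("female", "female"), ("F", "female"), ("2", "female"),
         ("male", "male"), ("m", "male"), ("1", "male")],
    )
    def test_tolerant_normalization(self, code, expected):
        assert normalize_sex(code) == expected

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError):
            normalize_sex("unknown")


class TestReadLifeTable:
    def _fixture_csv(self, tmp_path, sexes=("female", "male")):
        ages = [0, 1] + list(range(5, 90, 5))
        lines = ["sex,age,ex"]
        for sex in sexes:
            base = 80 if sex == "female" else 75
            lines += [f"{sex},{a},{base - 0.8 * a + 1}" for a in ages]
        return _write(tmp_path, "lt.csv", "\n".join(lines) + "\n")

    def test_fixture_has_2x19_entries(self, tmp_path):
        lt = read_life_table(self._fixture_csv(tmp_path))
        assert len(lt.entries) == 38
        assert len(lt.ages("female")) == 19 and len(lt.ages("male")) == 19

    def test_missing_sex_stratum_raises(self, tmp_path):
        with pytest.raises(ValueError, match="both sexes"):
            read_life_table(self._fixture_csv(tmp_path, sexes=("female",)))

    def test_duplicate_row_raises(self, tmp_path):
        p = _write(
            tmp_path, "lt.csv",
            "sex,age,ex\nfemale,0,80\nfemale,0,81\nmale,0,75\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_life_table(p)


class TestAssembleCitySeries:
    WINDOW = (date(2013, 1, 1), date(2013, 1, 5))

    def _expo(self, dates, pm):
        return pd.DataFrame({"date": dates, "pm25": pm})

    def _wx(self, dates, temp):
        return pd.DataFrame({"date": dates, "temp": temp, "rh": [50.0] * len(dates)})

    def test_zero_fill_on_no_death_days(self):
        s = assemble_city_series(
            "c1",
            {date(2013, 1, 2): (1, 6.5)},
            self._expo([f"2013-01-0{i}" for i in range(1, 6)], [10.0] * 5),
            self._wx([f"2013-01-0{i}" for i in range(1, 6)], [5.0] * 5),
            self.WINDOW,
        )
        assert list(s.deaths) == [0, 1, 0, 0, 0]
        assert list(s.yll) == [0, 6.5, 0, 0, 0]
        assert len(s) == 5

    def test_missing_exposure_day_is_nan(self):
        dates = ["2013-01-01", "2013-01-02", "2013-01-04", "2013-01-05"]
        s = assemble_city_series(
            "c1", {}, self._expo(dates, [10.0] * 4),
            self._wx([f"2013-01-0{i}" for i in range(1, 6)], [5.0] * 5), self.WINDOW,
        )
        assert np.isnan(s.pm25[2]) and np.isfinite(s.pm25).sum() == 4

    def test_weather_fully_outside_window_gives_empty_overlap(self):
        s = assemble_city_series(
            "c1", {}, self._expo(["2013-01-01"], [10.0]),
            self._wx(["2014-06-01", "2014-06-02"], [5.0, 6.0]), self.WINDOW,
        )
        assert np.isnan(s.temp).all() and np.isnan(s.rh).all()
        assert len(s) == 5  # output length always equals window length

    def test_duplicate_dates_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_city_series(
                "c1", {}, self._expo(["2013-01-01", "2013-01-01"], [10.0, 11.0]),
                self._wx(["2013-01-01"], [5.0]), self.WINDOW,
            )

    def test_death_outside_window_raises(self):
        with pytest.raises(ValueError, match="outside window"):
            assemble_city_series(
                "c1", {date(2014, 1, 1): (1, 5.0)},
                self._expo(["2013-01-01"], [10.0]), self._wx(["2013-01-01"], [5.0]),
                self.WINDOW,
            )


class TestSeriesInvariants:
    def _series(self, **kw):
        n = 5
        base = dict(
            city_id="c",
            dates=daily_grid((date(2013, 1, 1), date(2013, 1, 5))),
            yll=[0, 6.5, 0, 0, 0],
            deaths=[0, 1, 0, 0, 0],
            pm25=[10] * n, so2=[5] * n, no2=[5] * n, o3=[40] * n,
            temp=[5] * n, rh=[50] * n,
        )
        base.update(kw)
        return CityDailySeries(**base)

    def test_yll_on_zero_death_day_rejected(self):
        with pytest.raises(ValueError, match="no deaths"):
            self._series(yll=[1.0, 6.5, 0, 0, 0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="pm25"):
            self._series(pm25=[-1, 10, 10, 10, 10])

    def test_rh_bounds_enforced(self):
        with pytest.raises(ValueError, match="rh"):
            self._series(rh=[50, 101, 50, 50, 50])

    def test_non_integer_deaths_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            self._series(deaths=[0, 1.5, 0, 0, 0], yll=[0, 6.5, 0, 0, 0])


class TestRegionAndMeta:
    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            CityMeta("c1", "Atlantis", 0.0, 0.0)

    def test_series_without_meta_rejected(self, small_study):
        dataset, _ = small_study
        with pytest.raises(ValueError, match="no CityMeta"):
            StudyDataset(series=dataset.series, meta=dataset.meta[1:],
                         life_table=dataset.life_table)


def test_study_roundtrip_is_lossless(tmp_path, small_study):
    """Writing then reading a StudyDataset preserves every value."""
    dataset, _ = small_study
    write_study(dataset, tmp_path)
    back = read_study(tmp_path)
    assert {s.city_id for s in back.series} == {s.city_id for s in dataset.series}
    orig = {s.city_id: s for s in dataset.series}
    for s in back.series:
        o = orig[s.city_id]
        assert np.array_equal(s.dates, o.dates)
        assert np.array_equal(s.deaths, o.deaths)  # integers exact
        for var in ("yll", "pm25", "so2", "no2", "o3", "temp", "rh"):
            np.testing.assert_allclose(getattr(s, var), getattr(o, var),
                                       rtol=0, atol=1e-12)
    for m, mo in zip(sorted(back.meta, key=lambda m: m.city_id),
                     sorted(dataset.meta, key=lambda m: m.city_id)):
        assert m.city_id == mo.city_id and m.region == mo.region
        for k, v in mo.covariates.items():
            assert abs(m.covariates[k] - v) <= 1e-12 * max(1.0, abs(v))
    assert back.life_table.entries == pytest.approx(dataset.life_table.entries)
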