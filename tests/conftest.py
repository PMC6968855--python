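from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from pm25yll import (
    CityMeta,
    LifeTable,
    SyntheticTruth,
    fit_city_gam,
    generate_life_table,
    generate_study,
)


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return generate_life_table(seed=7)


@pytest.fixture(scope="session")
def tiny_life_table() -> LifeTable:
    """A hand-sized abridged table for exact-value tests."""
    entries = {}
    for sex, top in (("female", 80.0), ("male", 76.0)):
        for age in (0.0, 1.0, 5.0, 40.0, 60.0, 85.0):
            entries[(sex, age)] = top - age * 0.85 + 1.0  # decreasing, > 0
    return LifeTable(entries=entries, year=2016)


@pytest.fixture(scope="session")
def small_study():
    """A 5-city, 600-day synthetic study at the default effect size."""
    truth = SyntheticTruth(seed=5)
    dataset, truth = generate_study(
        {"East": 3, "North": 2}, truth=truth, n_days=600, seed=5
    )
    return dataset, truth


@pytest.fixture(scope="session")
def small_effects(small_study):
    dataset, _ = small_study
    return [fit_city_gam(s)[0] for s in dataset.series]


@pytest.fixture()
def east_meta() -> CityMeta:
    return CityMeta("EAX1", "East", 120.0, 30.0, {})
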