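"""Years of life lost (YLL) from a sex-specific life table.

Each death contributes its remaining life expectancy e_x at the decedent's
exact age and sex; daily city YLL is the sum over that day's deaths. Ages
between abridged-table bounds are linearly interpolated; ages at or above
the open-ended top band use the top band's e_x.
"""

from __future__ import annotations

from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import DeathRecord, LifeTable, daily_grid

__all__ = ["remaining_life_expectancy", "daily_yll"]


def remaining_life_expectancy(lt: LifeTable, age: float, sex: str) -> float:
    """Remaining life expectancy e_x at ``age`` for ``sex``.

    Linear interpolation within abridged age bands; exact at band bounds;
    clipped to the top band's value above it.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    ages = lt.ages(sex)
    ex = lt.ex(sex)
    # np.interp clamps on both ends, which matches the band conventions here:
    # below the first bound (age 0) cannot occur, above the last uses e_top.
    return float(np.interp(age, ages, ex))


def daily_yll(
    deaths: Iterable[DeathRecord],
    lt: LifeTable,
    window: tuple[Date, Date],
) -> dict[Date, tuple[int, float]]:
    """Sum per-death e_x into a full-window mapping date -> (count, yll).

    Every day of the window appears; days with no deaths map to (0, 0.0).
    A death dated outside the window raises, naming the record.
    """
    grid = daily_grid(window)
    out: dict[Date, list] = {d.astype(object): [0, 0.0] for d in grid}
    for rec in deaths:
        key = rec.date
        if key not in out:
            raise ValueError(f"death outside window {window[0]}..{window[1]}: {rec}")
        ex = remaining_life_expectancy(lt, rec.age, rec.sex)
        out[key][0] += 1
        out[key][1] += ex
    return {d: (c, y) for d, (c, y) in out.items()}
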