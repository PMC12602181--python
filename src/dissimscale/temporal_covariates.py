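"""Minimum colonization time and succession time.

*Minimum colonization time* of a species in a unit (plot or transect) is the
number of years between the survey at hand and the earliest survey in which
the species was recorded in that unit — a lower bound on how long it has
been present. By default the clock runs from the first-ever record even if
the species temporarily disappeared from the unit in between
(``reset_on_gap=True`` restarts the clock after each local disappearance).

*Succession time* is the number of years between the survey and the
abandonment of the field as cropland.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataValidationError

logger = logging.getLogger(__name__)


def colonization_time(
    presence_years: Sequence[int],
    observation_year: int,
    reset_on_gap: bool = False,
    survey_years: Sequence[int] | None = None,
) -> int:
    """Years since the species first colonized the unit, at ``observation_year``.

    ``presence_years`` are the survey years in which the species was recorded
    in the unit; ``observation_year`` must be one of them. With
    ``reset_on_gap`` the clock restarts at the first year of the current
    uninterrupted run of surveys, which requires the unit's full survey
    schedule ``survey_years`` to know where the gaps are.
    """
    present = sorted(set(int(y) for y in presence_years))
    observation_year = int(observation_year)
    if observation_year not in present:
        raise DataValidationError(
            f"observation year {observation_year} is not a presence year"
        )
    if not reset_on_gap:
        first = min(y for y in present if y <= observation_year)
        return observation_year - first
    if survey_years is None:
        raise DataValidationError("reset_on_gap requires the unit's survey schedule")
    schedule = sorted(set(int(y) for y in survey_years))
    if observation_year not in schedule:
        raise DataValidationError("observation year is not in the survey schedule")
    first = observation_year
    for y in reversed([y for y in schedule if y <= observation_year]):
        if y in present:
            first = y
        else:
            break
    return observation_year - first


def succession_time(survey_year: int, abandonment_year: int) -> int:
    """Years since field abandonment at the survey date."""
    if survey_year < abandonment_year:
        raise DataValidationError(
            f"survey year {survey_year} precedes abandonment year {abandonment_year}"
        )
    return int(survey_year) - int(abandonment_year)


def add_temporal_covariates(
    cover: pd.DataFrame,
    abandonment: Mapping[str, int],
    unit_cols: Sequence[str] = ("field", "transect", "plot"),
    reset_on_gap: bool = False,
    survey_years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Attach ``colonization_time`` and ``succession_time`` to a cover table.

    ``unit_cols`` define the unit within which colonization is tracked
    (plot at neighborhood scale, transect at site scale — pass the cover
    table already aggregated to that scale). Rows whose survey predates the
    field's abandonment are dropped with a logged count: succession time is
    undefined there.
    """
    unit_cols = list(unit_cols)
    out = cover.copy()
    first_year = out.groupby(unit_cols + ["species"])["year"].transform("min")
    if reset_on_gap:
        col = pd.Series(0, index=out.index, dtype=int)
        for _, g in out.groupby(unit_cols + ["species"], sort=False):
            years = g["year"].tolist()
            col.loc[g.index] = [
                colonization_time(years, y, reset_on_gap=True, survey_years=survey_years)
                for y in g["year"]
            ]
        out["colonization_time"] = col
    else:
        out["colonization_time"] = out["year"] - first_year

    aband = out["field"].map(lambda f: abandonment[f])
    out["succession_time"] = out["year"] - aband
    n_neg = int((out["succession_time"] < 0).sum())
    if n_neg:
        logger.info("dropping %d rows surveyed before field abandonment", n_neg)
        out = out[out["succession_time"] >= 0].reset_index(drop=True)
    return out
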