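"""Site-scale (transect) data from neighborhood-scale (plot) data.

Site-scale cover of a species in a transect-year is its mean cover across
the plots surveyed that year, with absences contributing zero — so the
denominator is the number of plots actually surveyed, not the nominal plot
count. Environmental variables are averaged the same way; burn treatment and
abandonment year are already site-scale attributes and pass through
unchanged.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .data_model import ENV_VARIABLES
from .errors import DataValidationError

logger = logging.getLogger(__name__)


def aggregate_cover(
    cover: pd.DataFrame,
    plots_surveyed: Mapping[tuple, int] | None = None,
) -> pd.DataFrame:
    """Average plot covers to transect scale, one row per
    (field, transect, year, species).

    ``plots_surveyed`` optionally maps (field, transect, year) to the number
    of plots surveyed; by default it is inferred as the number of distinct
    plots with any record in that transect-year.
    """
    if cover.empty:
        raise DataValidationError("cannot aggregate an empty cover table")
    key = ["field", "transect", "year"]
    if plots_surveyed is None:
        counts = cover.groupby(key)["plot"].nunique()
    else:
        counts = pd.Series(plots_surveyed)
        counts.index.names = key
    if (counts < 1).any():
        raise DataValidationError("a transect-year with zero surveyed plots")

    sums = cover.groupby(key + ["species"], as_index=False)["cover"].sum()
    n = sums.set_index(key).index.map(counts)
    sums["cover"] = sums["cover"] / n
    logger.info(
        "aggregate_cover: %d transect-year communities from %d plot rows",
        sums.groupby(key).ngroups, len(cover),
    )
    return sums


def aggregate_env(env: pd.DataFrame) -> pd.DataFrame:
    """Average plot-level environmental measurements to transect scale.

    Soil and light variables are arithmetic means over plots with a value
    (missing plot measurements are skipped; an all-missing variable stays
    missing). ``burned`` and ``abandonment_year``, when present, must be
    homogeneous within a transect and pass through unchanged.
    """
    key = ["field", "transect"]
    present = [v for v in ENV_VARIABLES if v in env.columns]
    out = env.groupby(key, as_index=False)[present].mean()
    for col in ("burned", "abandonment_year"):
        if col in env.columns:
            grp = env.groupby(key)[col]
            n_distinct = grp.nunique(dropna=True)
            if (n_distinct > 1).any():
                raise DataValidationError(
                    f"{col} varies within transect(s) "
                    f"{n_distinct.index[n_distinct > 1].tolist()[:3]}; "
                    "it is a site-scale attribute"
                )
            out[col] = grp.first().to_numpy()
    for v in present:
        n_missing = int(out[v].isna().sum())
        if n_missing:
            logger.warning("aggregate_env: %s missing for %d transects", v, n_missing)
    return out
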