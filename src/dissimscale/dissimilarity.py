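"""Per-species dissimilarity to the rest of its community.

For every species in every community (a plot-year at neighborhood scale, a
transect-year at site scale) five metric families are computed:

* ``ranked_multi`` — Euclidean distance in the 3-axis trait space from the
  target species to the cover-weighted centroid of the other members
  (competitive-hierarchy position in multivariate trait space);
* ``pairwise_multi`` — mean trait-space distance between the target and each
  other member (niche difference irrespective of sorting);
* ``ranked_uni_<trait>`` — signed difference between the target's trait value
  and the cover-weighted community mean (positive = higher than the rest);
* ``pairwise_uni_<trait>`` — mean absolute trait difference to each member;
* ``phylo_dist`` — cover-weighted mean patristic distance to the other
  members of the community.

The target species is excluded from the "rest of the community" for every
metric by default (``include_target`` restores inclusion in the means).
Weighted means are invariant to rescaling all covers, so raw percent covers
are used as weights without renormalization. Species lacking complete trait
data receive no functional metrics; species absent from the phylogeny
receive no phylogenetic metric; a community with no eligible partner yields
missing values, never zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import NON_PLANT_RECORDS, TRAIT_NAMES, PhyloDistances
from .errors import DegenerateInputError
from .trait_space import TraitSpace

logger = logging.getLogger(__name__)

UNIT_COLS = {
    "neighborhood": ["field", "transect", "plot", "year"],
    "site": ["field", "transect", "year"],
}


@dataclass
class MetricConfig:
    """Switches for the under-specified corners of the metric definitions."""

    include_target: bool = False  # include the target in community means/sets
    pairwise_weighted: bool = False  # cover-weight pairwise functional means
    phylo_weighted: bool = True  # cover-weight the phylogenetic mean


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def weighted_centroid(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Cover-weighted mean coordinate (center of gravity) of a point set."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if points.shape[0] == 0:
        raise DegenerateInputError("centroid of an empty point set is undefined")
    return (weights[:, None] * points).sum(axis=0) / weights.sum()


def ranked_multivariate(
    target: np.ndarray, others: np.ndarray, weights: np.ndarray
) -> float:
    """Euclidean distance from the target to the weighted centroid of the
    other community members."""
    centroid = weighted_centroid(others, weights)
    return float(np.linalg.norm(np.asarray(target, dtype=float) - centroid))


def pairwise_multivariate(
    target: np.ndarray,
    others: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Mean Euclidean distance from the target to each other member
    (cover-weighted when ``weights`` is given)."""
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.shape[0] == 0:
        raise DegenerateInputError("pairwise dissimilarity needs at least one other member")
    d = np.linalg.norm(others - np.asarray(target, dtype=float), axis=1)
    if weights is None:
        return float(d.mean())
    w = np.asarray(weights, dtype=float)
    return float((w * d).sum() / w.sum())


def ranked_univariate(target: float, values: np.ndarray, weights: np.ndarray) -> float:
    """Signed difference between the target's trait value and the
    cover-weighted mean of the other members' values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("ranked univariate dissimilarity needs other members")
    w = np.asarray(weights, dtype=float)
    return float(target - (w * values).sum() / w.sum())


def pairwise_univariate(
    target: float, values: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """(Weighted) mean absolute trait difference between the target and each
    other member."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("pairwise univariate dissimilarity needs other members")
    d = np.abs(target - values)
    if weights is None:
        return float(d.mean())
    w = np.asarray(weights, dtype=float)
    return float((w * d).sum() / w.sum())


def phylo_dissimilarity(
    target: str,
    others: Sequence[str],
    weights: np.ndarray,
    distances: PhyloDistances,
    weighted: bool = True,
) -> float:
    """Cover-weighted mean patristic distance from the target species to the
    other members of the community."""
    if target not in distances:
        raise DegenerateInputError(f"species {target!r} is not on the phylogeny")
    others = list(others)
    if not others:
        raise DegenerateInputError("phylogenetic dissimilarity needs other members")
    d = distances.row(target, others)
    if not weighted:
        return float(d.mean())
    w = np.asarray(weights, dtype=float)
    return float((w * d).sum() / w.sum())


# ---------------------------------------------------------------------------
# full table
# ---------------------------------------------------------------------------

def _metric_columns() -> list[str]:
    cols = ["ranked_multi", "pairwise_multi", "phylo_dist"]
    cols += [f"ranked_uni_{t}" for t in TRAIT_NAMES]
    cols += [f"pairwise_uni_{t}" for t in TRAIT_NAMES]
    return cols


def compute_all(
    cover: pd.DataFrame,
    space: TraitSpace,
    traits: pd.DataFrame,
    phylo: PhyloDistances | None,
    scale: str = "neighborhood",
    config: MetricConfig | None = None,
) -> pd.DataFrame:
    """One dissimilarity record per species x community at the given scale.

    ``cover`` must already be at the resolution of ``scale`` (plot rows for
    neighborhood, transect-aggregated rows for site). Bare-ground and litter
    records are never community members. Missing metrics are NaN, with
    ``n_func_others`` / ``n_phylo_others`` recording how many eligible
    partners each species had.
    """
    config = config or MetricConfig()
    unit_cols = UNIT_COLS[scale]
    work = cover[~cover["species"].isin(NON_PLANT_RECORDS)]

    func_species = set(space.scores.index)
    trait_values = traits.reindex(columns=list(TRAIT_NAMES))
    phylo_species = set(phylo.species) if phylo is not None else set()

    records: list[dict] = []
    for key, g in work.groupby(unit_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        species = g["species"].to_numpy()
        covers = g["cover"].to_numpy(dtype=float)
        m = len(species)

        in_space = np.array([s in func_species for s in species])
        coords = space.scores.reindex(species).to_numpy(dtype=float)  # NaN rows allowed
        tvals = trait_values.reindex(species).to_numpy(dtype=float)  # m x 7
        in_tree = np.array([s in phylo_species for s in species])

        # pairwise trait-space distances among in-space members
        idx_space = np.flatnonzero(in_space)
        if idx_space.size:
            sub = coords[idx_space]
            dmat = cdist(sub, sub)

        base = dict(zip(unit_cols, key))
        for i in range(m):
            rec = dict(base)
            rec["scale"] = scale
            rec["species"] = species[i]
            rec["cover"] = covers[i]
            for col in _metric_columns():
                rec[col] = np.nan

            # --- multivariate functional metrics
            n_func_others = 0
            if in_space[i]:
                others = idx_space if config.include_target else idx_space[idx_space != i]
                n_func_others = int((idx_space != i).sum())
                if n_func_others >= 1:
                    w = covers[others]
                    rec["ranked_multi"] = ranked_multivariate(coords[i], coords[others], w)
                    pos_i = int(np.flatnonzero(idx_space == i)[0])
                    pos_o = np.array([int(np.flatnonzero(idx_space == j)[0]) for j in others])
                    dists = dmat[pos_i, pos_o]
                    if config.pairwise_weighted:
                        rec["pairwise_multi"] = float((w * dists).sum() / w.sum())
                    else:
                        rec["pairwise_multi"] = float(dists.mean())
            rec["n_func_others"] = n_func_others

            # --- univariate metrics, per trait on whoever has that trait
            for t_idx, t in enumerate(TRAIT_NAMES):
                if np.isnan(tvals[i, t_idx]):
                    continue
                have = np.flatnonzero(~np.isnan(tvals[:, t_idx]))
                others = have if config.include_target else have[have != i]
                if (have != i).sum() < 1:
                    continue
                v = tvals[others, t_idx]
                w = covers[others]
                rec[f"ranked_uni_{t}"] = ranked_univariate(tvals[i, t_idx], v, w)
                rec[f"pairwise_uni_{t}"] = pairwise_univariate(
                    tvals[i, t_idx], v, w if config.pairwise_weighted else None
                )

            # --- phylogenetic metric
            n_phylo_others = 0
            if in_tree[i]:
                others = np.flatnonzero(in_tree) if config.include_target else np.flatnonzero(
                    in_tree & (np.arange(m) != i)
                )
                n_phylo_others = int((in_tree & (np.arange(m) != i)).sum())
                if n_phylo_others >= 1:
                    rec["phylo_dist"] = phylo_dissimilarity(
                        species[i], list(species[others]), covers[others],
                        phylo, weighted=config.phylo_weighted,
                    )
            rec["n_phylo_others"] = n_phylo_others
            records.append(rec)

    out = pd.DataFrame.from_records(records)
    if out.empty:
        out = pd.DataFrame(
            columns=unit_cols + ["scale", "species", "cover"] + _metric_columns()
            + ["n_func_others", "n_phylo_others"]
        )
    n_missing = int(out["ranked_multi"].isna().sum()) if len(out) else 0
    logger.info(
        "compute_all[%s]: %d records, %d without functional metrics",
        scale, len(out), n_missing,
    )
    return out
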