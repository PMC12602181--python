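"""Core domain tables, file readers/writers, origin recoding, and
data-quality filters shared by every pipeline stage.

All tabular data are plain :class:`pandas.DataFrame` objects in long format.
A *cover table* has one row per (field, transect, plot, year, species) with a
percent-cover value; species absent from a community simply have no row.
Trait, species-origin and environment tables are keyed by species or plot.
Phylogenies are consumed as newick files with branch lengths and reduced to a
patristic (cophenetic) distance matrix, the only tree-derived object the
downstream metrics need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import DataFormatError, DataValidationError, DegenerateInputError

logger = logging.getLogger(__name__)

#: Key columns identifying one cover observation.
COVER_KEY = ["field", "transect", "plot", "year", "species"]
COVER_COLUMNS = COVER_KEY + ["cover"]

#: The seven leaf / whole-plant / seed traits used to build the trait space.
TRAIT_NAMES = (
    "sla",
    "height",
    "leaf_area",
    "ldmc",
    "leaf_fresh_mass",
    "leaf_dry_mass",
    "seed_mass",
)

ORIGIN_CATEGORIES = ("native", "introduced", "unknown")

#: Ground-layer records that are surveyed but are never community members.
NON_PLANT_RECORDS = ("bare_ground", "litter")

ENV_VARIABLES = ("soil_n", "soil_c", "soil_om", "light")


# ---------------------------------------------------------------------------
# cover table
# ---------------------------------------------------------------------------

def validate_cover_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format cover table and drop zero-cover rows.

    Returns a copy with canonical column order and dtypes. Raises
    :class:`DataFormatError` for missing columns and
    :class:`DataValidationError` for negative covers or duplicated keys.
    """
    for col in COVER_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"cover table is missing required column {col!r}")
    out = df[COVER_COLUMNS].reset_index(drop=True)
    out["cover"] = pd.to_numeric(out["cover"], errors="coerce")
    if out["cover"].isna().any():
        bad = out.index[out["cover"].isna()][0]
        raise DataFormatError(f"cover not parseable as a number at row {bad}")
    neg = out.index[out["cover"] < 0]
    if len(neg):
        raise DataValidationError(f"negative cover at row {neg[0]}")
    dup = out.duplicated(subset=COVER_KEY)
    if dup.any():
        key = out.loc[dup.idxmax(), COVER_KEY].tolist()
        raise DataValidationError(f"duplicated observation key {key}")
    n_zero = int((out["cover"] == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-cover rows (absence encoded by row absence)", n_zero)
        out = out[out["cover"] > 0]
    out["year"] = out["year"].astype(int)
    for col in ("field", "transect", "plot", "species"):
        out[col] = out[col].astype(str)
    return out.reset_index(drop=True)


def read_cover_table(path: str | Path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited cover table.

    ``columns`` optionally maps canonical names (``field``, ``transect``,
    ``plot``, ``year``, ``species``, ``cover``) to the column names used in
    the file, to tolerate dialects.
    """
    df = pd.read_csv(path, comment="#")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return validate_cover_table(df)


def write_cover_table(df: pd.DataFrame, path: str | Path) -> None:
    df[COVER_COLUMNS].to_csv(path, index=False)


def exclude_taxa(cover: pd.DataFrame, taxa: Iterable[str]) -> pd.DataFrame:
    """Drop every observation of the given taxa (e.g. trees invading
    grassland plots). An empty set is the identity."""
    taxa = set(taxa)
    if not taxa:
        return cover
    keep = ~cover["species"].isin(taxa)
    logger.info("exclude_taxa: removed %d observations of %d taxa", int((~keep).sum()), len(taxa))
    return cover[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# species origin
# ---------------------------------------------------------------------------

def recode_origin(species: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw USDA origin status to a binary native/introduced factor.

    Species of unknown origin (including genus-level taxa) are counted as
    native; only the USDA *introduced* category is treated as introduced.
    """
    if "origin_raw" not in species.columns:
        raise DataFormatError("species table is missing column 'origin_raw'")
    bad = set(species["origin_raw"].unique()) - set(ORIGIN_CATEGORIES)
    if bad:
        raise DataValidationError(f"unrecognized origin categories: {sorted(bad)}")
    out = species.copy()
    out["origin_binary"] = np.where(out["origin_raw"] == "introduced", "introduced", "native")
    counts = out["origin_binary"].value_counts().to_dict()
    logger.info("origin recoding: %s", counts)
    return out


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

def read_trait_table(path: str | Path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a species x trait table (one row per species, seven trait
    columns, blanks for missing values)."""
    df = pd.read_csv(path, comment="#")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    if "species" not in df.columns:
        raise DataFormatError("trait table is missing column 'species'")
    missing = [t for t in TRAIT_NAMES if t not in df.columns]
    if missing:
        raise DataFormatError(f"trait table is missing trait columns {missing}")
    df = df.set_index("species")
    out = df[list(TRAIT_NAMES)].apply(pd.to_numeric, errors="coerce")
    out.index = out.index.astype(str)
    return out


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename_axis("species").to_csv(path)


def trait_complete_species(traits: pd.DataFrame) -> pd.Index:
    """Species with all seven trait values present."""
    return traits.index[traits[list(TRAIT_NAMES)].notna().all(axis=1)]


def trait_coverage(community: pd.DataFrame, traits: pd.DataFrame) -> tuple[float, float]:
    """Fraction of taxa, and fraction of total cover, accounted for by
    trait-complete species in one community (rows of a single plot/transect
    x year)."""
    if community.empty:
        raise DegenerateInputError("trait coverage is undefined for an empty community")
    complete = trait_complete_species(traits)
    is_complete = community["species"].isin(complete)
    taxa_frac = float(is_complete.mean())
    total = float(community["cover"].sum())
    cover_frac = float(community.loc[is_complete, "cover"].sum() / total) if total > 0 else 0.0
    return taxa_frac, cover_frac


def unit_trait_coverage(
    cover: pd.DataFrame, traits: pd.DataFrame, unit_cols: Sequence[str]
) -> pd.DataFrame:
    """Per-community trait coverage: one row per unit with both fractions."""
    complete = trait_complete_species(traits)
    work = cover.assign(_complete=cover["species"].isin(complete))
    grouped = work.groupby(list(unit_cols))
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "taxa_frac": g["_complete"].mean(),
                "cover_frac": g.loc[g["_complete"], "cover"].sum() / g["cover"].sum(),
            }
        ),
        include_groups=False,
    )
    return out.reset_index()


def filter_by_cover_coverage(
    cover: pd.DataFrame,
    traits: pd.DataFrame,
    threshold: float,
    unit_cols: Sequence[str] = ("field", "transect", "plot", "year"),
) -> pd.DataFrame:
    """Keep only communities in which trait-complete species hold strictly
    more than ``threshold`` of total percent cover (robustness filter against
    missing trait data)."""
    if not 0 <= threshold <= 1:
        raise DataValidationError("coverage threshold must be in [0, 1]")
    cov = unit_trait_coverage(cover, traits, unit_cols)
    keep_units = cov.loc[cov["cover_frac"] > threshold, list(unit_cols)]
    merged = cover.merge(keep_units, on=list(unit_cols), how="inner")
    logger.info(
        "coverage filter (> %.0f%%): kept %d of %d communities",
        100 * threshold,
        len(keep_units),
        len(cov),
    )
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# species / environment tables
# ---------------------------------------------------------------------------

def read_species_table(path: str | Path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    if "species" not in df.columns or "origin_raw" not in df.columns:
        raise DataFormatError("species table needs columns 'species' and 'origin_raw'")
    df["species"] = df["species"].astype(str)
    return recode_origin(df)


def read_env_table(path: str | Path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    for col in ("field", "transect", "plot"):
        if col not in df.columns:
            raise DataFormatError(f"environment table is missing column {col!r}")
        df[col] = df[col].astype(str)
    return df


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def normalize_tip_label(label: str) -> str:
    """Canonical species label: stripped, internal spaces -> underscores."""
    return label.strip().replace(" ", "_")


@dataclass
class PhyloDistances:
    """Patristic (cophenetic) distance matrix over the tips of a phylogeny.

    Distances are sums of branch lengths along tip-to-tip paths, in the
    branch-length units of the input tree.
    """

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.species)}

    def __contains__(self, species: str) -> bool:
        return species in self._index

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def row(self, species: str, others: Sequence[str]) -> np.ndarray:
        i = self._index[species]
        idx = [self._index[s] for s in others]
        return self.matrix[i, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "PhyloDistances":
        labels = [normalize_tip_label(t.label) for t in tree.taxon_namespace]
        if len(set(labels)) != len(labels):
            raise DataValidationError("duplicate tip labels in phylogeny")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise DataFormatError("phylogeny has edges without branch lengths")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: normalize_tip_label(t.label))
        species = [normalize_tip_label(t.label) for t in taxa]
        n = len(taxa)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[i], taxa[j])
                mat[i, j] = mat[j, i] = d
        return cls(species=species, matrix=mat)


def read_phylogeny(path: str | Path) -> PhyloDistances:
    """Read a newick tree with branch lengths and return patristic distances.

    Tip labels are normalized (spaces -> underscores) so they match species
    identifiers in the cover and trait tables; cover-table species absent
    from the tree are permitted (they receive no phylogenetic metric).
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise DataFormatError(f"could not parse newick file {path}: {exc}") from exc
    return PhyloDistances.from_tree(tree)


def phylogenetic_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance implied by a tree: V[i, j] is the shared
    root-to-MRCA path length of tips i and j (their shared evolutionary
    history), computed as (r_i + r_j - d_ij) / 2 from root distances r and
    patristic distances d. Tips ordered alphabetically by normalized label.
    """
    pd_obj = PhyloDistances.from_tree(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    root_dist = {
        normalize_tip_label(leaf.taxon.label): leaf.root_distance
        for leaf in tree.leaf_node_iter()
    }
    r = np.array([root_dist[s] for s in pd_obj.species])
    V = (r[:, None] + r[None, :] - pd_obj.matrix) / 2.0
    return pd_obj.species, V
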