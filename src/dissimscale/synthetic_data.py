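"""Synthetic survey designs and assembly-simulated cover data.

The generator emulates the structure of a long-term grassland succession
survey: 26 old fields abandoned in a staggered sequence, four permanent 39-m
transects per field (six in two fields), 25 plots of 0.5 m x 1 m per
transect placed every 1.5 m, eight surveys between 1983 and 2016, and
periodic burning of half of each field from 2006 onward.

Species covers are produced by a minimal assembly model that encodes the two
competing community-assembly hypotheses as opposing terms in expected
log-cover:

    E[log cover of s in plot p] = alpha
        - gamma_E * (x_s - E_p)^2      (environmental filtering)
        + gamma_L * d_s                (limiting similarity / niche escape)

where ``x_s`` is the species' score on the first trait-space axis, ``E_p``
the plot's position on a hierarchical environmental gradient, and ``d_s``
its ranked multivariate dissimilarity to the community assembled in the
previous survey (the regional pool at equal covers before the first
survey). Lognormal noise is added, species below a presence threshold are
absent, and plot richness is capped at the most abundant species
(recruitment limitation). Setting one gamma positive and the other zero
yields data with a known, recoverable signature of a single process.

Everything is deterministic under an integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
import dendropy
import numpy as np
import pandas as pd

from .data_model import TRAIT_NAMES, PhyloDistances, phylogenetic_covariance
from .errors import DataValidationError, LayoutError
from .trait_space import TraitSpace, build_trait_space

logger = logging.getLogger(__name__)

#: Eight surveys, roughly every five years across 1983-2016.
DEFAULT_SURVEY_YEARS = (1983, 1988, 1993, 1997, 2002, 2007, 2011, 2016)


# ---------------------------------------------------------------------------
# survey design
# ---------------------------------------------------------------------------

@dataclass
class SurveyDesign:
    """Plot layout plus the temporal frame of the survey."""

    plots: pd.DataFrame  # field, transect, plot, position_m, burned
    abandonment: dict[str, int]  # field -> year
    survey_years: tuple[int, ...]
    burn_start: int

    @property
    def n_fields(self) -> int:
        return self.plots["field"].nunique()

    @property
    def n_transects(self) -> int:
        return self.plots.groupby(["field", "transect"]).ngroups

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    def env_frame(self) -> pd.DataFrame:
        """Plot table with abandonment year attached."""
        out = self.plots.copy()
        out["abandonment_year"] = out["field"].map(self.abandonment)
        return out


def generate_design(
    n_fields: int = 26,
    n_transects_default: int = 4,
    fields_with_extra: int = 2,
    extra_transects: int = 6,
    transect_length_m: float = 39.0,
    plot_spacing_m: float = 1.5,
    plot_length_m: float = 1.0,
    first_plot_at_m: float = 1.5,
    plots_per_transect: int | None = None,
    survey_years: tuple[int, ...] = DEFAULT_SURVEY_YEARS,
    burn_start: int = 2006,
    abandonment_range: tuple[int, int] = (1927, 2015),
) -> SurveyDesign:
    """Deterministic survey layout.

    Plot positions follow the geometric rule: plots of ``plot_length_m``
    placed every ``plot_spacing_m`` starting at ``first_plot_at_m``, each
    fully inside the transect. If ``plots_per_transect`` is given it must
    agree with that rule. With the default parameters the layout yields 108
    transects and 2700 plots. Burning (from ``burn_start``) is assigned to
    alternate transects, so half of each field's plots burn and the
    treatment is homogeneous at site scale. Abandonment years are staggered
    evenly across ``abandonment_range``.
    """
    if n_fields < 1 or n_transects_default < 1:
        raise LayoutError("need at least one field and one transect")
    if fields_with_extra > n_fields:
        raise LayoutError("more extra-transect fields than fields")
    geometric = int(np.floor((transect_length_m - plot_length_m - first_plot_at_m) / plot_spacing_m)) + 1
    if plots_per_transect is None:
        plots_per_transect = geometric
    elif plots_per_transect != geometric:
        raise LayoutError(
            f"{plots_per_transect} plots/transect inconsistent with geometry "
            f"({geometric} plots of {plot_length_m} m every {plot_spacing_m} m "
            f"in {transect_length_m} m)"
        )
    positions = first_plot_at_m + plot_spacing_m * np.arange(plots_per_transect)

    lo, hi = abandonment_range
    aband_years = np.linspace(lo, hi, n_fields).round().astype(int) if n_fields > 1 else np.array([lo])

    rows = []
    abandonment: dict[str, int] = {}
    for fi in range(n_fields):
        fid = f"F{fi + 1:02d}"
        abandonment[fid] = int(aband_years[fi])
        n_tr = extra_transects if fi < fields_with_extra else n_transects_default
        for ti in range(n_tr):
            tid = f"T{ti + 1}"
            burned = ti % 2 == 0  # alternate transects burn from burn_start
            for pi in range(plots_per_transect):
                rows.append(
                    {"field": fid, "transect": tid, "plot": f"P{pi + 1:02d}",
                     "position_m": float(positions[pi]), "burned": burned}
                )
    plots = pd.DataFrame(rows)
    logger.info(
        "generate_design: %d fields, %d transects, %d plots",
        n_fields, plots.groupby(["field", "transect"]).ngroups, len(plots),
    )
    return SurveyDesign(
        plots=plots, abandonment=abandonment,
        survey_years=tuple(int(y) for y in survey_years), burn_start=burn_start,
    )


# ---------------------------------------------------------------------------
# phylogeny, traits, origins
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips.

    Lineages split at exponential waiting times; after the last split the
    tree is extended by one more exponential draw so tip branches have
    positive length. Tip labels are s001, s002, ...
    """
    if n_species < 2:
        raise DataValidationError("need at least 2 species for a phylogeny")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    root = tree.seed_node
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    present = t + rng.exponential(1.0 / (birth_rate * len(active)))
    width = len(str(n_species))
    # deterministic labelling: sort pending tips by their traversal order
    for k, (node, born) in enumerate(active):
        node.edge.length = present - born
        taxon = taxa.new_taxon(label=f"s{k + 1:0{width}d}")
        node.taxon = taxon
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    lambda_signal: float,
    seed: int,
    trait_names: tuple[str, ...] = TRAIT_NAMES,
) -> pd.DataFrame:
    """Traits with tunable phylogenetic signal.

    Each trait is sqrt(lambda) x (Brownian realization on the tree, unit tip
    variance) + sqrt(1 - lambda) x (independent standard normal), then
    standardized. lambda = 0 gives no signal, lambda = 1 pure Brownian
    motion. Values are on a standardized (log-like) scale, which is all the
    scale-invariant downstream standardization ever uses.
    """
    if not 0 <= lambda_signal <= 1:
        raise DataValidationError("lambda_signal must be in [0, 1]")
    species, V = phylogenetic_covariance(tree)
    diag = np.sqrt(np.diag(V))
    corr = V / np.outer(diag, diag)  # unit tip variance
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(species)))
    rng = np.random.default_rng(seed)
    n = len(species)
    cols = {}
    for name in trait_names:
        bm = L @ rng.standard_normal(n)
        iid = rng.standard_normal(n)
        x = np.sqrt(lambda_signal) * bm + np.sqrt(1 - lambda_signal) * iid
        cols[name] = (x - x.mean()) / x.std(ddof=1)
    return pd.DataFrame(cols, index=pd.Index(species, name="species"))


def simulate_origins(
    species: list[str],
    prop_introduced: float,
    seed: int,
    prop_unknown: float = 0.125,
) -> pd.DataFrame:
    """Random native / introduced / unknown assignment at fixed proportions."""
    rng = np.random.default_rng(seed)
    n = len(species)
    n_intro = int(round(prop_introduced * n))
    n_unknown = int(round(prop_unknown * n))
    labels = np.array(["native"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_intro]] = "introduced"
    labels[order[n_intro:n_intro + n_unknown]] = "unknown"
    df = pd.DataFrame({"species": species, "origin_raw": labels})
    from .data_model import recode_origin

    return recode_origin(df)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_environment(
    design: SurveyDesign,
    env_sd: tuple[float, float, float] = (1.0, 0.5, 0.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Hierarchical environmental gradient and correlated covariates.

    The latent gradient is E_plot = field effect + transect effect + plot
    effect with the given SDs. Soil nitrogen, carbon, organic matter and
    light penetration are monotone transforms of E plus independent noise,
    in plausible units for nitrogen-poor sandy grassland soils (soil N a few
    tenths of a percent, C roughly tenfold N, light penetration a percent).
    """
    sd_field, sd_transect, sd_plot = env_sd
    if min(env_sd) < 0:
        raise DataValidationError("environment SDs must be non-negative")
    rng = np.random.default_rng(seed)
    plots = design.plots.copy()
    fields = plots["field"].unique()
    transects = plots[["field", "transect"]].drop_duplicates()
    f_eff = dict(zip(fields, sd_field * rng.standard_normal(len(fields))))
    t_eff = {
        (r.field, r.transect): sd_transect * rng.standard_normal()
        for r in transects.itertuples()
    }
    p_eff = sd_plot * rng.standard_normal(len(plots))
    E = (
        plots["field"].map(f_eff).to_numpy()
        + np.array([t_eff[(f, t)] for f, t in zip(plots["field"], plots["transect"])])
        + p_eff
    )
    noise = 0.05 * rng.standard_normal((4, len(plots)))
    plots["env_gradient"] = E
    plots["soil_n"] = np.clip(0.15 * np.exp(0.3 * E + noise[0]), 0.005, 5.0)
    plots["soil_c"] = np.clip(10.0 * plots["soil_n"] * np.exp(noise[1]), 0.05, 40.0)
    plots["soil_om"] = np.clip(2.0 + 0.8 * E + 2.0 * noise[2], 0.1, 20.0)
    plots["light"] = np.clip(50.0 + 20.0 * np.tanh(0.5 * E) + 20 * noise[3], 0.5, 99.5)
    return plots


# ---------------------------------------------------------------------------
# assembly simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Ground-truth parameters of the assembly model."""

    n_species: int = 303
    prop_introduced: float = 47 / 303
    gamma_e: float = 0.5  # environmental filtering strength (>= 0)
    gamma_l: float = 0.5  # limiting-similarity strength (sign free)
    env_sd: tuple[float, float, float] = (1.0, 0.5, 0.25)
    noise_sd: float = 0.7  # lognormal cover noise
    lambda_signal: float = 0.3  # weak phylogenetic trait signal
    alpha: float = float(np.log(5.0))  # baseline log percent cover
    presence_threshold: float = 3.0  # percent cover below which absent
    max_richness: int = 15  # recruitment cap per community
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the ground truth behind it."""

    cover: pd.DataFrame
    traits: pd.DataFrame
    species: pd.DataFrame  # origin table
    env: pd.DataFrame  # plot-level, includes burned + abandonment_year
    tree: dendropy.Tree
    phylo: PhyloDistances
    design: SurveyDesign
    space: TraitSpace
    params: SimulationParams
    truth: dict = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick")


def simulate_assembly(
    traits: pd.DataFrame,
    space: TraitSpace,
    design: SurveyDesign,
    env: pd.DataFrame,
    params: SimulationParams,
) -> pd.DataFrame:
    """Assemble communities plot by plot, survey by survey.

    Returns a long-format cover table. The first survey assembles each plot
    from the regional pool (equal covers); later surveys use the plot's
    previous realized community to measure each candidate's dissimilarity,
    so colonization histories are meaningful.
    """
    if traits.empty:
        raise DataValidationError("empty species pool")
    pool = list(space.scores.index)
    coords = space.scores.to_numpy(dtype=float)
    x1 = coords[:, 0]
    n_pool = len(pool)
    rng = np.random.default_rng(params.seed)

    env_by_plot = env.set_index(["field", "transect", "plot"])
    rows = []
    for plot_key, E_p in env_by_plot["env_gradient"].items():
        # previous community: (indices into pool, covers); regional pool first
        prev_idx = np.arange(n_pool)
        prev_cov = np.ones(n_pool)
        for year in design.survey_years:
            d = np.zeros(n_pool)
            if params.gamma_l != 0.0:
                tot_w = prev_cov.sum()
                tot_wx = prev_cov @ coords[prev_idx]
                in_prev = np.full(n_pool, -1)
                in_prev[prev_idx] = np.arange(len(prev_idx))
                for s in range(n_pool):
                    j = in_prev[s]
                    if j >= 0:  # leave-one-out centroid
                        w = tot_w - prev_cov[j]
                        if w <= 0:
                            continue
                        centroid = (tot_wx - prev_cov[j] * coords[s]) / w
                    else:
                        centroid = tot_wx / tot_w
                    d[s] = np.linalg.norm(coords[s] - centroid)
            mu = (
                params.alpha
                - params.gamma_e * (x1 - E_p) ** 2
                + params.gamma_l * d
                + params.noise_sd * rng.standard_normal(n_pool)
            )
            cover = np.minimum(np.exp(mu), 100.0)
            present = np.flatnonzero(cover >= params.presence_threshold)
            if len(present) > params.max_richness:
                top = np.argsort(cover[present], kind="stable")[-params.max_richness:]
                present = present[np.sort(top)]
            for s in present:
                rows.append(
                    {"field": plot_key[0], "transect": plot_key[1], "plot": plot_key[2],
                     "year": year, "species": pool[s], "cover": float(cover[s])}
                )
            if len(present):
                prev_idx = present
                prev_cov = cover[present]
            # an emptied plot keeps its previous community as the reference
    out = pd.DataFrame(rows, columns=["field", "transect", "plot", "year", "species", "cover"])
    logger.info("simulate_assembly: %d observations in %d plot-years",
                len(out), out.groupby(["field", "transect", "plot", "year"]).ngroups)
    return out


def simulate_dataset(
    params: SimulationParams | None = None,
    design: SurveyDesign | None = None,
    **overrides,
) -> SyntheticDataset:
    """One self-consistent synthetic dataset: design, tree, traits, origins,
    environment and assembled cover, all derived from ``params.seed``."""
    params = replace(params, **overrides) if params else SimulationParams(**overrides)
    if design is None:
        design = generate_design()
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    tree = simulate_phylogeny(params.n_species, seed=seeds[0])
    traits = simulate_traits(tree, params.lambda_signal, seed=seeds[1])
    species = simulate_origins(list(traits.index), params.prop_introduced, seed=seeds[2])
    env = simulate_environment(design, params.env_sd, seed=seeds[3])
    space = build_trait_space(traits, n_axes=3)
    cover = simulate_assembly(traits, space, design, env, params)
    phylo = PhyloDistances.from_tree(tree)

    env_full = env.merge(design.env_frame()[["field", "transect", "plot", "abandonment_year"]],
                         on=["field", "transect", "plot"])
    truth = {
        "gamma_e": params.gamma_e, "gamma_l": params.gamma_l,
        "alpha": params.alpha, "noise_sd": params.noise_sd,
        "axis1_scores": dict(zip(space.scores.index, space.scores.iloc[:, 0])),
    }
    return SyntheticDataset(
        cover=cover, traits=traits, species=species, env=env_full, tree=tree,
        phylo=phylo, design=design, space=space, params=params, truth=truth,
    )


def reduced_design(
    n_fields: int = 10,
    n_transects: int = 2,
    plots_per_transect: int = 3,
    survey_years: tuple[int, ...] = (1994, 2005, 2016),
) -> SurveyDesign:
    """A scaled-down survey design for simulation experiments: same nested
    geometry, fewer units, abandonment staggered early enough that every
    survey postdates it."""
    # transect just long enough for the requested plot count under the
    # standard 1.5 m spacing rule
    length = 2.5 + 1.5 * (plots_per_transect - 1)
    return generate_design(
        n_fields=n_fields, n_transects_default=n_transects, fields_with_extra=0,
        transect_length_m=length, survey_years=survey_years,
        abandonment_range=(1927, 1980),
    )
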