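"""Simulation experiments that validate the pipeline end to end.

These are the package's own checks that the machinery can recover known
ground truth: assembly simulations with a single active process must yield
the matching dissimilarity-abundance slope, neutral simulations must not;
Brownian traits must give Blomberg's K near one; the mixed-model stage must
recover known coefficients and collapse to ordinary least squares when
random variance is absent. They run at a deliberately reduced survey size
(10 fields, 2 transects each, 3 plots per transect, 3 surveys, 50 species)
so a full replicate set completes in minutes on one core.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .dissimilarity import compute_all
from .mixed_models import CORE_TERMS, LMMFit, ModelSpec, build_design, fit_lmm
from .scale_aggregation import aggregate_cover
from .synthetic_data import (
    SimulationParams,
    SurveyDesign,
    reduced_design,
    simulate_dataset,
    simulate_phylogeny,
    simulate_traits,
)
from .trait_space import blomberg_k, phylo_signal
from .data_model import phylogenetic_covariance

logger = logging.getLogger(__name__)

CORE_SPEC = ModelSpec("core", CORE_TERMS)
CORE_TRANSFORMS = {"phylo_dist": "z", "ranked_multi": "z"}

SCENARIOS = {
    # scenario -> (gamma_e, gamma_l, scale at which the signature is read)
    "limiting": (0.0, 0.5, "neighborhood"),
    "filtering": (0.5, 0.0, "site"),
    "neutral": (0.0, 0.0, "neighborhood"),
}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def fit_core_model(ds, scale: str) -> LMMFit:
    """Run the analysis stages on a synthetic dataset and fit the core
    model (phylogenetic distance + ranked multivariate dissimilarity,
    crossed random intercepts) at the requested scale."""
    cover = aggregate_cover(ds.cover) if scale == "site" else ds.cover
    records = compute_all(cover, ds.space, ds.traits, ds.phylo, scale=scale)
    records = records.merge(
        ds.species[["species", "origin_binary"]], on="species", how="left"
    )
    design = build_design(records, CORE_SPEC, CORE_TRANSFORMS, scale=scale)
    return fit_lmm(design, CORE_SPEC, scale=scale, reml=True)


def recovery_experiment(
    scenario: str,
    n_reps: int = 20,
    seed: int = 0,
    n_species: int = 50,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """Slope and p-value of ranked multivariate dissimilarity across
    replicate assembly simulations of one scenario.

    ``limiting`` turns on only the limiting-similarity term and reads the
    neighborhood-scale slope (expected positive); ``filtering`` turns on
    only environmental filtering and reads the site-scale slope (expected
    negative); ``neutral`` has neither process (expected non-significant).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    gamma_e, gamma_l, scale = SCENARIOS[scenario]
    design = design or reduced_design()
    rows = []
    for rep, rep_seed in enumerate(_spawn_seeds(seed, n_reps)):
        params = SimulationParams(
            n_species=n_species, gamma_e=gamma_e, gamma_l=gamma_l, seed=rep_seed
        )
        ds = simulate_dataset(params, design=design)
        fit = fit_core_model(ds, scale)
        slope = float(fit.params["ranked_multi"])
        p = float(fit.pvalues["ranked_multi"])
        rows.append(
            {"scenario": scenario, "rep": rep, "seed": rep_seed, "scale": scale,
             "slope": slope, "p_value": p, "n": fit.n}
        )
        logger.info("recovery[%s] rep %d: slope=%.3f p=%.4f", scenario, rep, slope, p)
    return pd.DataFrame(rows)


def recovery_success_rate(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of replicates with the scenario's expected outcome."""
    scenario = results["scenario"].iloc[0]
    if scenario == "limiting":
        ok = (results["slope"] > 0) & (results["p_value"] < alpha)
    elif scenario == "filtering":
        ok = (results["slope"] < 0) & (results["p_value"] < alpha)
    else:  # neutral: no detection
        ok = results["p_value"] >= alpha
    return float(ok.mean())


# ---------------------------------------------------------------------------
# phylogenetic signal calibration
# ---------------------------------------------------------------------------

def signal_calibration(
    n_reps: int = 20,
    n_tips: int = 100,
    seed: int = 0,
    n_perm: int = 199,
) -> pd.DataFrame:
    """Blomberg's K on Brownian traits versus tip-permuted traits.

    Brownian evolution should give K near one; destroying the phylogenetic
    structure by permuting tip values should give K well below one with a
    non-significant permutation p-value.
    """
    rows = []
    for rep, rep_seed in enumerate(_spawn_seeds(seed, n_reps)):
        sub = _spawn_seeds(rep_seed, 3)
        tree = simulate_phylogeny(n_tips, seed=sub[0])
        species, V = phylogenetic_covariance(tree)
        trait = simulate_traits(tree, lambda_signal=1.0, seed=sub[1]).iloc[:, 0]
        x = trait.reindex(species).to_numpy()
        k_bm = blomberg_k(x, V)
        rng = np.random.default_rng(sub[2])
        permuted = pd.Series(rng.permutation(x), index=species, name=trait.name)
        res_perm = phylo_signal(permuted, tree, statistic="K", n_perm=n_perm, seed=sub[2])
        rows.append(
            {"rep": rep, "k_brownian": k_bm, "k_permuted": res_perm.estimate,
             "p_permuted": res_perm.p_value}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-model sanity
# ---------------------------------------------------------------------------

def _simulate_lmm_data(
    seed: int,
    n: int = 2000,
    n_species: int = 20,
    n_transects: int = 10,
    n_years: int = 5,
    beta: Sequence[float] = (1.0, 0.5, -0.3),
    sd_species: float = 0.5,
    sd_year: float = 0.3,
    sd_transect: float = 0.4,
    sd_resid: float = 1.0,
) -> pd.DataFrame:
    """Data drawn directly from the mixed model: two continuous predictors
    (named after the core dissimilarity terms so the standard model spec
    applies) plus crossed species / year / transect intercepts."""
    rng = np.random.default_rng(seed)
    species = rng.integers(n_species, size=n)
    year = rng.integers(n_years, size=n)
    transect = rng.integers(n_transects, size=n)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    u_s = sd_species * rng.standard_normal(n_species)
    u_y = sd_year * rng.standard_normal(n_years)
    u_t = sd_transect * rng.standard_normal(n_transects)
    y = (
        beta[0] + beta[1] * x1 + beta[2] * x2
        + u_s[species] + u_y[year] + u_t[transect]
        + sd_resid * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {"y": y, "phylo_dist": x1, "ranked_multi": x2,
         "species": [f"sp{i}" for i in species],
         "year": year, "transect_id": [f"tr{i}" for i in transect]}
    )


def beta_recovery_experiment(
    n_reps: int = 20,
    seed: int = 1,
    beta: Sequence[float] = (1.0, 0.5, -0.3),
    **sim_kwargs,
) -> pd.DataFrame:
    """Fit the mixed model to data simulated from it (seeds ``seed`` to
    ``seed + n_reps - 1``) and record whether each true coefficient falls in
    its 95% Wald interval."""
    rows = []
    terms = ["Intercept", "phylo_dist", "ranked_multi"]
    for rep in range(n_reps):
        data = _simulate_lmm_data(seed + rep, beta=beta, **sim_kwargs)
        fit = fit_lmm(data, CORE_SPEC, scale="site", reml=True)
        row = {"rep": rep, "seed": seed + rep}
        for term, true in zip(terms, beta):
            lo, hi = fit.wald_interval(term)
            row[f"covered_{term}"] = bool(lo <= true <= hi)
            row[f"estimate_{term}"] = float(fit.params[term])
        rows.append(row)
    return pd.DataFrame(rows)


def null_slope_pvalues(
    n_sims: int = 200,
    seed: int = 0,
    n: int = 150,
    n_species: int = 10,
    n_transects: int = 5,
    n_years: int = 3,
) -> np.ndarray:
    """Wald p-values of a predictor with zero true effect, across many small
    simulated fits — should be uniform on [0, 1]."""
    out = []
    for sim_seed in _spawn_seeds(seed, n_sims):
        data = _simulate_lmm_data(
            sim_seed, n=n, n_species=n_species, n_transects=n_transects,
            n_years=n_years, beta=(1.0, 0.0, 0.0),
        )
        fit = fit_lmm(data, CORE_SPEC, scale="site", reml=True)
        out.append(float(fit.pvalues["phylo_dist"]))
    return np.asarray(out)


def ols_reduction_check(seed: int = 0, n: int = 10000) -> float:
    """Max absolute difference between mixed-model and OLS fixed-effect
    estimates on data with zero random variance."""
    import statsmodels.api as sm

    data = _simulate_lmm_data(
        seed, n=n, sd_species=0.0, sd_year=0.0, sd_transect=0.0, sd_resid=1.0
    )
    fit = fit_lmm(data, CORE_SPEC, scale="site", reml=True)
    X = sm.add_constant(data[["phylo_dist", "ranked_multi"]], has_constant="add")
    ols = sm.OLS(data["y"].to_numpy(), X).fit()
    ols_params = np.asarray(ols.params)
    lmm_params = fit.params[["Intercept", "phylo_dist", "ranked_multi"]].to_numpy()
    return float(np.max(np.abs(lmm_params - ols_params)))
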