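"""End-to-end orchestration: data in (files or simulation), dissimilarity
tables at both scales, covariates, model selection, fitted coefficients and
origin contrasts out — all governed by one configuration and one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import data_model
from .data_model import TRAIT_NAMES
from .dissimilarity import MetricConfig, compute_all
from .errors import ConfigError
from .mixed_models import (
    CORE_TERMS,
    LMMFit,
    ModelSpec,
    SelectionResult,
    build_design,
    drop_collinear,
    origin_contrasts,
    select_model,
)
from .scale_aggregation import aggregate_cover, aggregate_env
from .synthetic_data import SimulationParams, generate_design, simulate_dataset
from .temporal_covariates import add_temporal_covariates
from .trait_space import build_trait_space

logger = logging.getLogger(__name__)

ENV_TERMS = ("soil_n", "soil_om", "light", "burned")
TEMPORAL_TERMS = ("colonization_time", "succession_time")
UNI_TERMS = tuple(f"ranked_uni_{t}" for t in TRAIT_NAMES)

DEFAULT_TRANSFORMS: dict[str, str] = {
    "phylo_dist": "z",
    "ranked_multi": "z",
    **{t: "z" for t in UNI_TERMS},
    "soil_n": "log_z",
    "soil_om": "log_z",
    "light": "z",
    "colonization_time": "log1p_z",
    "succession_time": "log1p_z",
}


def default_ladder() -> list[ModelSpec]:
    """Candidate fixed-effect structures, from the core dissimilarity-only
    model up to all covariates with origin interactions. Soil carbon is not
    a candidate term (it tracks soil nitrogen too closely)."""
    full = CORE_TERMS + UNI_TERMS + ENV_TERMS + TEMPORAL_TERMS
    return [
        ModelSpec("core", CORE_TERMS),
        ModelSpec("core_univariate", CORE_TERMS + UNI_TERMS),
        ModelSpec("core_environment", CORE_TERMS + ENV_TERMS + TEMPORAL_TERMS),
        ModelSpec("full_interactions", full, interactions=full),
    ]


@dataclass
class RunConfig:
    """One reproducibility surface for a whole pipeline run.

    Exactly one of ``inputs`` (paths to cover/traits/species/env/tree files)
    and ``simulation`` (generator parameters) must be given.
    """

    seed: int = 0
    outdir: str | Path = "runs/latest"
    inputs: dict[str, str] | None = None
    simulation: dict[str, Any] | None = None
    design: dict[str, Any] = field(default_factory=dict)
    metrics: dict[str, Any] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    ladder: list[dict] | None = None
    exclude: list[str] = field(default_factory=list)
    coverage_threshold: float | None = None
    r_threshold: float = 0.7
    vif_threshold: float = 5.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigError("exactly one of 'inputs' and 'simulation' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def model_specs(self) -> list[ModelSpec]:
        if self.ladder is None:
            return default_ladder()
        return [
            ModelSpec(d["name"], tuple(d["fixed"]), tuple(d.get("interactions", ())))
            for d in self.ladder
        ]

    def hash(self) -> str:
        canon = dataclasses.asdict(self)
        canon["outdir"] = None  # output location does not affect results
        blob = json.dumps(canon, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScaleResult:
    records: pd.DataFrame
    selection: SelectionResult
    contrasts: pd.DataFrame
    kept_predictors: list[str]

    @property
    def fit(self) -> LMMFit:
        return self.selection.winner_fit


@dataclass
class RunResult:
    config: RunConfig
    scales: dict[str, ScaleResult]
    outdir: Path

    def summary(self) -> pd.DataFrame:
        return summarize_run(self)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_data(config: RunConfig):
    """Return (cover, traits, species, env, phylo, abandonment, survey_years)."""
    if config.simulation is not None:
        sim = dict(config.simulation)
        design = generate_design(**config.design) if config.design else None
        params = SimulationParams(**{**sim, "seed": sim.get("seed", config.seed)})
        ds = simulate_dataset(params, design=design)
        return (
            ds.cover, ds.traits, ds.species, ds.env, ds.phylo,
            ds.design.abandonment, ds.design.survey_years, ds.space,
        )
    paths = config.inputs
    for key in ("cover", "traits", "species", "env", "tree"):
        if key not in paths:
            raise ConfigError(f"inputs is missing path for {key!r}")
    cover = data_model.read_cover_table(paths["cover"])
    traits = data_model.read_trait_table(paths["traits"])
    species = data_model.read_species_table(paths["species"])
    env = data_model.read_env_table(paths["env"])
    phylo = data_model.read_phylogeny(paths["tree"])
    aband = (
        env[["field", "abandonment_year"]].drop_duplicates().set_index("field")
        ["abandonment_year"].astype(int).to_dict()
    )
    years = tuple(sorted(cover["year"].unique()))
    space = build_trait_space(traits, n_axes=3)
    return cover, traits, species, env, phylo, aband, years, space


def _records_for_scale(
    scale: str, cover: pd.DataFrame, space, traits, phylo, env, species,
    abandonment, metric_config: MetricConfig,
) -> pd.DataFrame:
    if scale == "site":
        cover = aggregate_cover(cover)
        env_scale = aggregate_env(env)
        unit = ["field", "transect"]
    else:
        env_scale = env
        unit = ["field", "transect", "plot"]
    cover = add_temporal_covariates(cover, abandonment, unit_cols=unit)
    records = compute_all(cover, space, traits, phylo, scale=scale, config=metric_config)
    records = records.merge(
        cover[unit + ["year", "species", "colonization_time", "succession_time"]],
        on=unit + ["year", "species"], how="left",
    )
    env_cols = [c for c in ("soil_n", "soil_c", "soil_om", "light", "burned") if c in env_scale.columns]
    records = records.merge(env_scale[unit + env_cols], on=unit, how="left")
    if "burned" in records.columns:
        records["burned"] = records["burned"].astype(float)
    records = records.merge(
        species[["species", "origin_binary"]], on="species", how="left"
    )
    return records


def _fit_scale(records: pd.DataFrame, config: RunConfig, scale: str) -> ScaleResult:
    specs = config.model_specs()
    largest = max(specs, key=lambda s: len(s.fixed))
    design = build_design(records, largest, config.transforms, scale=scale)
    kept, _report = drop_collinear(
        design[list(largest.fixed)],
        r_threshold=config.r_threshold,
        vif_threshold=config.vif_threshold,
        protected=CORE_TERMS,
    )
    dropped = set(largest.fixed) - set(kept)
    if dropped:
        logger.info("[%s] collinearity removed: %s", scale, sorted(dropped))
        specs = [
            ModelSpec(
                s.name,
                tuple(t for t in s.fixed if t in kept),
                tuple(t for t in s.interactions if t in kept),
            )
            for s in specs
        ]
    selection = select_model(records, specs, config.transforms, scale=scale)
    contrasts = origin_contrasts(selection.winner_fit)
    return ScaleResult(
        records=records, selection=selection, contrasts=contrasts,
        kept_predictors=kept,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage at both spatial scales and write the artifacts.

    Outputs (per scale: dissimilarity records, model-selection table,
    coefficients, origin contrasts; plus a cross-scale summary) are stamped
    with the config hash and seed via ``manifest.json``; re-running the same
    config reproduces them byte for byte.
    """
    np.random.seed(config.seed % (2**31))  # statsmodels optimizers are deterministic anyway
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cover, traits, species, env, phylo, abandonment, years, space = _load_data(config)
    if config.exclude:
        cover = data_model.exclude_taxa(cover, config.exclude)
    if config.coverage_threshold is not None:
        cover = data_model.filter_by_cover_coverage(
            cover, traits, config.coverage_threshold
        )
    metric_config = MetricConfig(**config.metrics)

    scales: dict[str, ScaleResult] = {}
    for scale in ("neighborhood", "site"):
        records = _records_for_scale(
            scale, cover, space, traits, phylo, env, species, abandonment, metric_config
        )
        result = _fit_scale(records, config, scale)
        scales[scale] = result
        records.to_csv(outdir / f"{scale}_dissimilarity.csv", index=False)
        result.selection.table.to_csv(outdir / f"{scale}_selection.csv", index=False)
        result.fit.coefficient_table().to_csv(
            outdir / f"{scale}_coefficients.csv", index=False
        )
        result.contrasts.to_csv(outdir / f"{scale}_contrasts.csv", index=False)

    run = RunResult(config=config, scales=scales, outdir=outdir)
    summary = summarize_run(run, alpha=config.alpha)
    summary.to_csv(outdir / "summary.csv", index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "scales": {
            s: {
                "winner": r.selection.winner.name,
                "n": r.fit.n,
                "marginal_r2": r.fit.r2()[0],
                "conditional_r2": r.fit.r2()[1],
            }
            for s, r in scales.items()
        },
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return run


def summarize_run(run: RunResult, alpha: float = 0.05) -> pd.DataFrame:
    """Tabular summary: per predictor, scale and origin, is the fitted
    relationship positive, negative or not significant."""
    rows = []
    for scale, result in run.scales.items():
        for r in result.contrasts.itertuples():
            for origin, slope, p in (
                ("native", r.slope_native, r.p_native),
                ("introduced", r.slope_introduced, r.p_introduced),
            ):
                verdict = "ns" if p >= alpha else ("positive" if slope > 0 else "negative")
                rows.append(
                    {"scale": scale, "predictor": r.predictor, "origin": origin,
                     "direction": verdict, "slope": slope, "p_value": p,
                     "differs_by_origin": bool(
                         r.interacted and r.p_difference < alpha
                     )}
                )
    return pd.DataFrame(rows)
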