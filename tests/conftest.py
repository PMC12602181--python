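"""Shared fixtures: tiny hand-built tables and one cached synthetic dataset."""

import numpy as np
import pandas as pd
import pytest

from dissimscale.data_model import TRAIT_NAMES
from dissimscale.trait_space import TraitSpace


@pytest.fixture
def toy_cover() -> pd.DataFrame:
    """Two plots, two years, four species."""
    rows = [
        ("F1", "T1", "P1", 2000, "sp_a", 30.0),
        ("F1", "T1", "P1", 2000, "sp_b", 10.0),
        ("F1", "T1", "P1", 2000, "sp_c", 5.0),
        ("F1", "T1", "P2", 2000, "sp_a", 20.0),
        ("F1", "T1", "P2", 2000, "sp_d", 15.0),
        ("F1", "T1", "P1", 2006, "sp_a", 25.0),
        ("F1", "T1", "P1", 2006, "sp_b", 40.0),
    ]
    return pd.DataFrame(rows, columns=["field", "transect", "plot", "year", "species", "cover"])


@pytest.fixture
def toy_traits() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    species = ["sp_a", "sp_b", "sp_c", "sp_d", "sp_e"]
    df = pd.DataFrame(
        rng.uniform(1, 10, size=(5, 7)), index=pd.Index(species, name="species"),
        columns=list(TRAIT_NAMES),
    )
    df.loc["sp_c", "seed_mass"] = np.nan  # sp_c is trait-incomplete
    return df


def make_random_community(rng, n_members, n_traits=7):
    """Random coordinates, trait values, covers and a random metric-ish
    distance matrix for one community (test helper)."""
    species = [f"s{i}" for i in range(n_members)]
    coords = rng.normal(size=(n_members, 3))
    traits = pd.DataFrame(
        rng.normal(size=(n_members, n_traits)), index=species, columns=list(TRAIT_NAMES)
    )
    covers = rng.uniform(0.5, 60.0, size=n_members)
    pts = rng.normal(size=(n_members, 4))
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)  # metric by construction
    return species, coords, traits, covers, D


def make_trait_space(species, coords) -> TraitSpace:
    axes = ["axis_1", "axis_2", "axis_3"]
    return TraitSpace(
        scores=pd.DataFrame(np.asarray(coords), index=species, columns=axes),
        loadings=pd.DataFrame(np.zeros((7, 3)), index=list(TRAIT_NAMES), columns=axes),
        varexp=np.array([0.5, 0.3, 0.2]),
        varexp_all=np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0, 0.0]),
        trait_means=pd.Series(0.0, index=list(TRAIT_NAMES)),
        trait_sds=pd.Series(1.0, index=list(TRAIT_NAMES)),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One cached reduced-size synthetic dataset (limiting-similarity on)."""
    from dissimscale.synthetic_data import SimulationParams, reduced_design, simulate_dataset

    return simulate_dataset(
        SimulationParams(n_species=30, gamma_e=0.3, gamma_l=0.3, seed=123),
        design=reduced_design(n_fields=4),
    )
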