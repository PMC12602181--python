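"""Multivariate trait space and phylogenetic signal.

Traits are z-standardized (sample SD, n-1) and projected onto principal
component axes; the first three axes define the functional volume in which
multivariate dissimilarities are measured. Per-trait phylogenetic signal can
be quantified with Blomberg's K or Pagel's lambda, each with a one-sided
permutation p-value obtained by shuffling trait values across tips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model import phylogenetic_covariance
from .errors import DataValidationError, DegenerateInputError

logger = logging.getLogger(__name__)

#: Traits that are sizes or masses and are log-transformed when the optional
#: pre-scaling log transform is enabled.
LOG_TRAITS = ("height", "leaf_area", "leaf_fresh_mass", "leaf_dry_mass", "seed_mass")


# ---------------------------------------------------------------------------
# standardization and PCA
# ---------------------------------------------------------------------------

def standardize_traits(
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-scale each trait column (mean 0, sample SD 1).

    Returns the scaled matrix and the means/SDs used, so the same scaling can
    be re-applied to new species. Raises :class:`DegenerateInputError` naming
    the trait if any column has zero variance.
    """
    if traits.isna().any().any():
        raise DataValidationError("standardize_traits requires trait-complete input")
    if len(traits) < 2:
        raise DegenerateInputError("need at least 2 species to standardize traits")
    means = traits.mean()
    sds = traits.std(ddof=1)
    zero = sds.index[sds == 0]
    if len(zero):
        raise DegenerateInputError(f"trait {zero[0]!r} has zero variance")
    scaled = (traits - means) / sds
    return scaled, means, sds


@dataclass
class TraitSpace:
    """Species coordinates on the retained principal axes of trait space.

    ``varexp_all`` holds the variance-explained fraction of every axis (they
    sum to one); ``scores``/``loadings`` keep only the retained axes.
    """

    scores: pd.DataFrame  # species x axis_1..axis_k
    loadings: pd.DataFrame  # trait x axis_1..axis_k
    varexp: np.ndarray  # retained axes
    varexp_all: np.ndarray  # all axes
    trait_means: pd.Series
    trait_sds: pd.Series

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    @property
    def axis_columns(self) -> list[str]:
        return list(self.scores.columns)

    def coordinates(self, species) -> pd.DataFrame:
        """Axis scores for the requested species (NaN rows for species the
        space was not fitted on)."""
        return self.scores.reindex(species)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scores.rename_axis("species").to_csv(directory / "trait_space_scores.csv")
        meta = {
            "loadings": {c: self.loadings[c].to_dict() for c in self.loadings.columns},
            "varexp": self.varexp.tolist(),
            "varexp_all": self.varexp_all.tolist(),
            "trait_means": self.trait_means.to_dict(),
            "trait_sds": self.trait_sds.to_dict(),
        }
        (directory / "trait_space_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TraitSpace":
        directory = Path(directory)
        scores = pd.read_csv(directory / "trait_space_scores.csv", index_col="species")
        scores.index = scores.index.astype(str)
        meta = json.loads((directory / "trait_space_meta.json").read_text())
        loadings = pd.DataFrame(meta["loadings"])
        return cls(
            scores=scores,
            loadings=loadings,
            varexp=np.asarray(meta["varexp"]),
            varexp_all=np.asarray(meta["varexp_all"]),
            trait_means=pd.Series(meta["trait_means"]),
            trait_sds=pd.Series(meta["trait_sds"]),
        )


def build_trait_space(
    traits: pd.DataFrame,
    n_axes: int = 3,
    log_transform: bool = False,
) -> TraitSpace:
    """Fit the PCA trait space on trait-complete species.

    Rows with any missing trait are dropped (those species receive no
    functional metrics downstream). Axis signs are fixed so that each axis'
    largest-magnitude loading is positive, making output reproducible across
    linear-algebra backends.
    """
    complete = traits.dropna()
    n_dropped = len(traits) - len(complete)
    if n_dropped:
        logger.info("build_trait_space: dropped %d trait-incomplete species", n_dropped)
    if log_transform:
        complete = complete.copy()
        for t in LOG_TRAITS:
            if t in complete.columns:
                if (complete[t] <= 0).any():
                    raise DataValidationError(f"log transform of non-positive trait {t!r}")
                complete[t] = np.log(complete[t])
    n_traits = complete.shape[1]
    if n_axes > n_traits:
        raise DataValidationError(f"cannot retain {n_axes} axes from {n_traits} traits")
    if len(complete) <= n_axes:
        raise DataValidationError(
            f"need more than {n_axes} species to fit a {n_axes}-axis space; got {len(complete)}"
        )
    scaled, means, sds = standardize_traits(complete)

    pca = PCA(n_components=n_traits)
    scores = pca.fit_transform(scaled.to_numpy())
    loadings = pca.components_.T  # trait x axis
    # sign convention: largest-|loading| entry of each axis is positive
    for j in range(n_traits):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    varexp_all = pca.explained_variance_ratio_

    axis_names = [f"axis_{j + 1}" for j in range(n_axes)]
    return TraitSpace(
        scores=pd.DataFrame(scores[:, :n_axes], index=complete.index, columns=axis_names),
        loadings=pd.DataFrame(loadings[:, :n_axes], index=complete.columns, columns=axis_names),
        varexp=varexp_all[:n_axes].copy(),
        varexp_all=varexp_all,
        trait_means=means,
        trait_sds=sds,
    )


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    trait: str
    statistic: str  # "K" or "lambda"
    estimate: float
    p_value: float
    n_perm: int


def _check_signal_inputs(x: np.ndarray, V: np.ndarray) -> None:
    if np.var(x) == 0:
        raise DegenerateInputError("trait has zero variance across tips")
    off = V - np.diag(np.diag(V))
    if np.allclose(off, 0):
        raise DegenerateInputError("star phylogeny: phylogenetic signal is undefined")


def blomberg_k(x: np.ndarray, V: np.ndarray) -> float:
    """Blomberg's K: observed MSE0/MSE ratio relative to its Brownian-motion
    expectation on the tree.

    MSE0 is the mean squared deviation of tip values from the phylogenetic
    (GLS) mean; MSE is the same deviation in the metric of the tree
    covariance V. Under Brownian evolution E[K] = 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    denom = one @ Vinv @ one
    a = (one @ Vinv @ x) / denom
    r = x - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Vinv @ r) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def _lambda_loglik(x: np.ndarray, V: np.ndarray, lam: float) -> float:
    n = len(x)
    Vl = lam * V + (1 - lam) * np.diag(np.diag(V))
    sign, logdet = np.linalg.slogdet(Vl)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(Vl)
    one = np.ones(n)
    a = (one @ Vinv @ x) / (one @ Vinv @ one)
    r = x - a
    sigma2 = (r @ Vinv @ r) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda(x: np.ndarray, V: np.ndarray, grid_size: int = 101) -> float:
    """Profile-likelihood estimate of Pagel's lambda on a [0, 1] grid.

    Lambda rescales the off-diagonal (shared-history) entries of the tree
    covariance; 0 erases phylogenetic structure, 1 keeps pure Brownian.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    lls = [_lambda_loglik(x, V, lam) for lam in grid]
    return float(grid[int(np.argmax(lls))])


def phylo_signal(
    trait: pd.Series,
    tree: dendropy.Tree,
    statistic: str = "K",
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Phylogenetic signal of one trait with a permutation p-value.

    ``trait`` must provide a value for every tip of ``tree``. The p-value is
    the (+1-smoothed) fraction of tip permutations whose statistic is at
    least the observed one (one-sided: stronger-than-random signal).
    """
    if n_perm < 99:
        raise DataValidationError("n_perm must be at least 99")
    species, V = phylogenetic_covariance(tree)
    missing = [s for s in species if s not in trait.index]
    if missing:
        raise DataValidationError(f"trait values missing for tips {missing[:5]}")
    x = trait.reindex(species).to_numpy(dtype=float)
    _check_signal_inputs(x, V)

    if statistic == "K":
        stat = lambda v: blomberg_k(v, V)  # noqa: E731
    elif statistic == "lambda":
        stat = lambda v: pagel_lambda(v, V, grid_size=21)  # noqa: E731
    else:
        raise DataValidationError(f"unknown signal statistic {statistic!r}")

    observed = stat(x)
    if statistic == "lambda":  # report fine-grid estimate, permute on coarse grid
        observed_report = pagel_lambda(x, V)
    else:
        observed_report = observed

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = stat(rng.permutation(x))
        if perm >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return SignalResult(
        trait=str(trait.name), statistic=statistic, estimate=observed_report,
        p_value=p, n_perm=n_perm,
    )


def signal_table(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    statistic: str = "K",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Phylogenetic signal of every trait column, as one tidy table."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for trait_seed, name in zip(ss.spawn(len(traits.columns)), traits.columns):
        res = phylo_signal(
            traits[name], tree, statistic=statistic, n_perm=n_perm,
            seed=int(trait_seed.generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {"trait": name, "statistic": res.statistic, "estimate": res.estimate,
             "p_value": res.p_value}
        )
    return pd.DataFrame(rows)
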