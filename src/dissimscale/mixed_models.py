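"""Linear mixed models of species abundance on dissimilarity and covariates.

The response is log(percent cover + 1). Fixed effects are the dissimilarity
metrics (phylogenetic distance and ranked multivariate functional
dissimilarity are always included), optional univariate trait
dissimilarities, environmental and temporal covariates, and their
interactions with species origin (native/introduced). Random intercepts are
crossed: species, survey year, plot-within-transect and
transect-within-field at neighborhood scale; species, year and
transect-within-field at site scale.

Estimation uses residual maximum likelihood (REML) for reported fits and
plain maximum likelihood when comparing fixed-effect structures with
information criteria (AICc/BIC are not comparable across fixed effects under
REML). Inference on coefficients is large-sample Wald (normal); variance
explained is reported as marginal and conditional R-squared in the
variance-components (Nakagawa–Schielzeth) formulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConvergenceError, DataValidationError

logger = logging.getLogger(__name__)

#: The two dissimilarity terms at the core of the analysis; every candidate
#: model must contain them.
CORE_TERMS = ("phylo_dist", "ranked_multi")

RANDOM_FACTORS = {
    "neighborhood": ("species", "year", "plot_id", "transect_id"),
    "site": ("species", "year", "transect_id"),
}


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def transform_response(cover) -> np.ndarray:
    """log(percent cover + 1): compresses the right tail and keeps zeros."""
    cover = np.asarray(cover, dtype=float)
    if (cover < 0).any():
        raise DataValidationError("negative cover in response")
    return np.log(cover + 1.0)


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataValidationError(f"cannot z-scale constant column {x.name!r}")
    return (x - x.mean()) / sd


def apply_transform(x: pd.Series, how: str) -> pd.Series:
    """Apply one named transform: identity, z, log, log_z, log1p, log1p_z."""
    if how in ("identity", None, ""):
        return x
    if how == "z":
        return _zscore(x)
    if how in ("log", "log_z"):
        if (x <= 0).any():
            raise DataValidationError(f"log transform of non-positive values in {x.name!r}")
        out = np.log(x)
        return _zscore(out) if how == "log_z" else out
    if how in ("log1p", "log1p_z"):
        if (x < 0).any():
            raise DataValidationError(f"log1p transform of negative values in {x.name!r}")
        out = np.log1p(x)
        return _zscore(out) if how == "log1p_z" else out
    raise DataValidationError(f"unknown transform {how!r}")


def prepare_predictors(
    df: pd.DataFrame, transforms: Mapping[str, str]
) -> pd.DataFrame:
    """Return a copy with the named columns transformed; rows with missing
    values in any transformed column are dropped first (logged count)."""
    cols = [c for c in transforms if c in df.columns]
    keep = df[cols].notna().all(axis=1) if cols else pd.Series(True, index=df.index)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("prepare_predictors: dropped %d rows with missing predictors", n_drop)
    out = df[keep].copy()
    for c in cols:
        out[c] = apply_transform(out[c], transforms[c])
    return out


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    flagged_vif: list[str]
    r_threshold: float
    vif_threshold: float


def _vif_one(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def collinearity_screen(
    X: pd.DataFrame, r_threshold: float = 0.7, vif_threshold: float = 5.0
) -> CollinearityReport:
    """Pairwise Pearson correlations and variance inflation factors.

    VIF_j = 1 / (1 - R²_j) from regressing predictor j on all the others;
    exactly collinear predictors are reported with infinite VIF rather than
    raising.
    """
    if X.shape[1] < 2:
        raise DataValidationError("collinearity screen needs at least 2 predictors")
    if len(X) <= X.shape[1]:
        raise DataValidationError("collinearity screen needs n > p rows")
    corr = X.corr()
    arr = X.to_numpy(dtype=float)
    vif = pd.Series({c: _vif_one(arr, j) for j, c in enumerate(X.columns)})
    pairs = []
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if abs(r) > r_threshold:
                pairs.append((cols[i], cols[j], float(r)))
    flagged_vif = [c for c in cols if vif[c] > vif_threshold]
    return CollinearityReport(corr, vif, pairs, flagged_vif, r_threshold, vif_threshold)


def drop_collinear(
    X: pd.DataFrame,
    r_threshold: float = 0.7,
    vif_threshold: float = 5.0,
    protected: Sequence[str] = CORE_TERMS,
) -> tuple[list[str], CollinearityReport]:
    """Iteratively remove collinear predictors.

    Of any flagged pair, the later-listed predictor is dropped; then the
    predictor with the highest VIF above threshold is dropped, repeatedly.
    ``protected`` predictors (by default the two core dissimilarity terms)
    are never removed. Returns the kept column list and the final report.
    """
    kept = list(X.columns)
    protected = set(protected)
    while len(kept) >= 2:
        report = collinearity_screen(X[kept], r_threshold, vif_threshold)
        drop = None
        for a, b, _r in report.flagged_pairs:
            for candidate in (b, a):  # prefer dropping the later-listed
                if candidate not in protected:
                    drop = candidate
                    break
            if drop:
                break
        if drop is None:
            candidates = [c for c in report.flagged_vif if c not in protected]
            if candidates:
                drop = max(candidates, key=lambda c: (report.vif[c], kept.index(c)))
        if drop is None:
            return kept, report
        logger.info("drop_collinear: removing %r", drop)
        kept.remove(drop)
    if len(kept) >= 2:
        return kept, collinearity_screen(X[kept], r_threshold, vif_threshold)
    return kept, None


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure.

    ``fixed`` lists predictor columns; ``interactions`` lists the subset that
    is additionally interacted with species origin (which adds the origin
    main effect). The two core dissimilarity terms must always be present.
    """

    name: str
    fixed: tuple[str, ...]
    interactions: tuple[str, ...] = ()

    def __post_init__(self):
        missing = [t for t in CORE_TERMS if t not in self.fixed]
        if missing:
            raise DataValidationError(
                f"model {self.name!r} is missing core dissimilarity terms {missing}"
            )
        extra = [t for t in self.interactions if t not in self.fixed]
        if extra:
            raise DataValidationError(f"interaction terms not in fixed terms: {extra}")

    @property
    def design_columns(self) -> list[str]:
        cols = list(self.fixed)
        if self.interactions:
            cols.append("introduced")
            cols += [interaction_name(p) for p in self.interactions]
        return cols

    def n_fixed_coefficients(self) -> int:
        return 1 + len(self.design_columns)  # + intercept


def interaction_name(predictor: str) -> str:
    return f"{predictor}_x_introduced"


def make_unit_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Attach globally unique transect and plot labels (nesting made
    explicit: transect within field, plot within transect)."""
    out = df.copy()
    out["transect_id"] = out["field"].astype(str) + ":" + out["transect"].astype(str)
    if "plot" in out.columns:
        out["plot_id"] = out["transect_id"] + ":" + out["plot"].astype(str)
    return out


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    transforms: Mapping[str, str] | None = None,
    scale: str = "neighborhood",
) -> pd.DataFrame:
    """Model-ready table: response ``y``, transformed predictors, origin
    dummy, product columns for the origin interactions, and random-factor
    labels. Rows with any missing required variable are dropped."""
    factors = RANDOM_FACTORS[scale]
    work = make_unit_labels(records)
    needed = set(spec.fixed) | {"cover", "origin_binary"} | set(factors)
    missing_cols = [c for c in needed if c not in work.columns]
    if missing_cols:
        raise DataValidationError(f"design is missing columns {sorted(missing_cols)}")
    keep = work[list(spec.fixed) + ["cover"]].notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("build_design: dropped %d rows with missing values", n_drop)
    work = work[keep].copy()

    if transforms:
        for c, how in transforms.items():
            if c in spec.fixed:
                work[c] = apply_transform(work[c], how)
    work["y"] = transform_response(work["cover"])
    work["introduced"] = (work["origin_binary"] == "introduced").astype(float)
    for p in spec.interactions:
        work[interaction_name(p)] = work[p] * work["introduced"]
    cols = ["y"] + spec.design_columns + list(factors)
    return work[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Fitted mixed (or degenerate fixed-effects-only) model."""

    spec: ModelSpec
    scale: str
    reml: bool
    params: pd.Series
    bse: pd.Series
    cov_fe: pd.DataFrame
    vcomp: dict[str, float]
    sigma2: float
    llf: float
    n: int
    var_fixed: float
    converged: bool
    singular: bool = False
    method: str = "lmm"
    factors: tuple[str, ...] = field(default_factory=tuple)

    @property
    def k(self) -> int:
        """Parameter count for information criteria: fixed coefficients plus
        variance components plus the residual variance."""
        return len(self.params) + len(self.vcomp) + 1

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def wald_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (
            float(self.params[term] - z * self.bse[term]),
            float(self.params[term] + z * self.bse[term]),
        )

    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)

    def bic(self) -> float:
        return bic(self.llf, self.k, self.n)

    def r2(self) -> tuple[float, float]:
        return r2_components(self.var_fixed, sum(self.vcomp.values()), self.sigma2)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p_value": self.pvalues}
        ).rename_axis("term").reset_index()


def fit_lmm(
    design: pd.DataFrame,
    spec: ModelSpec,
    scale: str = "neighborhood",
    reml: bool = True,
) -> LMMFit:
    """Fit the mixed model with crossed random intercepts.

    Random factors with fewer than two observed levels are dropped (with all
    factors collapsed the model degenerates to ordinary least squares, which
    is fit directly). Non-convergence raises :class:`ConvergenceError`;
    variance components estimated at (near) zero only set the ``singular``
    flag.
    """
    terms = spec.design_columns
    factors = tuple(
        f for f in RANDOM_FACTORS[scale] if f in design.columns and design[f].nunique() >= 2
    )
    dropped = set(RANDOM_FACTORS[scale]) - set(factors)
    if dropped:
        logger.warning("fit_lmm: random factors with < 2 levels dropped: %s", sorted(dropped))

    X = sm.add_constant(design[terms], has_constant="add").rename(
        columns={"const": "Intercept"}
    )
    y = design["y"].to_numpy(dtype=float)

    if not factors:  # degenerate limit: ordinary least squares
        ols = sm.OLS(y, X).fit()
        resid_var = float(ols.ssr / ols.df_resid)
        return LMMFit(
            spec=spec, scale=scale, reml=reml,
            params=ols.params, bse=ols.bse,
            cov_fe=pd.DataFrame(ols.cov_params(), index=X.columns, columns=X.columns),
            vcomp={}, sigma2=resid_var, llf=float(ols.llf), n=len(y),
            var_fixed=float(np.var(ols.fittedvalues)), converged=True, method="ols",
            factors=(),
        )

    vc_formula = {f: f"0 + C({f})" for f in factors}
    data = design.copy()
    formula = "y ~ " + " + ".join(terms) if terms else "y ~ 1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data=data, groups=np.ones(len(data)), vc_formula=vc_formula,
            re_formula="0",
        )
        res = None
        for opt in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=reml, method=opt, maxiter=500)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"mixed model failed: {exc}") from exc
            if res.converged:
                break
    if not res.converged:
        raise ConvergenceError(
            f"mixed model for {spec.name!r} did not converge "
            f"(gradient norm at exit; see statsmodels trace)"
        )

    fe_names = list(res.fe_params.index)
    vc_names = list(model.exog_vc.names)
    vcomp = {name: float(v) for name, v in zip(vc_names, res.vcomp)}
    singular = any(v < 1e-8 for v in vcomp.values())

    # Fixed-effect covariance as (X' V^-1 X)^-1 conditional on the estimated
    # variance components (GLS; Woodbury through the random-effect design),
    # which is stable where the optimizer Hessian at a boundary is not.
    Xmat = np.asarray(model.exog)
    Zparts, gparts = [], []
    for name, mats in zip(vc_names, model.exog_vc.mats):
        Zk = np.asarray(mats[0].todense() if hasattr(mats[0], "todense") else mats[0])
        if vcomp[name] > 1e-12:
            Zparts.append(Zk)
            gparts.append(np.full(Zk.shape[1], vcomp[name]))
    s2 = float(res.scale)
    if Zparts:
        Z = np.hstack(Zparts)
        g = np.concatenate(gparts)
        A = np.diag(s2 / g) + Z.T @ Z
        XtVinvX = (Xmat.T @ Xmat - Xmat.T @ Z @ np.linalg.solve(A, Z.T @ Xmat)) / s2
    else:
        XtVinvX = Xmat.T @ Xmat / s2
    cov_fe = pd.DataFrame(np.linalg.inv(XtVinvX), index=fe_names, columns=fe_names)
    bse_fe = pd.Series(np.sqrt(np.diag(cov_fe)), index=fe_names)

    exog = np.asarray(model.exog)
    fitted_fixed = exog @ res.fe_params.to_numpy()
    return LMMFit(
        spec=spec, scale=scale, reml=reml,
        params=res.fe_params.copy(), bse=bse_fe, cov_fe=cov_fe,
        vcomp=vcomp, sigma2=float(res.scale), llf=float(res.llf), n=len(y),
        var_fixed=float(np.var(fitted_fixed)), converged=True, singular=singular,
        factors=factors,
    )


# ---------------------------------------------------------------------------
# information criteria, R², contrasts, selection
# ---------------------------------------------------------------------------

def aicc(llf: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion:
    AICc = -2ll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise DataValidationError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bic(llf: float, k: int, n: int) -> float:
    """Bayesian information criterion: BIC = -2ll + k ln n."""
    return -2.0 * llf + k * np.log(n)


def r2_components(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R² from variance components.

    marginal = var_f / (var_f + var_r + var_e); conditional adds the summed
    random-intercept variances to the numerator.
    """
    total = var_fixed + var_random + var_resid
    return float(var_fixed / total), float((var_fixed + var_random) / total)


def origin_contrasts(fit: LMMFit) -> pd.DataFrame:
    """Per-origin slopes for every fixed predictor.

    For predictors interacted with origin: the native slope is the base
    coefficient, the introduced slope adds the interaction coefficient (SE
    propagated through the coefficient covariance), and the native-introduced
    difference is the Wald test on the interaction coefficient itself. A
    predictor without an interaction is reported as a common slope.
    """
    rows = []
    for p in fit.spec.fixed:
        b = float(fit.params[p])
        se = float(fit.bse[p])
        row = {"predictor": p, "slope_native": b, "se_native": se,
               "p_native": float(2 * stats.norm.sf(abs(b / se)))}
        iname = interaction_name(p)
        if p in fit.spec.interactions and iname in fit.params.index:
            bi = float(fit.params[iname])
            sei = float(fit.bse[iname])
            cov = float(fit.cov_fe.loc[p, iname])
            slope_int = b + bi
            se_int = float(np.sqrt(se**2 + sei**2 + 2 * cov))
            row.update(
                slope_introduced=slope_int, se_introduced=se_int,
                p_introduced=float(2 * stats.norm.sf(abs(slope_int / se_int))),
                difference=bi, se_difference=sei,
                p_difference=float(2 * stats.norm.sf(abs(bi / sei))),
                interacted=True,
            )
        else:
            row.update(
                slope_introduced=b, se_introduced=se, p_introduced=row["p_native"],
                difference=0.0, se_difference=np.nan, p_difference=np.nan,
                interacted=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SelectionResult:
    table: pd.DataFrame
    winner: ModelSpec
    winner_fit: LMMFit  # refit under REML


def select_model(
    records: pd.DataFrame,
    specs: Sequence[ModelSpec],
    transforms: Mapping[str, str] | None = None,
    scale: str = "neighborhood",
) -> SelectionResult:
    """Rank candidate fixed-effect structures by AICc (then BIC, then k).

    All candidates are fit by maximum likelihood on the common set of rows
    that are complete for the union of their predictors, so criteria are
    comparable; the winner is refit under REML.
    """
    if len(specs) < 1:
        raise DataValidationError("select_model needs at least one candidate")
    all_fixed, all_inter = [], []
    for s in specs:
        all_fixed += [t for t in s.fixed if t not in all_fixed]
        all_inter += [t for t in s.interactions if t not in all_inter]
    union = ModelSpec("union", tuple(all_fixed), tuple(all_inter))
    full_design = build_design(records, union, transforms, scale)

    rows, fits = [], {}
    for s in specs:
        cols = ["y"] + s.design_columns + list(RANDOM_FACTORS[scale])
        design = full_design[[c for c in cols if c in full_design.columns]]
        fit = fit_lmm(design, s, scale, reml=False)
        fits[s.name] = fit
        rows.append(
            {"model": s.name, "k": fit.k, "llf": fit.llf,
             "aicc": fit.aicc(), "bic": fit.bic(), "n": fit.n}
        )
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    order = table.sort_values(["aicc", "bic", "k"], kind="mergesort")
    winner_name = order.iloc[0]["model"]
    winner = next(s for s in specs if s.name == winner_name)

    cols = ["y"] + winner.design_columns + list(RANDOM_FACTORS[scale])
    design = full_design[[c for c in cols if c in full_design.columns]]
    winner_fit = fit_lmm(design, winner, scale, reml=True)
    return SelectionResult(table=table, winner=winner, winner_fit=winner_fit)
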