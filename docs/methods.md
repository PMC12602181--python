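# Methods

This note documents the models and procedures implemented in `dissimscale`,
the choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## The scientific question

Two classical hypotheses make opposite predictions about which colonizing
species (native or introduced) become abundant in a plant community. Under
*pre-adaptation* (environmental filtering), species similar or closely
related to the residents succeed because they share environmentally suitable
characteristics. Under *limiting similarity*, dissimilar or distantly
related species succeed because they escape competition. Because competition
between herbaceous individuals operates at sub-metre distances while
environmental heterogeneity emerges over tens of metres, the two signatures
are expected at different spatial grains. The package therefore measures
species-to-community dissimilarity at two nested scales — 0.5-m² plots
("neighborhood") and ~40-m² transects ("site") — and models abundance on
those dissimilarities at each scale separately.

## Dissimilarity metrics

For a target species *t* in a community with members *j* (covers *w_j*),
with 3-axis trait-space coordinates *z* and patristic distances *d*:

- **ranked multivariate** = ‖z_t − c‖ where c = Σ w_j z_j / Σ w_j over the
  *other* members (cover-weighted leave-one-out centroid);
- **pairwise multivariate** = mean_j ‖z_t − z_j‖;
- **ranked univariate (per trait x)** = x_t − Σ w_j x_j / Σ w_j (signed:
  positive means the species exceeds the community mean);
- **pairwise univariate** = mean_j |x_t − x_j|;
- **phylogenetic distance** = Σ w_j d(t, j) / Σ w_j.

Choices where the definitions are under-specified:

- **Leave-one-out everywhere.** Target exclusion is unambiguous only for the
  multivariate centroid; we apply it to the univariate means, pairwise sets
  and the phylogenetic mean for internal consistency
  (`MetricConfig(include_target=True)` restores inclusion).
- **Weighting of pairwise metrics.** The pairwise definitions say "the
  mean"; the phylogenetic one says cover-weighted. Defaults follow the
  letter of each: pairwise functional metrics unweighted, phylogenetic
  weighted; both switchable. Note the Jensen-type bound
  `pairwise_uni ≥ |ranked_uni|` holds only when both sides use the same
  weighting.
- **Eligibility.** Functional metrics use trait-complete co-occurring
  species; the phylogenetic metric uses tree-matched species. Raw covers are
  used as weights (weighted means are invariant to rescaling, so no
  renormalization is needed). A species with no eligible partner gets a
  missing value, never a zero: "dissimilarity to the rest of the community"
  is undefined for a singleton. Bare-ground and litter records are never
  community members.

## Trait space and phylogenetic signal

The seven traits (SLA, plant height, leaf area, LDMC, leaf fresh and dry
mass, seed mass) are z-standardized (sample SD, n−1) over trait-complete
species and projected onto principal components; the first three axes define
the functional volume. Axis signs are fixed so each axis' largest-magnitude
loading is positive, making output stable across linear-algebra backends.
An optional log transform of the mass/area traits before scaling is off by
default. Missing traits are not imputed; trait-incomplete species simply
receive no functional metrics.

Per-trait phylogenetic signal is offered as Blomberg's K (default) and
Pagel's λ (profile likelihood on a λ grid over the tree covariance), each
with a one-sided permutation p-value ((1 + exceedances)/(n_perm + 1)). K is
the ratio of the observed MSE₀/MSE (deviations from the phylogenetic GLS
mean, in the ordinary versus tree metric) to its Brownian expectation on the
tree, so E[K] ≈ 1 under Brownian evolution. K is cross-checked against the
R `picante` implementation in the test suite. Both statistics are undefined
on a star tree or a constant trait and error accordingly.

## Temporal covariates

*Minimum colonization time* of a species in a unit is observation year minus
the earliest survey year in which the species was recorded there — a lower
bound on presence duration. By default the clock keeps running across local
disappearances (a gap does not reset it); `reset_on_gap=True` restarts it at
the first year of the current uninterrupted run of surveys. Site-scale
colonization time is recomputed from the pooled transect composition, so it
can only equal or exceed each plot's value. *Succession time* is survey year
minus field abandonment year; plot-years surveyed before abandonment are
dropped as undefined.

## Site-scale aggregation

Site cover of a species is its mean cover across the plots surveyed in that
transect-year, with absences contributing zero. The denominator is the
number of plots actually surveyed that year, not the nominal 25, so
incompletely surveyed years are not deflated. Soil and light variables are
averaged the same way (missing plot values skipped); burn treatment and
abandonment year are site-scale attributes and must be homogeneous within a
transect.

## Mixed models

The response is log(percent cover + 1). Univariate dissimilarities are
z-scaled; skewed positive covariates (soil N, organic matter, the two time
variables) are log- (or log1p-) transformed then z-scaled; the transform map
is configurable. Random intercepts are crossed: species, survey year,
plot-in-transect and transect-in-field at neighborhood scale; species, year
and transect-in-field at site scale. Fitting uses statsmodels `MixedLM`
with variance components over a single grouping of all rows; the optimizer
chain is L-BFGS, then Powell, then CG (L-BFGS sometimes exits on a loose
gradient for variance-component-only models where Powell converges).

- **Inference.** Large-sample Wald (normal) tests and intervals, not
  Satterthwaite — a documented deviation from lme4/emmeans defaults. The
  fixed-effect covariance is computed analytically as (X′V⁻¹X)⁻¹ at the
  estimated variance components (the GLS covariance, as lme4 reports),
  which is stable where the optimizer Hessian at a variance boundary is not.
- **Selection.** Candidate fixed-effect structures — from the core model
  (phylogenetic distance + ranked multivariate dissimilarity, which every
  candidate must contain) up to all covariates with origin interactions —
  are compared by AICc (ties: BIC, then parameter count) under maximum
  likelihood on a common row set; the winner is refit under REML.
  Information criteria count k = fixed coefficients + variance components +
  residual. Soil carbon is not offered as a candidate term (it tracks soil
  nitrogen too closely).
- **Collinearity.** Before selection, predictors are screened by pairwise
  Pearson correlation and VIF (1/(1−R²) from regressing each on the rest);
  of a flagged pair (|r| > 0.7 or VIF > 5, configurable) the later-listed
  predictor is dropped; the core terms are never dropped. Exact collinearity
  reports an infinite VIF rather than crashing.
- **R².** Marginal = var(Xβ̂)/(var(Xβ̂) + Σ variance components + residual);
  conditional adds the variance components to the numerator
  (variance-components formulation).
- **Origin contrasts.** With origin interactions, the native slope is the
  base coefficient, the introduced slope adds the interaction coefficient
  (SE propagated through the coefficient covariance), and the
  native-introduced difference is the Wald test on the interaction term.
- **Degenerate limits.** Random factors with fewer than two observed levels
  are dropped; with none left the model is fit by OLS, so a fully collapsed
  random structure reduces exactly to least squares. Variance components
  estimated at (near) zero set a `singular` flag, not an error.

## Synthetic data

The generator emulates the survey frame of a long-term old-field succession
experiment: 26 fields abandoned in a staggered sequence (1927–2015), four
39-m transects per field (six in two fields), 25 plots of 0.5 m × 1 m every
1.5 m starting at 1.5 m, eight surveys between 1983 and 2016, and burning
of half of each field from 2006. Exact survey years are not part of the
frame, only their number and span; the default is (1983, 1988, 1993, 1997,
2002, 2007, 2011, 2016). Burning is assigned to alternate transects so the
treatment is homogeneous at site scale. The phylogeny is a pure-birth tree;
traits mix a Brownian realization on that tree with independent noise,
√λ·BM + √(1−λ)·N(0,1), so λ spans no signal to pure Brownian (default 0.3,
weak signal). The environment is a hierarchical gradient (field + transect +
plot effects, SDs 1.0/0.5/0.25) with soil and light covariates as monotone
transforms plus noise.

Covers come from a minimal assembly model that encodes the two hypotheses
as opposing terms in expected log cover:

    E[log cover] = α − γ_E (x_s − E_p)² + γ_L d_s

with lognormal noise (SD 0.7), where x_s is the species' first-axis score,
E_p the plot's gradient position, and d_s the species' ranked multivariate
dissimilarity to the plot's previous-survey community (the regional pool at
equal covers before the first survey). Species below a presence threshold
(3% cover) are absent, and plot richness is capped at the 15 most abundant
species (recruitment limitation). α = ln 5 puts typical covers at a few to
tens of percent, giving ~10–15 species per 0.5-m² plot. Filtering acts on
axis 1 only so the ground truth stays one-dimensional and interpretable.
Everything is deterministic under the seed.

This generator is a study in miniature, not a demographic model: there is
no dispersal, no individual-level birth–death, no litter dynamics, no
trait–origin correlation unless requested, and the assembly model is the
package's own construction. Passing recovery tests therefore show that the
pipeline detects each process when it is the sole generative force at the
scale where it operates — they do not show that real grassland dynamics
follow this model.

## Validation experiments and problem sizes

The `experiments` module runs the recovery and calibration suites at a
reduced survey size chosen as this package's standard desk-scale
configuration: 10 fields × 2 transects × 3 plots, 3 surveys (1994, 2005,
2016), 50 species, 20 replicates per scenario.

- *Limiting similarity* (γ_L = 0.5, γ_E = 0): the neighborhood-scale slope
  of log cover on ranked multivariate dissimilarity is significantly
  positive in ≥ 80% of replicates.
- *Environmental filtering* (γ_E = 0.5, γ_L = 0): the site-scale slope is
  significantly negative in ≥ 80% of replicates.
- *Neutral* (both zero): the slope is non-significant in ≥ 90% of
  replicates (type-I control at α = 0.05).
- *Signal calibration*: Brownian traits on 100-tip trees give mean K in
  [0.7, 1.3]; tip-permuted traits give mean K < 0.5 with non-significant
  permutation p in most replicates.
- *Mixed-model sanity*: with zero simulated random variance the fitted
  coefficients match OLS to 10⁻³ (at n = 10000; the residual gap is the
  boundary variance estimate, which shrinks with n); known coefficients
  fall inside their 95% Wald intervals in ≥ 17/20 seeded runs; null Wald
  p-values pass a Kolmogorov–Smirnov uniformity test.

`scripts/acceptance.py` re-runs all of the above from scratch and writes
the resulting rates and errors to JSON.

## Known limitations

- Wald inference is anticonservative in small samples relative to
  Satterthwaite or parametric-bootstrap alternatives.
- The GLS fixed-effect covariance conditions on the estimated variance
  components and ignores their sampling uncertainty (as does lme4).
- Pagel's λ uses a grid profile likelihood (resolution 0.01 for the
  estimate, 0.05 within permutations), not a continuous optimizer.
- The univariate metrics use raw trait values, so their scale depends on
  the trait; downstream z-scaling absorbs this for modelling but the raw
  records are not comparable across traits.
- Site-scale aggregation infers "plots surveyed" from the presence of any
  cover record; a surveyed plot that was entirely bare would need the
  explicit `plots_surveyed` argument.
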