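# dissimscale

Scale-dependent functional and phylogenetic dissimilarity analysis for
plant community assembly and invasion ecology.

## The problem

When a species colonizes a community, does it do better by *resembling* the
residents (pre-adaptation: it passes the same environmental filter) or by
*differing* from them (limiting similarity: it escapes competition)? The
two processes leave opposite signatures in the relationship between a
species' abundance and its dissimilarity to the rest of its community — and
they operate at different spatial grains: competition among herbs at
sub-metre neighborhoods, environmental filtering across tens of metres.

`dissimscale` implements the full analysis for long-term grassland survey
data. For every species in every community it computes, cover-weighted and
leave-one-out:

- **ranked multivariate dissimilarity** — Euclidean distance from the
  species to the community centroid in a 3-axis PCA trait space
  (competitive-hierarchy position);
- **pairwise multivariate dissimilarity** — mean trait-space distance to
  each co-occurring species (niche difference);
- **ranked and pairwise univariate dissimilarities** for each of seven
  traits (SLA, height, leaf area, LDMC, leaf fresh/dry mass, seed mass);
- **phylogenetic distance** — cover-weighted mean patristic distance to the
  co-occurring species.

It then models log(cover + 1) on these metrics — plus soil, light, burning
and colonization/succession-time covariates and their interactions with
species origin (native vs introduced) — with linear mixed models with
crossed random intercepts, at both the 0.5-m² plot ("neighborhood") and
~40-m² transect ("site") scale, with AICc/BIC model selection,
marginal/conditional R², and Wald contrasts between native and introduced
slopes. A synthetic survey generator with a known assembly model
(filtering strength γ_E vs limiting-similarity strength γ_L) makes every
stage testable end to end without field data. See `docs/methods.md` for
the model details and design choices.

## Worked example

Metric primitives operate on plain arrays — species coordinates (or trait
values) of the *other* community members plus their percent covers:

```python
>>> import numpy as np
>>> from dissimscale import weighted_centroid, ranked_multivariate, ranked_univariate
>>> weighted_centroid(np.array([[2., 0, 0], [8., 0, 0]]), np.array([30., 10.]))
array([3.5, 0. , 0. ])
>>> ranked_multivariate(np.zeros(3), np.array([[1., 0, 0], [0, 1., 0]]),
...                     np.array([50., 50.]))
0.7071067811865476
>>> ranked_univariate(4.0, np.array([2.0, 8.0]), np.array([30.0, 10.0]))
0.5
```

The first call is the cover-weighted centroid of two species at trait-space
positions 2 and 8 with covers 30% and 10% — the community sits at 3.5. The
second is a target species' distance to the centroid of two equally
abundant neighbors (√0.5). The third says the target's trait value of 4
exceeds the cover-weighted community mean (3.5) by +0.5: it ranks above its
community.

A full run — here on simulated data where only limiting similarity is
active (γ_L = 0.5, γ_E = 0) in a small survey of 6 fields and 40 species:

```python
from dissimscale import RunConfig, run_pipeline

cfg = RunConfig(
    seed=1, outdir="demo_run",
    simulation={"n_species": 40, "gamma_l": 0.5, "gamma_e": 0.0},
    design={"n_fields": 6, "n_transects_default": 2, "fields_with_extra": 0,
            "transect_length_m": 5.5, "survey_years": [1994, 2005, 2016],
            "abandonment_range": [1927, 1980]},
)
run = run_pipeline(cfg)
for scale, res in run.scales.items():
    r2m, r2c = res.fit.r2()
    print(f"{scale}: winner={res.selection.winner.name} "
          f"n={res.fit.n} R2m={r2m:.3f} R2c={r2c:.3f}")
```

prints

```
neighborhood: winner=core n=1620 R2m=0.036 R2c=0.068
site: winner=core n=1014 R2m=0.251 R2c=0.259
```

and `demo_run/summary.csv` holds the per-predictor verdicts; for the two
core dissimilarity terms:

```
       scale    predictor     origin direction    slope  p_value
neighborhood   phylo_dist     native        ns 0.010027 3.40e-01
neighborhood ranked_multi     native  positive 0.077195 6.49e-13
        site   phylo_dist     native        ns 0.011024 4.87e-01
        site ranked_multi     native  positive 0.285604 9.99e-73
```

Functionally distinct species reach higher cover (positive ranked-
dissimilarity slope) while phylogenetic distance shows nothing — exactly
the signature the generator was told to produce, since only the
limiting-similarity term was active and traits carry the signal. The run
directory also contains the per-scale dissimilarity tables, the AICc/BIC
selection table, fitted coefficients, native-vs-introduced contrasts, and
a `manifest.json` stamped with the seed and config hash; re-running the
same config reproduces every file byte for byte.

The same pipeline runs from files (`inputs:` instead of `simulation:` in
the config): a long-format cover CSV, a species × trait CSV, a species
origin CSV, a plot environment CSV, and a newick tree. A thin CLI wraps
the stages:

```sh
dissimscale simulate --seed 4 --n-species 50 --outdir data/
dissimscale run-all --config config.yaml
dissimscale summarize --rundir runs/latest
```

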