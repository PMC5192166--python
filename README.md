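# elevgrad

Multi-taxa analysis of elevational biodiversity gradients: how species
richness changes with altitude, which environmental hypotheses best explain
it, and how those answers shift as more taxonomic groups are pooled into a
single community.

The package is aimed at macroecologists working with site-by-species
matrices collected along mountain transects. It implements, as a tested and
reusable pipeline:

- **Richness estimation** — observed richness, the bias-corrected Chao1
  asymptotic estimator `S_obs + f1(f1−1)/(2(f2+1))`, the sample-coverage
  estimator `1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]`, and individual-based
  rarefaction to a common number of individuals (multivariate
  hypergeometric draws with a closed-form expectation
  `Σᵢ[1 − C(N−Nᵢ, n)/C(N, n)]`).
- **Mid-domain-effect (MDE) null model** — species elevational ranges are
  extracted, padded by 265 m at each end, and placed uniformly at random
  within hard domain boundaries (606–4,815 m by default) while conserving
  range lengths; the replicate-averaged per-site richness is the pattern
  expected from geometric constraints alone.
- **Pattern complexity** — each richness–elevation pattern is fitted by an
  ordinary linear regression (explained deviance `EDglm`) and a
  Gaussian-family penalized regression spline with basis dimension 5
  (`EDgam`, smoothing parameter by GCV); the statistic
  `complexity = (EDgam − EDglm)/EDgam` is 0 for a linear decline and
  approaches 1 for a strongly unimodal pattern.
- **Multi-model inference (MMI)** — all-subsets OLS over z-transformed
  predictors (temperature, precipitation, productivity, land area, the MDE
  prediction, plant richness), AIC/AICc, a ΔAIC < 4 best-fit set with
  renormalized Akaike weights, per-predictor variable importance (summed
  weights of models containing the predictor) and conditional
  model-averaged standardized betas.
- **Taxonomic upscaling** — for every subset of the available taxa, pooled
  richness, per-subset MDE predictions, shape statistics and MMI are
  recomputed and aggregated by coverage level (all 65,535 non-empty subsets
  of 16 taxa are enumerable; levels can also be subsampled).
- **Path analysis** — recursive observed-variable path models fitted
  equation-by-equation by OLS on standardized data, candidate structures
  pre-selected by per-equation AICc scans (ΔAICc < 3), ranked by a summed
  AICc, with direct/indirect effect decomposition along directed paths.
- **Synthetic mountain generator** — because comparable field data sets
  are typically available only on request, a fully seeded generator
  produces sites (temperature lapse ~0.56 °C/100 m, unimodal precipitation
  peaking near 2,200 m, productivity and area profiles) and multi-taxon
  communities with known drivers, so every stage is testable end to end.

## Worked example

```python
import elevgrad as eg
from elevgrad import upscale as up

sites = eg.generate_sites(seed=2)                      # 30 sites, 871-4550 m
communities = eg.staggered_temperature_assemblage(sites, n_taxa=8, seed=3)

row = communities[2].counts[4]                         # one taxon, one site
print(eg.chao1(row), eg.sample_coverage(row))

pooled = eg.pooled_richness(communities)
fit = eg.pattern_summary(pooled.to_numpy(float), sites.elevations)
print(f"EDglm={fit.ed_glm:.3f} EDgam={fit.ed_gam:.3f} "
      f"complexity={fit.complexity:.3f} -> {eg.classify_pattern(fit)}")

profile = eg.coverage_analysis(
    communities, sites, ("MAT", "MAP", "NPP", "area", "MDE"),
    mde_config=up.MDEConfig(reps=200), seed=4)
print(profile.level_summary().round(3))
print(eg.top_predictor_fractions(profile, "importance").round(2))
```

This prints, for the pooled 8-taxon community,

```
EDglm=0.750 EDgam=0.868 complexity=0.136 -> declining
```

— the community-level pattern is a near-linear decline (low complexity,
significant negative slope) even though individual taxa are unimodal —
and the coverage summaries

```
 level  median   q25   q75  n        level  MAT  MAP  NPP  area  MDE
     1   0.292 0.170 0.390  8            1 0.75 0.12  0.0   0.0 0.12
     2   0.215 0.096 0.404 28            2 0.71 0.11  0.0   0.0 0.18
     ...                                 ...
     7   0.129 0.121 0.164  8            7 1.00 0.00  0.0   0.0 0.00
     8   0.136 0.136 0.136  1            8 1.00 0.00  0.0   0.0 0.00
```

showing the two upscaling signatures: the median pattern complexity falls
as taxa are pooled (0.292 at single-taxon coverage to 0.136 at full
coverage), and mean annual temperature (MAT) becomes the top-ranked
predictor in every taxon combination at high coverage.

A command-line interface mirrors the library
(`elevgrad simulate | richness | rarefy | mde | shape | mmi | upscale |
standardize | paths | run`); `elevgrad run --seed 0 --out DIR` executes
the whole pipeline on the synthetic preset and writes every stage's
tables with seed and configuration metadata.

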