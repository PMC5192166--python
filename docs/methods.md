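# Methods

This note documents the models and procedures implemented in `elevgrad`,
the defaults they use, and the design choices made where several
reasonable options existed.

## The analysis pipeline

The pipeline addresses a standard macroecological question: along an
elevational gradient sampled at ~30 sites, which hypotheses — temperature,
water availability (precipitation), productivity, land area, geometric
constraints (the mid-domain effect), or plant richness as a resource for
animals — best explain species richness, and how does the answer change as
single taxonomic groups are pooled into an increasingly complete
community?  Stages: richness estimation → pattern shape → mid-domain-effect
null model → multi-model inference → combinatorial taxonomic upscaling →
sampling-effort standardization → path analysis.

## Richness estimation

Observed richness is the per-site count of species with positive
abundance.  For sampled (non-census) taxa three estimators correct for
incomplete sampling:

- **Chao1**, always in its bias-corrected form
  `S_obs + f1(f1−1)/(2(f2+1))` with `f1`/`f2` the singleton/doubleton
  counts.  The classic form `S_obs + f1²/(2 f2)` is undefined when a
  sample has no doubletons, which happens routinely in sparse arthropod
  samples; the bias-corrected form is finite everywhere, equals `S_obs`
  exactly when `f1 ≤ 1`, and never falls below the observed richness.
- **Sample coverage** (completeness), `1 − (f1/n)·[(n−1)f1/((n−1)f1+2f2)]`,
  the estimated share of individuals in the assemblage belonging to
  already-detected species.  Degenerate case: a single singleton
  (`n = 1`) gives coverage 0; no singletons give coverage 1.
- **Individual-based rarefaction** to a common total.  The unit is the
  taxon-wide pool of individuals — each individual keeps its site and
  species label, and a draw without replacement is a single multivariate
  hypergeometric sample over the site × species cells — because the
  standardization target (the smallest taxon total) is a taxon-level
  quantity.  A per-site mode is available behind a flag.  The Monte-Carlo
  mean is validated against the closed form
  `E[S] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]`.

Abundance-based estimators refuse presence/absence census taxa with an
explicit error rather than silently returning `S_obs`.

## Mid-domain-effect null model

Each species' elevational range is the interval between its lowest and
highest site of occurrence.  Because incomplete sampling underestimates
ranges (a species seen once has a zero-length range), every range is
padded by 265 m at both ends — half the largest elevational gap between
adjacent sampling elevations — and clipped to the domain, 606–4,815 m by
default.  Each of 200 replicates then places every augmented range at a
uniformly random feasible position inside the domain, conserving its
length: the midpoint is drawn from `[a + L/2, b − L/2]`.  A site is
covered when it lies in the closed placed interval.  The per-site mean
over replicates is the null richness profile.

Uniform feasible midpoints were chosen over permuting observed midpoints
(offered as `mode="permute"`) because they are the standard range-shuffle
Monte Carlo and admit an exact per-site expectation,

    E[S(x)] = Σ_species min(x − a, L, b − x, b − a − L) / (b − a − L),

used as the oracle in the tests (a range as long as the domain covers
every site with probability 1).

## Pattern shape and the complexity statistic

Two Gaussian-family models of richness on elevation are compared by
explained deviance `ED = 1 − RSS/TSS`:

- the **linear fit** (OLS), giving `EDglm`, the slope and its two-sided
  p-value;
- the **smooth fit**: a penalized natural cubic regression spline with
  basis dimension 5 (knots at elevation quantiles), second-derivative
  roughness penalty in the Green–Silverman form `K = Q R⁻¹ Qᵀ`, smoothing
  parameter chosen by GCV on a fixed log-spaced grid (λ from 1e−8 to 1e8,
  81 points, covariate rescaled to [0,1] and response to unit variance so
  the grid is scale-free), ties broken toward the smoother fit.

The penalty null space is exactly the linear functions, so for every λ
the smooth's RSS is bounded by the linear fit's RSS; `EDgam ≥ EDglm`
therefore holds by construction, and

    complexity = (EDgam − EDglm) / EDgam ∈ [0, 1]

is 0 for a linear pattern and near 1 for a symmetric unimodal one.  When
`EDgam < 1e−8` there is no signal to decompose and complexity is flagged
undefined.  The smooth's effective degrees of freedom are reported as
`tr(hat) − 1`, ranging from 1 (effectively linear) to basis_dim − 1; a
white-noise response shrinks toward edf ≈ 1.  Patterns are labelled
*declining* (complexity < 0.2 with a significantly negative slope),
*complex* (complexity ≥ 0.2), else *unresolved*.

Gaussian (not Poisson) families are used on richness counts throughout,
matching common practice for these comparisons.

## Multi-model inference

Predictors are z-transformed (sample s.d., n−1) so coefficients are
standardized betas.  All 2^p subsets are fitted by OLS with the
intercept always included; `AIC = n·ln(RSS/n) + 2k` and
`AICc = AIC + 2k(k+1)/(n−k−1)`, where k counts the intercept, slopes and
residual variance (intercept-only model: k = 2); the additive Gaussian
constant is dropped since it cancels in ΔAIC.  Models with
Δ < 4 form the best-fit set; their weights `∝ exp(−Δ/2)` are renormalized
to sum to 1.

- **Variable importance** is the summed weight of retained models
  containing the predictor.  It is computed over the Δ < 4 set (a
  full-model-space variant is available behind a flag).
- **Conditional model-averaged betas** average over the retained models
  containing the predictor, with weights renormalized within that subset.
  The unconditional standard error combines within-model variance and
  between-model spread, `se = Σ w'ᵢ √(varᵢ + (βᵢ − β̄)²)`, and
  significance is a two-sided normal test of `β̄/se` — a documented
  choice, since model-averaging practice does not fix the test.

A brute-force recomputation from first principles (independent code path
in the tests) reproduces AIC, weights, importance and conditional betas
exactly at small size.

## Taxonomic upscaling

For every non-empty subset of the analysed taxa (or a seeded uniform
subsample per coverage level): pooled richness is the per-site sum of the
member taxa's richness; the shape statistics are refitted; the MDE
prediction is recomputed from the pooled subset's own ranges using a
fixed per-subset RNG stream derived from (master seed, subset identity),
so results are independent of iteration order; and MMI is run with the
subset's pooled richness as response.  Plant analyses use minimum
temperature (MMT) and omit plant richness as a predictor; animal analyses
use mean annual temperature (MAT) and may include the full plant
community's richness (PSR) as a fixed predictor column.

Records are aggregated per coverage level into medians and interquartile
ranges of complexity, and into **top-rank fractions**: the share of
combinations in which each predictor ranks first by importance or by
|standardized beta|.  Ties on the primary criterion are resolved by the
secondary one.  This tie-break exists because importance saturates at 1:
whenever two predictors appear in every retained model they tie exactly
at 1.0, which is a positive-probability event, not a measure-zero
accident; the predictor with the larger |beta| is then ranked first.
Combinations still tied after both keys split credit equally.

Note that the number of non-empty subsets of 8 taxa is 2⁸ − 1 = 255 (and
65,535 for 16); enumeration is always over non-empty subsets.

### Effort standardization

To remove bias from unequal sampling intensity among taxa, each abundance
taxon is rarefied to a common number of individuals (default 83, or a
per-taxon mapping), richness is pooled, and MMI is rerun; over many
replicates (default 5,000; tests and the bundled pipeline use smaller,
documented sizes) the per-predictor mean and percentile 95% CI of
importance and beta are reported.

## Path analysis

Hypothesis: temperature and precipitation affect richness directly and
indirectly via productivity (and, for animals, via plant richness).
Candidate structures come from per-equation all-subsets OLS scans on
standardized data ranked by AICc; subsets with ΔAICc < 3 are retained and
their cross-product over equations defines the competing path models.
Each recursive model is fitted equation-by-equation by OLS — maximum
likelihood for recursive systems with uncorrelated errors, which is the
class considered here (no latent variables, no feedback) — giving
standardized path coefficients, per-equation R², and a model AICc from
the summed Gaussian log-likelihoods with K the total free parameter
count.  Edges present in competitive models but absent from the best one
are reported separately.  The total effect of one variable on another is
the direct coefficient plus the sum over directed paths of the products
of coefficients along each path.

## Synthetic mountain generator

The generator emulates a ~30-site transect on a large equatorial
mountain, so the pipeline can be exercised and validated without access
to restricted field data:

- **Sites** (defaults, all configurable): elevations quasi-evenly spaced
  with jitter over 871–4,550 m in six habitat bands of five sites; MAT
  declining at 0.56 °C/100 m from 25 °C at 700 m (noise s.d. 0.3 °C);
  MMT = MAT − 5 °C; MAP Gaussian-unimodal peaking at 3,000 mm yr⁻¹ near
  2,200 m (width 1,200 m, noise s.d. 100 mm); NPP a Miami-type
  minimum of temperature- and precipitation-limited production scaled to
  [0,1] (independent noise s.d. 0.06, reflecting satellite-index
  scatter); land area declining with elevation to a floor, with
  log-normal scatter (s.d. 0.35 on the log scale) because area within an
  elevational band is topographically rough, not a smooth function of
  elevation.  Missing MAT/MMT values can be imputed from an additive OLS
  model on elevation + habitat, mirroring how lost data loggers are
  handled in practice.
- **Taxa**: each species draws an elevational range (gamma widths around
  a taxon mean; midpoints uniform or Gaussian around a taxon optimum) and
  can occur only inside it.  Presence probabilities are scaled so that
  per-site expected richness equals `occupancy · pool · exp(Σ β z(cov))`;
  with `flatten_range_profile` the range-coverage profile is divided out
  (log-linear driver recovery is then exact), otherwise the profile shows
  through and Gaussian-midpoint taxa are unimodal.  Counts for present
  species are shifted-Poisson with mean `detection_rate` (≥ 1 individual
  given presence); census taxa record presence/absence.
- **Assemblages**: seeds for taxa are spawned from a master seed, and an
  optional shared site-quality random effect (log-normal, common to all
  taxa) models overdispersion that does not average out under pooling —
  without it, pooled synthetic richness is far less noisy than any real
  survey, and model selection resolves arbitrarily small systematic
  wiggles that field data could never support.

`staggered_temperature_assemblage` encodes the study condition used for
the upscaling analyses: taxon optima spaced evenly from 1,200 m below the
gradient base to 1,200 m above its top (lowland and alpine specialists
centred beyond the sampled transect are a real feature of mountain
systems; including them keeps the summed range-coverage profile roughly
flat across sites), species pools scaling linearly with the temperature
at each optimum (slope 0.6 per s.d.; warm-adapted clades are more
species-rich), a mild per-site temperature effect (0.1 on log richness),
and the shared site effect (s.d. 0.35).  Under these conditions single
taxa are unimodal (median complexity ≈ 0.2–0.4) while the pooled
community declines quasi-linearly with elevation and temperature carries
the inference — the qualitative behaviour the upscaling machinery is
designed to detect.  What passing these tests does **not** show: the
generator has no spatial autocorrelation, no temporal dynamics, no
interspecific interactions, and its noise is exchangeable across sites,
so conclusions about robustness to such structure require real data.

## Problem sizes and numerical choices

The bundled tests and the acceptance script use 30 sites, 8-taxon
assemblages (255 subsets, full enumeration), 200 MDE replicates per
subset, 200 replicates for driver-recovery rates and 100 simulations for
path-model ranking; rarefaction oracles run at 1,000 replicates and the
MDE oracle at 2,000.  These sizes give Monte-Carlo standard errors small
enough for 3-s.e. oracle comparisons while keeping a full run in the
tens of seconds.  Numerical guards: complexity clamps tiny negative
differences (EDgam − EDglm within 1e−8) to zero and errors on larger
violations; rank-deficient MMI subsets are excluded with a warning;
collinear path-model parents (|r| > 0.999) are rejected with the pair
named; degenerate rarefaction and coverage cases (n = 1) are handled
explicitly.

## Known limitations

- The GAM is a single-covariate penalized spline tailored to the
  richness–elevation use case, not a general additive-model framework.
- MMI assumes Gaussian errors on richness; counts are not modelled as
  Poisson, matching the convention adopted throughout.
- Path models are recursive with observed variables only; no fit indices
  beyond AICc and R² are computed.
- The upscaling driver recomputes MDE per subset but holds other
  predictors fixed; PSR, when used, is the full plant community's
  richness rather than being recomputed per animal subset (a flagged
  alternative would be straightforward but changes the question being
  asked).
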