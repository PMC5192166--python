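"""Synthetic tropical-mountain data generator.

Emulates the statistical structure of a multi-taxa elevational survey on a
large equatorial mountain: ~30 sites spanning the forest base to the alpine
zone, a quasi-linear temperature lapse, a unimodal precipitation profile
peaking in the montane forest belt, a productivity index limited by both
temperature and rainfall, and many taxonomic groups whose per-site richness
responds to chosen covariates with taxon-specific sign and strength while
individual species occupy unimodal (interval) elevational ranges.

Every stochastic quantity is driven by an explicit seed; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datatypes import SiteTable, TaxonCommunity, TaxonSpec, ValidationError

__all__ = [
    "generate_sites",
    "generate_taxon",
    "generate_assemblage",
    "impute_missing_climate",
    "staggered_temperature_assemblage",
    "kilimanjaro_preset",
]

# Default noise magnitudes (nothing hidden): s.d. of additive noise on each
# covariate, on the scale of that covariate.
DEFAULT_NOISE = {
    "elevation_jitter_frac": 0.25,  # fraction of the inter-site spacing
    "MAT_sd": 0.3,    # °C
    "MAP_sd": 100.0,  # mm yr⁻¹
    "NPP_sd": 0.06,   # index units (independent NDVI-like variation)
    "area_lognorm_sd": 0.35,  # log-scale s.d.: DEM-band area is topography-rough
}

#: MAT at the mountain base elevation (°C) and the base elevation itself.
BASE_TEMPERATURE_C = 25.0
BASE_ELEVATION_M = 700.0
#: Default MMT offset below MAT (°C).
MMT_OFFSET_C = 5.0
#: Width (m) of the Gaussian precipitation profile.
MAP_PROFILE_WIDTH_M = 1200.0
#: Peak precipitation (mm yr⁻¹) at the profile mode.
MAP_PEAK_MM = 3000.0

HABITAT_BANDS = (
    "savannah",
    "lower_montane_forest",
    "ocotea_forest",
    "podocarpus_forest",
    "erica_forest",
    "alpine_helichrysum",
)


def _npp_index(mat: np.ndarray, map_mm: np.ndarray) -> np.ndarray:
    # Miami-model style limitation: production limited by whichever of
    # temperature or precipitation is scarcer, normalised to [0, 1].
    npp_t = 1.0 / (1.0 + np.exp(1.315 - 0.119 * mat))
    npp_p = 1.0 - np.exp(-0.000664 * map_mm)
    return np.minimum(npp_t, npp_p)


def generate_sites(
    n_sites: int = 30,
    elev_min: float = 871.0,
    elev_max: float = 4550.0,
    lapse_rate: float = 0.56,
    map_peak_elev: float = 2200.0,
    seed: int | None = None,
    noise: dict | None = None,
    n_habitats: int = 6,
) -> SiteTable:
    """Generate a site table with covariates along an elevational gradient.

    Parameters
    ----------
    n_sites
        Number of study sites (≥ 2); quasi-evenly spaced with jitter.
    elev_min, elev_max
        Gradient extent in metres a.s.l.
    lapse_rate
        Temperature decline in °C per 100 m of elevation (must be > 0).
    map_peak_elev
        Elevation (m) of the unimodal precipitation maximum.
    seed
        Seed for all noise draws.
    noise
        Overrides for :data:`DEFAULT_NOISE` entries.
    n_habitats
        Number of equal elevational habitat bands used for labels.
    """
    if n_sites < 2:
        raise ValidationError("need at least 2 sites")
    if elev_min >= elev_max:
        raise ValidationError("elev_min must be below elev_max")
    if lapse_rate <= 0:
        raise ValidationError("lapse_rate must be positive (°C per 100 m)")
    cfg = dict(DEFAULT_NOISE)
    if noise:
        cfg.update(noise)
    rng = np.random.default_rng(seed)

    spacing = (elev_max - elev_min) / (n_sites - 1)
    elev = elev_min + spacing * np.arange(n_sites, dtype=float)
    jitter = rng.uniform(-1, 1, n_sites) * cfg["elevation_jitter_frac"] * spacing
    jitter[0] = abs(jitter[0])
    jitter[-1] = -abs(jitter[-1])
    elev = np.sort(elev + jitter)
    # enforce uniqueness under pathological jitter
    for i in range(1, n_sites):
        if elev[i] <= elev[i - 1]:
            elev[i] = elev[i - 1] + 1e-6

    mat = (
        BASE_TEMPERATURE_C
        - lapse_rate * (elev - BASE_ELEVATION_M) / 100.0
        + rng.normal(0.0, cfg["MAT_sd"], n_sites)
    )
    mmt = mat - MMT_OFFSET_C
    map_mm = MAP_PEAK_MM * np.exp(
        -(((elev - map_peak_elev) / MAP_PROFILE_WIDTH_M) ** 2)
    ) + rng.normal(0.0, cfg["MAP_sd"], n_sites)
    map_mm = np.clip(map_mm, 50.0, None)
    npp = np.clip(
        _npp_index(mat, map_mm) + rng.normal(0.0, cfg["NPP_sd"], n_sites), 0.0, 1.0
    )
    # Available land area shrinks with elevation (conical mountain) down to a
    # flat floor near the summit plateau.
    area = 20.0 + 280.0 * np.exp(-(elev - elev_min) / 1200.0)
    area = area * np.exp(rng.normal(0.0, cfg["area_lognorm_sd"], n_sites))

    band = np.minimum(
        ((elev - elev_min) / (elev_max - elev_min + 1e-9) * n_habitats).astype(int),
        n_habitats - 1,
    )
    if n_habitats == len(HABITAT_BANDS):
        habitat = [HABITAT_BANDS[b] for b in band]
    else:
        habitat = [f"band_{b}" for b in band]

    df = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n_sites)],
            "elevation_m": elev,
            "habitat": habitat,
            "MAT": mat,
            "MMT": mmt,
            "MAP": map_mm,
            "NPP": npp,
            "area": area,
        }
    )
    return SiteTable(df)


def _z(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _species_ranges(spec: TaxonSpec, elev: np.ndarray, rng: np.random.Generator):
    """Draw (lo, hi) elevational range per species in the pool."""
    n = spec.n_species_pool
    widths = rng.gamma(shape=4.0, scale=spec.range_width_mean / 4.0, size=n)
    kind = spec.range_midpoint[0]
    lo_e, hi_e = elev.min(), elev.max()
    if kind == "uniform":
        mids = rng.uniform(lo_e, hi_e, n)
    else:  # gaussian around a taxon optimum
        _, optimum, sd = spec.range_midpoint
        mids = rng.normal(optimum, sd, n)
    return mids - widths / 2.0, mids + widths / 2.0


def generate_taxon(
    spec: TaxonSpec,
    sites: SiteTable,
    seed: int | None = None,
    site_log_effects=None,
) -> TaxonCommunity:
    """Generate one taxon's site-by-species count matrix.

    Each species receives an elevational range and can occur only at sites
    inside it.  Per-site expected richness follows
    ``occupancy · pool · exp(Σ βc · z(covariate_c))`` (capped by the number
    of species whose range covers the site); present species receive counts
    with mean ``detection_rate`` (shifted Poisson, so presence implies at
    least one individual).  Census taxa record presence/absence instead.

    ``site_log_effects`` is an optional per-site additive term on the log
    expected richness, used to model site-quality effects shared across
    taxa (weather during sampling, microhabitat, disturbance) that make
    real richness data overdispersed relative to pure binomial sampling.
    """
    if len(sites) == 0:
        raise ValidationError("site table is empty")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    elev = sites.elevations
    n_sites = len(sites)

    if spec.n_species_pool == 0:
        matrix = pd.DataFrame(
            np.zeros((n_sites, 0), dtype=np.int64), index=sites.site_ids
        )
        return TaxonCommunity(spec.taxon_name, spec.kingdom, matrix, spec.is_census)

    lo, hi = _species_ranges(spec, elev, rng)
    in_range = (elev[:, None] >= lo[None, :]) & (elev[:, None] <= hi[None, :])
    n_cover = in_range.sum(axis=1).astype(float)  # species covering each site

    eta = np.zeros(n_sites)
    for cov, beta in spec.driver_coefficients.items():
        eta += beta * _z(sites.covariate(cov))
    if site_log_effects is not None:
        effects = np.asarray(site_log_effects, dtype=float)
        if effects.shape != (n_sites,):
            raise ValidationError("site_log_effects must have one value per site")
        eta = eta + effects
    target = spec.occupancy * spec.n_species_pool * np.exp(eta)

    if spec.flatten_range_profile:
        denom = np.where(n_cover > 0, n_cover, np.inf)
    else:
        denom = max(n_cover.mean(), 1.0)
    p_present = np.clip(target / denom, 0.0, 1.0)

    present = in_range & (rng.random((n_sites, spec.n_species_pool)) < p_present[:, None])
    if spec.is_census:
        counts = present.astype(np.int64)
    else:
        lam = max(spec.detection_rate, 1.0) - 1.0
        counts = np.where(
            present, 1 + rng.poisson(lam, size=present.shape), 0
        ).astype(np.int64)

    matrix = pd.DataFrame(
        counts,
        index=sites.site_ids,
        columns=[f"{spec.taxon_name}_sp{j + 1:03d}" for j in range(spec.n_species_pool)],
    )
    community = TaxonCommunity(spec.taxon_name, spec.kingdom, matrix, spec.is_census)
    # the assigned ranges, for diagnostics and range-containment checks
    community.species_ranges = pd.DataFrame(
        {"species": matrix.columns, "lo": lo, "hi": hi}
    )
    return community


def generate_assemblage(
    specs: list[TaxonSpec],
    sites: SiteTable,
    seed: int | None = None,
    shared_site_sd: float = 0.0,
) -> list[TaxonCommunity]:
    """Generate one community per spec with independent seed streams.

    ``shared_site_sd`` draws one normal per site on the log-richness scale
    and applies it to every taxon — a shared site-quality effect that
    survives pooling (unlike per-taxon sampling noise, which averages out
    as taxa are combined).
    """
    if not specs:
        raise ValidationError("need at least one TaxonSpec")
    names = [s.taxon_name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate taxon names in assemblage")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(specs) + 1)
    effects = None
    if shared_site_sd > 0:
        site_rng = np.random.default_rng(children[-1])
        effects = site_rng.normal(0.0, shared_site_sd, len(sites))
    return [
        generate_taxon(spec, sites,
                       seed=int(child.generate_state(1)[0] % (2**31)),
                       site_log_effects=effects)
        for spec, child in zip(specs, children[: len(specs)])
    ]


def impute_missing_climate(sites: SiteTable) -> tuple[SiteTable, dict]:
    """Fill missing MAT/MMT from an OLS fit on elevation + habitat.

    Missing temperature values (e.g. stolen data loggers) are replaced by
    predictions of an additive ordinary-least-squares model
    ``temperature ~ elevation_m + habitat`` fitted to the observed rows.
    Returns the completed table and the fit R² per imputed variable;
    non-missing rows are unchanged.
    """
    df = sites.data.copy()
    if "habitat" not in df.columns:
        raise ValidationError("imputation requires a 'habitat' column")
    r2: dict[str, float] = {}
    for var in ("MAT", "MMT"):
        if var not in df.columns or not df[var].isna().any():
            continue
        obs = df[df[var].notna()]
        mis = df[df[var].isna()]
        if len(obs) == 0:
            raise ValidationError(f"all {var} values missing; cannot impute")
        orphan = set(mis["habitat"]) - set(obs["habitat"])
        if orphan:
            raise ValidationError(
                f"habitat level(s) {sorted(orphan)} have no observed {var}; "
                "the additive model cannot predict them"
            )
        counts = obs.groupby("habitat").size()
        if (counts < 2).any() and obs["habitat"].nunique() > 1:
            thin = counts[counts < 2].index.tolist()
            raise ValidationError(
                f"need >= 2 observed {var} values per habitat level; too few in {thin}"
            )
        fit = smf.ols(f"{var} ~ elevation_m + C(habitat)", data=obs).fit()
        df.loc[df[var].isna(), var] = fit.predict(mis)
        r2[var] = float(fit.rsquared)
    return SiteTable(df), r2


def staggered_temperature_assemblage(
    sites: SiteTable,
    n_taxa: int = 8,
    kingdom: str = "animal",
    temperature_covariate: str = "MAT",
    beta_site: float = 0.1,
    amplitude_slope: float = 0.6,
    base_pool: int = 150,
    optimum_span: float = 1200.0,
    optimum_sd: float = 600.0,
    range_width_mean: float = 1800.0,
    occupancy: float = 0.12,
    detection_rate: float = 6.0,
    shared_site_sd: float = 0.35,
    is_census: bool = False,
    seed: int | None = None,
    name_prefix: str = "taxon",
    names: list[str] | None = None,
) -> list[TaxonCommunity]:
    """Multi-taxon assemblage with staggered optima and a shared
    temperature effect on community richness.

    Taxon optima are spaced evenly from ``optimum_span`` metres below the
    gradient base to the same distance above its top (lowland and alpine
    specialists centred beyond the sampled sites are a real feature of
    mountain transects), so the summed range-coverage profile is roughly
    flat across the sites.  The shared temperature effect enters in two
    ways that mirror how warm-adapted clades dominate tropical mountains:
    each taxon's species pool scales linearly with the temperature at its
    optimum (slope ``amplitude_slope`` per s.d. of the site temperature),
    and every taxon has a mild per-site effect ``beta_site`` on log
    expected richness.  ``shared_site_sd`` adds a site-quality random
    effect common to all taxa (overdispersion that does not average out
    under pooling).  Single taxa therefore show unimodal richness bumps
    while the pooled community declines quasi-linearly with elevation,
    tracking temperature.
    """
    elev = sites.elevations
    elo, ehi = elev.min(), elev.max()
    temp = sites.covariate(temperature_covariate)
    t_mean, t_sd = temp.mean(), temp.std(ddof=1)
    # temperature at an arbitrary elevation, from the generating lapse model
    def temp_at(e: float) -> float:
        offset = MMT_OFFSET_C if temperature_covariate == "MMT" else 0.0
        return BASE_TEMPERATURE_C - 0.56 * (e - BASE_ELEVATION_M) / 100.0 - offset

    if names is not None and len(names) != n_taxa:
        raise ValidationError("names must have one entry per taxon")
    specs = []
    lo, hi = elo - optimum_span, ehi + optimum_span
    for i in range(n_taxa):
        opt = lo + (i + 0.5) / n_taxa * (hi - lo)
        z_opt = (temp_at(opt) - t_mean) / t_sd
        amp = max(0.05, 1.0 + amplitude_slope * z_opt)
        specs.append(
            TaxonSpec(
                taxon_name=names[i] if names else f"{name_prefix}_{i}",
                kingdom=kingdom,
                n_species_pool=max(10, int(round(base_pool * amp))),
                driver_coefficients={temperature_covariate: beta_site},
                range_width_mean=range_width_mean,
                range_midpoint=("gaussian", opt, optimum_sd),
                occupancy=occupancy,
                flatten_range_profile=False,
                detection_rate=detection_rate,
                is_census=is_census,
            )
        )
    return generate_assemblage(specs, sites, seed=seed, shared_site_sd=shared_site_sd)


# ---------------------------------------------------------------------------
# Default multi-taxon preset

_PLANT_TAXA = [
    "ferns", "orchids", "trees", "shrubs",
    "herbs", "grasses", "sedges", "lianas",
]
_ANIMAL_TAXA = [
    "gastropods", "millipedes", "spiders", "true_bugs",
    "collembola", "parasitoid_wasps", "ants", "bees",
    "aculeate_wasps", "ground_beetles", "dung_beetles", "birds",
    "moths", "bats", "frogs", "orthoptera",
]


def kilimanjaro_preset(seed: int | None = None) -> tuple[SiteTable, list[TaxonCommunity]]:
    """Default synthetic mountain: 30 sites, 8 plant + 16 animal taxa.

    Plant taxa respond to minimum temperature and are recorded as complete
    censuses; animal taxa are sampled with abundance counts and respond to
    mean annual temperature.  Both assemblages have staggered elevational
    optima (single-taxon patterns range from declining to unimodal) and
    community richness that declines with elevation, tracking temperature.
    """
    base = 0 if seed is None else seed
    sites = generate_sites(seed=base + 1)
    plants = staggered_temperature_assemblage(
        sites, n_taxa=len(_PLANT_TAXA), kingdom="plant",
        temperature_covariate="MMT", base_pool=100, is_census=True,
        seed=base + 2, names=list(_PLANT_TAXA),
    )
    animals = staggered_temperature_assemblage(
        sites, n_taxa=len(_ANIMAL_TAXA), kingdom="animal",
        temperature_covariate="MAT", base_pool=120,
        seed=base + 3, names=list(_ANIMAL_TAXA),
    )
    return sites, plants + animals
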