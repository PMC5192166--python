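"""Taxonomic upscaling: how richness patterns and their inferred drivers
change as more taxonomic groups are pooled into the analysed community.

For every subset of the available taxa (or a seeded subsample per
coverage level) the driver (1) pools species richness over the member
taxa, (2) fits the linear and smooth richness–elevation models and the
complexity statistic, (3) recomputes mid-domain-effect predictions from
the pooled species ranges, and (4) runs multi-model inference with pooled
richness as the response.  Records are aggregated per coverage level
(number of taxa pooled) into medians, interquartile ranges, and the
fraction of combinations in which each predictor ranks first by
importance or |standardized beta|.

Also provides the sampling-effort-standardized community analysis:
rarefy every abundance taxon to a common number of individuals, pool, run
multi-model inference, repeat, and summarize importance/beta with
percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from . import mde as mde_mod
from . import mmi as mmi_mod
from . import richness as rich_mod
from . import shape as shape_mod
from .datatypes import SiteTable, TaxonCommunity, ValidationError

__all__ = ["MDEConfig", "MMIConfig", "SubsampleConfig", "CoverageProfile",
           "enumerate_combinations", "analyse_subset", "coverage_analysis",
           "top_predictor_fractions", "standardized_community_mmi"]


@dataclass
class MDEConfig:
    pad: float = mde_mod.DEFAULT_PAD_M
    domain: tuple[float, float] = mde_mod.DEFAULT_DOMAIN_M
    reps: int = 200


@dataclass
class MMIConfig:
    criterion: str = "AIC"
    delta_cut: float = 4.0
    full_space_importance: bool = False


@dataclass
class SubsampleConfig:
    max_per_level: int | None = None


@dataclass
class CoverageProfile:
    """Per-combination records plus per-level summaries.

    ``records`` has one row per analysed subset: coverage level, subset id
    (member taxa joined by '+'), complexity, explained deviances, and
    per-predictor importance (``imp_*``) and standardized beta
    (``beta_*``) columns.
    """

    records: pd.DataFrame
    predictors: tuple[str, ...]

    def level_summary(self) -> pd.DataFrame:
        """Median and interquartile range of complexity per coverage level."""
        g = self.records.groupby("level")["complexity"]
        out = g.agg(median="median",
                    q25=lambda s: s.quantile(0.25),
                    q75=lambda s: s.quantile(0.75),
                    n="size")
        return out.reset_index()


def enumerate_combinations(
    taxa: list[str],
    level: int,
    max_per_level: int | None = None,
    seed: int | None = None,
) -> list[tuple[str, ...]]:
    """All C(T, k) subsets of size ``level`` in deterministic
    (binary-counter over sorted names) order, or a seeded uniform sample
    of ``max_per_level`` of them."""
    t = len(taxa)
    if not 1 <= level <= t:
        raise ValidationError(f"level must be in 1..{t}, got {level}")
    ordered = sorted(taxa)
    total = comb(t, level)
    if max_per_level is None or max_per_level >= total:
        return list(combinations(ordered, level))
    rng = np.random.default_rng(seed)
    # index-based sampling without materializing all subsets
    chosen = rng.choice(total, size=max_per_level, replace=False)
    chosen.sort()
    out = []
    for rank in chosen:
        out.append(tuple(_unrank_combination(ordered, level, int(rank))))
    return out


def _unrank_combination(items: list, k: int, rank: int) -> list:
    # colexicographic unranking consistent with itertools order
    out, start = [], 0
    n = len(items)
    for slot in range(k):
        for idx in range(start, n):
            block = comb(n - idx - 1, k - slot - 1)
            if rank < block:
                out.append(items[idx])
                start = idx + 1
                break
            rank -= block
    return out


def _subset_seed(master_seed: int | None, subset: tuple[str, ...]) -> int:
    """Stable per-subset RNG stream: order-independent and parallel-safe."""
    h = np.uint64(0xCBF29CE484222325)
    for token in ("|".join(subset), str(master_seed)):
        for b in token.encode():
            h = np.uint64((int(h) ^ b) * 0x100000001B3 % (1 << 64))
    return int(h % (2**31))


def analyse_subset(
    subset: tuple[str, ...],
    communities: list[TaxonCommunity],
    sites: SiteTable,
    predictor_names: tuple[str, ...],
    mde_config: MDEConfig,
    mmi_config: MMIConfig,
    master_seed: int | None = None,
    fixed_predictors: pd.DataFrame | None = None,
) -> dict:
    """Run the full per-subset pipeline (steps 1–4) for one taxon subset."""
    pooled = rich_mod.pooled_richness(communities, list(subset))
    elev = sites.elevations
    fit = shape_mod.pattern_summary(pooled.to_numpy(dtype=float), elev)

    ranges = mde_mod.observed_ranges(communities, sites, list(subset),
                                     domain=mde_config.domain)
    aug = mde_mod.augment_ranges(ranges, pad=mde_config.pad)
    mde_pred = mde_mod.mde_predict(aug, elev, reps=mde_config.reps,
                                   seed=_subset_seed(master_seed, subset))

    if fixed_predictors is None:
        pred = pd.DataFrame(
            {name: sites.covariate(name) for name in predictor_names if name != "MDE"}
        )
    else:
        pred = fixed_predictors.copy()
    if "MDE" in predictor_names:
        pred["MDE"] = mde_pred
    mmi_res = mmi_mod.mmi_analysis(
        pooled.to_numpy(dtype=float), pred,
        criterion=mmi_config.criterion, delta_cut=mmi_config.delta_cut,
        full_space_importance=mmi_config.full_space_importance,
    )
    rec = {
        "level": len(subset),
        "subset": "+".join(subset),
        "complexity": fit.complexity,
        "ed_gam": fit.ed_gam,
        "ed_glm": fit.ed_glm,
        "edf": fit.edf,
        "glm_slope": fit.glm_slope,
        "label": shape_mod.classify_pattern(fit),
    }
    for p in pred.columns:
        rec[f"imp_{p}"] = mmi_res.table.loc[p, "importance"]
        rec[f"beta_{p}"] = mmi_res.table.loc[p, "beta"]
    return rec


def coverage_analysis(
    communities: list[TaxonCommunity],
    sites: SiteTable,
    predictor_names: tuple[str, ...] = ("MAT", "MAP", "NPP", "area", "MDE"),
    mde_config: MDEConfig | None = None,
    mmi_config: MMIConfig | None = None,
    subsample_config: SubsampleConfig | None = None,
    seed: int | None = None,
    levels: list[int] | None = None,
) -> CoverageProfile:
    """Analyse richness patterns and drivers across all taxon subsets.

    ``predictor_names`` may include the special name ``MDE``, which is
    recomputed for every subset from the pooled member taxa's ranges; the
    remaining names must be site-table columns (e.g. a fixed full-plant
    ``PSR`` column for animal analyses).
    """
    if not communities:
        raise ValidationError("need at least one community")
    mde_config = mde_config or MDEConfig()
    mmi_config = mmi_config or MMIConfig()
    subsample_config = subsample_config or SubsampleConfig()
    for c in communities:
        c.check_alignment(sites)
    taxa = [c.taxon_name for c in communities]
    levels = levels if levels is not None else list(range(1, len(taxa) + 1))

    fixed = pd.DataFrame(
        {name: sites.covariate(name) for name in predictor_names if name != "MDE"}
    )
    records = []
    for k in levels:
        subsets = enumerate_combinations(
            taxa, k, max_per_level=subsample_config.max_per_level,
            seed=None if seed is None else seed + k,
        )
        for subset in subsets:
            records.append(
                analyse_subset(subset, communities, sites, predictor_names,
                               mde_config, mmi_config, master_seed=seed,
                               fixed_predictors=fixed)
            )
    return CoverageProfile(pd.DataFrame(records), predictors=tuple(
        p for p in predictor_names
    ))


def top_predictor_fractions(
    profile: CoverageProfile, criterion: str = "importance"
) -> pd.DataFrame:
    """Share of combinations per level where each predictor ranks first.

    ``criterion`` is 'importance' or 'abs_beta'.  Ties on the primary
    criterion are resolved by the other one: importance saturates at 1,
    so two predictors present in every best-fit model tie exactly, and
    the one with the larger |standardized beta| is then ranked first (and
    vice versa for the abs_beta criterion).  Combinations still tied
    after both keys split credit equally, so fractions per level sum to 1
    (less when a combination has no defined values).
    """
    if criterion not in ("importance", "abs_beta"):
        raise ValidationError("criterion must be 'importance' or 'abs_beta'")
    if profile.records.empty:
        raise ValidationError("empty coverage profile")
    imp_cols = [c for c in profile.records.columns if c.startswith("imp_")]
    preds = [c[len("imp_"):] for c in imp_cols]
    beta_cols = [f"beta_{p}" for p in preds]

    rows = []
    for level, grp in profile.records.groupby("level"):
        credit = dict.fromkeys(preds, 0.0)
        n_comb = len(grp)
        for _, rec in grp.iterrows():
            imp = rec[imp_cols].to_numpy(dtype=float)
            absb = np.abs(rec[beta_cols].to_numpy(dtype=float))
            primary, secondary = (imp, absb) if criterion == "importance" else (absb, imp)
            if np.all(np.isnan(primary)):
                continue
            best = np.nanmax(primary)
            tied = [i for i, v in enumerate(primary) if v == best]
            if len(tied) > 1:
                sec = np.array([secondary[i] for i in tied])
                if not np.all(np.isnan(sec)):
                    sec_best = np.nanmax(sec)
                    tied = [i for i, s in zip(tied, sec) if s == sec_best]
            for i in tied:
                credit[preds[i]] += 1.0 / len(tied)
        row = {"level": level}
        row.update({p: credit[p] / n_comb for p in preds})
        rows.append(row)
    return pd.DataFrame(rows)


def standardized_community_mmi(
    communities: list[TaxonCommunity],
    sites: SiteTable,
    predictor_names: tuple[str, ...] = ("MAT", "MAP", "NPP", "area", "MDE"),
    n_rarefy: int | dict = 83,
    reps: int = 5000,
    seed: int | None = None,
    mmi_config: MMIConfig | None = None,
    mde_config: MDEConfig | None = None,
) -> pd.DataFrame:
    """Sampling-effort-standardized community-level multi-model inference.

    Per replicate every abundance (non-census) taxon is rarefied to
    ``n_rarefy`` individuals (an int applied to all taxa, or a mapping
    taxon name → count), richness is pooled across all taxa, and
    multi-model inference is run; the MDE predictor (if requested) is
    recomputed per replicate from the rarefied communities.  Returns the
    per-predictor mean and percentile 95% confidence interval of variable
    importance and standardized beta across replicates.
    """
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    mmi_config = mmi_config or MMIConfig()
    mde_config = mde_config or MDEConfig()
    if isinstance(n_rarefy, dict):
        n_for = dict(n_rarefy)
    else:
        n_for = {c.taxon_name: int(n_rarefy) for c in communities}
    for c in communities:
        c.check_alignment(sites)
        if not c.is_census and c.total_individuals() < n_for[c.taxon_name]:
            raise ValidationError(
                f"taxon {c.taxon_name!r} has {c.total_individuals()} individuals, "
                f"fewer than n_rarefy={n_for[c.taxon_name]}"
            )
    rng = np.random.default_rng(seed)
    elev = sites.elevations
    fixed = pd.DataFrame(
        {name: sites.covariate(name) for name in predictor_names if name != "MDE"}
    )

    imp_rows, beta_rows = [], []
    for _ in range(reps):
        reduced = [
            c if c.is_census else rich_mod.rarefy_once(c, n_for[c.taxon_name], rng)
            for c in communities
        ]
        pooled = rich_mod.pooled_richness(reduced)
        pred = fixed.copy()
        if "MDE" in predictor_names:
            ranges = mde_mod.observed_ranges(reduced, sites, domain=mde_config.domain)
            aug = mde_mod.augment_ranges(ranges, pad=mde_config.pad)
            pred["MDE"] = mde_mod.mde_predict(
                aug, elev, reps=mde_config.reps,
                seed=int(rng.integers(2**31)),
            )
        res = mmi_mod.mmi_analysis(
            pooled.to_numpy(dtype=float), pred,
            criterion=mmi_config.criterion, delta_cut=mmi_config.delta_cut,
        )
        imp_rows.append(res.table["importance"])
        beta_rows.append(res.table["beta"])

    imp = pd.DataFrame(imp_rows)
    beta = pd.DataFrame(beta_rows)
    out = []
    for p in imp.columns:
        out.append({
            "predictor": p,
            "importance_mean": imp[p].mean(),
            "importance_lo": imp[p].quantile(0.025),
            "importance_hi": imp[p].quantile(0.975),
            "beta_mean": beta[p].mean(),
            "beta_lo": beta[p].quantile(0.025),
            "beta_hi": beta[p].quantile(0.975),
        })
    return pd.DataFrame(out).set_index("predictor")
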