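"""Species-richness estimation: observed counts, Chao1, sample coverage,
individual-based rarefaction, and pooled multi-taxon richness.

Chao1 is the bias-corrected form
``S_obs + f1(f1 − 1) / (2(f2 + 1))`` (defined even when there are no
doubletons); sample coverage is the Chao–Jost estimator
``1 − (f1/n)·[(n−1)f1 / ((n−1)f1 + 2f2)]``.  Rarefaction subsamples
individuals without replacement from the taxon-wide pool (individuals keep
their site and species labels), so per-site richness can be recomputed at a
common total sampling effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import SiteTable, TaxonCommunity, ValidationError

__all__ = [
    "abundance_summary",
    "observed_richness",
    "chao1",
    "sample_coverage",
    "rarefy_taxon",
    "expected_rarefied_richness",
    "pooled_richness",
    "richness_table",
    "coverage_elevation_report",
]


def _as_counts(v) -> np.ndarray:
    counts = np.asarray(v)
    if counts.ndim != 1:
        raise ValidationError("abundance vector must be one-dimensional")
    if counts.size == 0:
        raise ValidationError("abundance vector is empty")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValidationError("abundances must be non-negative integers")
    return counts.astype(np.int64)


def abundance_summary(v) -> dict:
    """n, S_obs, singleton and doubleton counts of an abundance vector."""
    counts = _as_counts(v)
    return {
        "n": int(counts.sum()),
        "s_obs": int((counts > 0).sum()),
        "f1": int((counts == 1).sum()),
        "f2": int((counts == 2).sum()),
    }


def _require_abundance(community: TaxonCommunity, op: str) -> None:
    if community.is_census:
        raise ValidationError(
            f"{op} needs abundance data; {community.taxon_name!r} is a "
            "presence/absence census"
        )


def observed_richness(community: TaxonCommunity) -> pd.Series:
    """Number of species with count > 0 at each site."""
    arr = community.counts
    return pd.Series(
        (arr > 0).sum(axis=1), index=community.site_ids, name=community.taxon_name
    )


def chao1(v) -> float:
    """Bias-corrected Chao1 asymptotic richness estimate.

    Uses ``S_obs + f1(f1 − 1)/(2(f2 + 1))``, which is defined for f2 = 0
    and never falls below the observed richness.
    """
    s = abundance_summary(v)
    if s["n"] < 1:
        raise ValidationError("Chao1 needs at least one individual")
    return s["s_obs"] + s["f1"] * (s["f1"] - 1) / (2.0 * (s["f2"] + 1))


def sample_coverage(v) -> float:
    """Estimated sample coverage (completeness) of an abundance vector.

    The estimated proportion of the assemblage's individuals belonging to
    species already detected; 1 when there are no singletons.
    """
    s = abundance_summary(v)
    n, f1, f2 = s["n"], s["f1"], s["f2"]
    if n < 1:
        raise ValidationError("coverage needs at least one individual")
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:  # only possible when n == 1 (a lone singleton)
        return 0.0
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def expected_rarefied_richness(v, n_draw: int) -> float:
    """Closed-form expected richness of a sample of ``n_draw`` individuals.

    Hypergeometric expectation ``Σ_i [1 − C(N−N_i, n)/C(N, n)]`` over
    species with abundance ``N_i`` and total ``N``.
    """
    counts = _as_counts(v)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if n_draw > total:
        raise ValidationError(f"cannot draw {n_draw} from {total} individuals")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    p_absent = np.where(
        total - counts >= n_draw,
        np.exp(log_choose(total - counts, n_draw) - log_choose(total, n_draw)),
        0.0,
    )
    return float(np.sum(1.0 - p_absent))


def rarefy_taxon(
    community: TaxonCommunity,
    n_individuals: int,
    reps: int = 1000,
    seed: int | None = None,
    per_site: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo rarefaction of a taxon to a common number of individuals.

    Draws ``n_individuals`` without replacement from the taxon-wide pool of
    individuals (multivariate hypergeometric over site × species cells),
    then recomputes per-site richness; returns one row per replicate with
    sites as columns.  With ``per_site=True`` each site's individuals are
    instead rarefied independently to ``n_individuals`` (sites with fewer
    individuals raise an error).
    """
    _require_abundance(community, "rarefaction")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    arr = community.counts
    rng = np.random.default_rng(seed)

    if per_site:
        out = np.zeros((reps, arr.shape[0]), dtype=np.int64)
        for i, row in enumerate(arr):
            tot = int(row.sum())
            if n_individuals > tot:
                raise ValidationError(
                    f"site {community.site_ids[i]!r} has only {tot} individuals, "
                    f"short of {n_individuals} by {n_individuals - tot}"
                )
            for r in range(reps):
                draw = rng.multivariate_hypergeometric(row, n_individuals)
                out[r, i] = int((draw > 0).sum())
        return pd.DataFrame(out, columns=community.site_ids)

    flat = arr.ravel()
    total = int(flat.sum())
    if n_individuals > total:
        raise ValidationError(
            f"taxon {community.taxon_name!r} has only {total} individuals, "
            f"short of {n_individuals} by {n_individuals - total}"
        )
    out = np.zeros((reps, arr.shape[0]), dtype=np.int64)
    for r in range(reps):
        draw = rng.multivariate_hypergeometric(flat, n_individuals).reshape(arr.shape)
        out[r] = (draw > 0).sum(axis=1)
    return pd.DataFrame(out, columns=community.site_ids)


def rarefy_once(
    community: TaxonCommunity, n_individuals: int, rng: np.random.Generator
) -> TaxonCommunity:
    """One rarefaction draw returned as a new community (same shape)."""
    _require_abundance(community, "rarefaction")
    arr = community.counts
    flat = arr.ravel()
    total = int(flat.sum())
    if n_individuals > total:
        raise ValidationError(
            f"taxon {community.taxon_name!r} has only {total} individuals, "
            f"short of {n_individuals} by {n_individuals - total}"
        )
    draw = rng.multivariate_hypergeometric(flat, n_individuals).reshape(arr.shape)
    matrix = pd.DataFrame(draw, index=community.site_ids, columns=community.matrix.columns)
    return TaxonCommunity(community.taxon_name, community.kingdom, matrix, False)


def pooled_richness(
    communities: list[TaxonCommunity], subset: list[str] | None = None
) -> pd.Series:
    """Per-site cumulative richness summed over the member taxa."""
    by_name = {c.taxon_name: c for c in communities}
    if subset is None:
        subset = list(by_name)
    if not subset:
        raise ValidationError("taxon subset is empty")
    unknown = [t for t in subset if t not in by_name]
    if unknown:
        raise ValidationError(f"unknown taxon name(s): {unknown}")
    members = [by_name[t] for t in subset]
    ref_sites = members[0].site_ids
    for c in members[1:]:
        if c.site_ids != ref_sites:
            raise ValidationError(
                f"site sets differ between {members[0].taxon_name!r} and {c.taxon_name!r}"
            )
    total = sum(observed_richness(c) for c in members)
    total.name = "pooled_richness"
    return total


def richness_table(
    community: TaxonCommunity, estimators: tuple[str, ...] = ("observed",)
) -> pd.DataFrame:
    """Per-site richness table with optional Chao1 and coverage columns."""
    out = pd.DataFrame({"observed": observed_richness(community)})
    arr = community.counts
    if "chao1" in estimators:
        _require_abundance(community, "Chao1")
        out["chao1"] = [chao1(row) if row.sum() > 0 else 0.0 for row in arr]
    if "coverage" in estimators:
        _require_abundance(community, "sample coverage")
        out["coverage"] = [
            sample_coverage(row) if row.sum() > 0 else np.nan for row in arr
        ]
    return out


def coverage_elevation_report(
    communities: list[TaxonCommunity], sites: SiteTable
) -> pd.DataFrame:
    """Per-taxon Pearson correlation of per-site sample coverage with elevation.

    A screening table for sampling-completeness bias: a strong correlation
    means completeness varies systematically along the gradient.
    """
    from scipy.stats import pearsonr

    rows = []
    for c in communities:
        if c.is_census:
            continue
        c.check_alignment(sites)
        cov = richness_table(c, ("observed", "coverage"))["coverage"]
        mask = cov.notna().to_numpy()
        if mask.sum() < 3 or cov[mask].nunique() < 2:
            r = p = np.nan
        else:
            r, p = pearsonr(sites.elevations[mask], cov.to_numpy()[mask])
        rows.append(
            {
                "taxon": c.taxon_name,
                "mean_coverage": float(np.nanmean(cov)),
                "pearson_r_elevation": float(r),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
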