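"""Information-theoretic multi-model inference over all predictor subsets.

All 2^p ordinary-least-squares models (intercept always included) are
ranked by AIC or its small-sample correction AICc; a ΔAIC cut defines the
best-fit set over which Akaike weights are renormalized.  From the
retained set the module computes per-predictor variable importance (the
summed weight of models containing the predictor) and conditional
model-averaged standardized coefficients with unconditional standard
errors that combine within-model variance and between-model spread.

Formulae (Gaussian likelihood, additive constants dropped — they cancel
in ΔAIC): ``AIC = n·ln(RSS/n) + 2k`` and
``AICc = AIC + 2k(k+1)/(n−k−1)``, where k counts intercept, slopes and
the residual variance (so the intercept-only model has k = 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = ["ModelFit", "ModelTable", "MMIResult", "z_transform",
           "all_subsets_fit", "retain_best", "variable_importance",
           "averaged_betas", "mmi_analysis"]


def z_transform(columns: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample s.d. 1 (n−1 denominator)."""
    out = {}
    for name in columns.columns:
        x = columns[name].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"cannot z-transform constant column {name!r}")
        out[name] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=columns.index)


@dataclass
class ModelFit:
    """One candidate OLS model."""

    terms: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    rss: float
    k: int
    aic: float
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class ModelTable:
    """Candidate (or retained) model set with selection statistics."""

    models: list[ModelFit]
    n: int
    predictors: tuple[str, ...]
    criterion: str = "AIC"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            row = {"terms": "+".join(m.terms) if m.terms else "(intercept)",
                   "k": m.k, "rss": m.rss, "aic": m.aic, "aicc": m.aicc,
                   "delta": m.delta, "weight": m.weight}
            for p in self.predictors:
                row[f"beta_{p}"] = m.beta.get(p, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _score(m: ModelFit, criterion: str) -> float:
    return m.aicc if criterion == "AICc" else m.aic


def all_subsets_fit(response, predictors: pd.DataFrame, criterion: str = "AIC") -> ModelTable:
    """Fit all 2^p predictor subsets by OLS and score them.

    ``predictors`` should already be z-transformed so that coefficients
    are standardized betas.  Rank-deficient subsets are dropped with a
    warning entry rather than aborting the analysis.
    """
    if criterion not in ("AIC", "AICc"):
        raise ValidationError("criterion must be 'AIC' or 'AICc'")
    y = np.asarray(response, dtype=float)
    names = tuple(predictors.columns)
    p = len(names)
    if p > 16:
        raise ValidationError("more than 16 predictors: all-subsets fit refused")
    n = y.size
    if n <= p + 2:
        raise ValidationError(f"need n > p + 2 (n={n}, p={p})")
    x_full = predictors.to_numpy(dtype=float)

    models: list[ModelFit] = []
    for size in range(p + 1):
        for subset in combinations(range(p), size):
            design = np.column_stack([np.ones(n)] + [x_full[:, j] for j in subset])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                import warnings

                warnings.warn(
                    f"rank-deficient design for subset {[names[j] for j in subset]}; "
                    "model excluded"
                )
                continue
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            rss = float(resid @ resid)
            k = design.shape[1] + 1  # + residual variance
            dof = n - design.shape[1]
            sigma2 = rss / dof if dof > 0 else np.nan
            cov = sigma2 * np.linalg.inv(design.T @ design)
            se = np.sqrt(np.diag(cov))
            aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
            aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
            models.append(
                ModelFit(
                    terms=tuple(names[j] for j in subset),
                    beta={names[j]: float(coef[i + 1]) for i, j in enumerate(subset)},
                    se={names[j]: float(se[i + 1]) for i, j in enumerate(subset)},
                    rss=rss, k=k, aic=float(aic), aicc=float(aicc),
                )
            )
    table = ModelTable(models, n=n, predictors=names, criterion=criterion)
    _set_deltas_and_weights(table)
    return table


def _set_deltas_and_weights(table: ModelTable) -> None:
    scores = np.array([_score(m, table.criterion) for m in table.models])
    deltas = scores - scores.min()
    raw = np.exp(-deltas / 2.0)
    weights = raw / raw.sum()
    for m, d, w in zip(table.models, deltas, weights):
        m.delta = float(d)
        m.weight = float(w)


def retain_best(table: ModelTable, delta_cut: float = 4.0) -> ModelTable:
    """Keep models with Δ < delta_cut; renormalize weights over the set."""
    if not table.models:
        raise ValidationError("empty model table")
    kept = [m for m in table.models if m.delta < delta_cut]
    out = ModelTable(
        [ModelFit(**vars(m)) for m in kept],
        n=table.n, predictors=table.predictors, criterion=table.criterion,
    )
    _set_deltas_and_weights(out)
    return out


def variable_importance(table: ModelTable) -> pd.Series:
    """Summed Akaike weight of the models containing each predictor."""
    imp = {}
    for p in table.predictors:
        imp[p] = float(sum(m.weight for m in table.models if p in m.terms))
    return pd.Series(imp, name="importance")


@dataclass
class MMIResult:
    """Per-predictor importance and conditional model-averaged estimates."""

    table: pd.DataFrame  # index predictor; importance, beta, se, p, significant
    retained: ModelTable = field(repr=False, default=None)

    def top_predictor(self, criterion: str = "importance") -> str:
        col = "importance" if criterion == "importance" else "beta"
        vals = self.table[col].abs() if col == "beta" else self.table[col]
        return vals.idxmax()


def averaged_betas(table: ModelTable, alpha: float = 0.05) -> MMIResult:
    """Conditional model-averaged standardized betas over the retained set.

    For each predictor, the average runs over retained models containing
    it, with weights renormalized within that subset.  The unconditional
    standard error follows the model-averaging variance formula
    ``Σ w'_i √(var_i + (β_i − β̄)²)``; the p-value is a two-sided normal
    test of β̄/se.  Predictors absent from every retained model get
    importance 0 and NaN estimates.
    """
    imp = variable_importance(table)
    rows = {}
    for p in table.predictors:
        containing = [m for m in table.models if p in m.terms]
        if not containing:
            rows[p] = {"importance": 0.0, "beta": np.nan, "se": np.nan,
                       "p": np.nan, "significant": False}
            continue
        w = np.array([m.weight for m in containing])
        w = w / w.sum()
        betas = np.array([m.beta[p] for m in containing])
        ses = np.array([m.se[p] for m in containing])
        beta_bar = float(w @ betas)
        se_u = float(w @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
        zval = beta_bar / se_u if se_u > 0 else np.nan
        pval = 2.0 * stats.norm.sf(abs(zval)) if np.isfinite(zval) else np.nan
        rows[p] = {"importance": float(imp[p]), "beta": beta_bar, "se": se_u,
                   "p": float(pval), "significant": bool(pval < alpha)}
    return MMIResult(pd.DataFrame(rows).T.astype(
        {"importance": float, "beta": float, "se": float, "p": float}
    ), retained=table)


def mmi_analysis(
    response,
    predictors: pd.DataFrame,
    criterion: str = "AIC",
    delta_cut: float = 4.0,
    standardize: bool = True,
    full_space_importance: bool = False,
) -> MMIResult:
    """End-to-end multi-model inference: z-transform, all-subsets fit,
    best-set retention, importance and averaged betas.

    With ``full_space_importance`` the importance column is recomputed
    over the full 2^p model space instead of the retained set.
    """
    x = z_transform(predictors) if standardize else predictors
    table = all_subsets_fit(response, x, criterion=criterion)
    retained = retain_best(table, delta_cut=delta_cut)
    result = averaged_betas(retained)
    if full_space_importance:
        result.table["importance"] = variable_importance(table)
    return result
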