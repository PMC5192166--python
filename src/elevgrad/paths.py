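"""Recursive path analysis separating direct from indirect effects.

Path models here are recursive (acyclic) systems of observed variables:
each endogenous variable is regressed on its parents by ordinary least
squares, which is maximum-likelihood for recursive systems with
uncorrelated errors.  All variables are z-standardized first, so edge
coefficients are standardized path coefficients and an indirect effect is
the product of coefficients along a directed path.

Candidate model structures are built by information-theoretic
pre-selection: for every endogenous variable an all-subsets OLS scan
ranked by AICc retains the well-supported predictor sets (ΔAICc below a
cut, default 3), and the cross-product of per-equation retained sets
defines the competing path specifications, themselves ranked by a model
AICc (per-equation Gaussian log-likelihoods summed; K = total free
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from . import mmi as mmi_mod
from .datatypes import ValidationError

__all__ = ["PathSpec", "PathFit", "preselect_paths", "fit_path_model",
           "indirect_effects", "rank_path_models"]


@dataclass(frozen=True)
class PathSpec:
    """One candidate path model: ordered endogenous equations.

    ``equations`` maps each endogenous variable, in causal order, to the
    tuple of its parents (exogenous variables or earlier endogenous
    variables).  The implied edge list must be acyclic by construction.
    """

    equations: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        endogenous = [v for v, _ in self.equations]
        if len(set(endogenous)) != len(endogenous):
            raise ValidationError("duplicate endogenous variable in path spec")
        for var, parents in self.equations:
            for p in parents:
                if p in endogenous and p not in seen:
                    raise ValidationError(
                        f"edge {p} -> {var} violates the causal order (cycle risk)"
                    )
            seen.add(var)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(p, var) for var, parents in self.equations for p in parents]

    def parents_of(self, var: str) -> tuple[str, ...]:
        for v, parents in self.equations:
            if v == var:
                return parents
        return ()


@dataclass
class PathFit:
    """Fitted path model: standardized edge coefficients and diagnostics."""

    spec: PathSpec
    coefficients: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    aicc: float
    n: int

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": s, "sink": t, "beta": self.coefficients[(s, t)],
             "p": self.p_values[(s, t)]}
            for (s, t) in self.coefficients
        ]
        return pd.DataFrame(rows)


def preselect_paths(
    data: pd.DataFrame,
    endogenous_specs: dict[str, list[str]],
    delta_cut: float = 3.0,
) -> list[PathSpec]:
    """Candidate path models from per-equation all-subsets AICc scans.

    For each endogenous variable (in the given causal order) all subsets
    of its candidate predictors are fitted by OLS on z-standardized data
    and ranked by AICc; subsets with ΔAICc < ``delta_cut`` are retained.
    The cross-product of retained subsets over equations gives the list
    of candidate :class:`PathSpec` objects (empty parent sets are kept
    only if retained and at least one equation has parents).
    """
    z = mmi_mod.z_transform(data[sorted({v for v in endogenous_specs}
                                        | {p for ps in endogenous_specs.values() for p in ps})])
    retained_sets: list[list[tuple[str, ...]]] = []
    for var, candidates in endogenous_specs.items():
        if not candidates:
            raise ValidationError(f"endogenous variable {var!r} has no candidates")
        table = mmi_mod.all_subsets_fit(
            z[var].to_numpy(), z[list(candidates)], criterion="AICc"
        )
        best = mmi_mod.retain_best(table, delta_cut=delta_cut)
        retained_sets.append([m.terms for m in best.models])
    specs = []
    endo = list(endogenous_specs)
    for combo in product(*retained_sets):
        specs.append(PathSpec(tuple(zip(endo, combo))))
    return specs


def fit_path_model(spec: PathSpec, data: pd.DataFrame) -> PathFit:
    """Fit a recursive path model equation-by-equation by OLS.

    Data are z-standardized internally; each endogenous variable with at
    least one parent is regressed on its parents.  The model AICc sums
    Gaussian log-likelihoods over equations with K = total free
    parameters (per equation: intercept + slopes + residual variance).
    """
    used = sorted({v for v, _ in spec.equations}
                  | {p for _, ps in spec.equations for p in ps})
    missing = [v for v in used if v not in data.columns]
    if missing:
        raise ValidationError(f"variables not in data: {missing}")
    if data[used].isna().any().any():
        raise ValidationError("path analysis requires complete data")
    z = mmi_mod.z_transform(data[used])
    n = len(z)

    coefs: dict[tuple[str, str], float] = {}
    pvals: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    loglik_total = 0.0
    k_total = 0
    any_parents = False
    for var, parents in spec.equations:
        if not parents:
            continue
        any_parents = True
        x = z[list(parents)].to_numpy()
        corr = np.corrcoef(x, rowvar=False)
        if len(parents) > 1:
            iu = np.triu_indices(len(parents), 1)
            worst = np.argmax(np.abs(corr[iu]))
            if np.abs(corr[iu][worst]) > 0.999:
                a, b = parents[iu[0][worst]], parents[iu[1][worst]]
                raise ValidationError(f"collinear parents {a!r} and {b!r} for {var!r}")
        y = z[var].to_numpy()
        design = np.column_stack([np.ones(n), x])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise ValidationError(f"rank-deficient equation for {var!r}")
        resid = y - design @ coef
        rss = float(resid @ resid)
        dof = n - design.shape[1]
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        tvals = coef / se
        for i, p in enumerate(parents):
            coefs[(p, var)] = float(coef[i + 1])
            pvals[(p, var)] = float(2 * stats.t.sf(abs(tvals[i + 1]), dof))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2[var] = 1.0 - rss / tss
        loglik_total += -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        k_total += design.shape[1] + 1
    if not any_parents:
        raise ValidationError("path spec has no equations with parents")
    aicc = -2 * loglik_total + 2 * k_total
    if n - k_total - 1 > 0:
        aicc += 2 * k_total * (k_total + 1) / (n - k_total - 1)
    else:
        aicc = np.inf
    return PathFit(spec, coefs, pvals, r2, float(aicc), n)


def rank_path_models(
    specs: list[PathSpec], data: pd.DataFrame, delta_cut: float = 3.0
) -> tuple[list[PathFit], pd.DataFrame]:
    """Fit candidate specs, rank by AICc, and report competing edges.

    Returns the fits sorted by AICc together with a table of edges that
    appear in any competitive model (ΔAICc < ``delta_cut``) but not in
    the best one (the 'interrupted line' edges).
    """
    if not specs:
        raise ValidationError("no candidate path specs")
    fits = sorted((fit_path_model(s, data) for s in specs), key=lambda f: f.aicc)
    best = fits[0]
    best_edges = set(best.spec.edges)
    competing = set()
    for f in fits[1:]:
        if f.aicc - best.aicc < delta_cut:
            competing |= set(f.spec.edges) - best_edges
    comp = pd.DataFrame(sorted(competing), columns=["source", "sink"])
    return fits, comp


def indirect_effects(fit: PathFit, source: str, sink: str) -> dict:
    """Decompose the total effect of ``source`` on ``sink``.

    The direct effect is the coefficient of the source→sink edge (0 if
    absent); each indirect contribution is the product of coefficients
    along a directed path of length ≥ 2; the total is their sum.
    """
    children: dict[str, list[str]] = {}
    for (s, t), _ in fit.coefficients.items():
        children.setdefault(s, []).append(t)
    all_vars = {v for e in fit.coefficients for v in e}
    if source not in all_vars or sink not in all_vars:
        raise ValidationError(f"{source!r} or {sink!r} not in the fitted graph")

    paths: list[tuple[list[str], float]] = []

    def walk(node: str, trail: list[str], prod: float) -> None:
        if node == sink and len(trail) > 1:
            paths.append((list(trail), prod))
            return
        for child in children.get(node, []):
            walk(child, trail + [child], prod * fit.coefficients[(node, child)])

    walk(source, [source], 1.0)
    direct = fit.coefficients.get((source, sink), 0.0)
    indirect = [(p, v) for p, v in paths if len(p) > 2]
    indirect_total = sum(v for _, v in indirect)
    return {
        "direct": direct,
        "indirect_paths": indirect,
        "indirect": indirect_total,
        "total": direct + indirect_total,
    }
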