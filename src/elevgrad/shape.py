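"""Shape of elevational richness patterns: linear vs smooth fits.

The pattern-complexity statistic compares the explained deviance of an
ordinary linear regression of richness on elevation (EDglm) with that of a
penalized smooth fit (EDgam):

    complexity = (EDgam − EDglm) / EDgam

Complexity is 0 for a purely linear pattern and approaches 1 when the
smooth captures structure (e.g. a mid-elevation hump) that the line
cannot.  The smooth is a Gaussian-family penalized natural cubic
regression spline with a small basis (default dimension 5, knots at
elevation quantiles) and an integrated-squared-second-derivative penalty,
whose null space is exactly the linear functions; the smoothing parameter
is selected by generalized cross-validation (GCV).  Because the penalty
null space contains every straight line, the smooth's residual sum of
squares can never exceed the linear fit's, so EDgam ≥ EDglm holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .datatypes import ValidationError

__all__ = ["FitSummary", "fit_glm", "fit_gam", "complexity", "classify_pattern",
           "pattern_summary"]

#: EDgam below this is treated as no signal → complexity undefined.
COMPLEXITY_TOLERANCE = 1e-8
#: log10 endpoints and resolution of the GCV smoothing-parameter grid
#: (on covariate rescaled to [0, 1] and response scaled to unit variance).
LAMBDA_GRID = np.logspace(-8.0, 8.0, 81)


@dataclass
class FitSummary:
    """Linear and smooth fit of one richness–elevation pattern."""

    ed_glm: float
    ed_gam: float
    edf: float
    glm_slope: float
    glm_p: float

    @property
    def complexity(self) -> float:
        return complexity(self.ed_gam, self.ed_glm)


def _check_xy(y, x, min_n: int = 3):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("richness and elevation must be 1-D and equal length")
    if y.size < min_n:
        raise ValidationError(f"need at least {min_n} sites")
    if np.ptp(x) == 0:
        raise ValidationError("elevation is constant")
    if np.ptp(y) == 0:
        raise ValidationError("constant richness: explained deviance undefined")
    return y, x


def fit_glm(richness, elevation) -> dict:
    """OLS fit of richness on elevation (Gaussian family, identity link).

    Returns explained deviance ``1 − RSS/TSS``, the slope, and its
    two-sided p-value.
    """
    y, x = _check_xy(richness, elevation)
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    tss = float(np.sum((y - y.mean()) ** 2))
    ed = 1.0 - float(np.sum(resid**2)) / tss
    return {"ed": ed, "slope": float(res.slope), "p": float(res.pvalue),
            "intercept": float(res.intercept)}


def _natural_spline_design(x01: np.ndarray, knots: np.ndarray):
    """Basis matrix and roughness penalty for a natural cubic spline.

    The spline is parametrized by its values at the knots; the basis
    column j evaluates the natural cubic interpolant of the j-th unit
    vector.  The penalty ``gᵀ K g`` equals the integrated squared second
    derivative, with ``K = Q R⁻¹ Qᵀ`` built from knot spacings
    (Green–Silverman form); K annihilates linear knot values.
    """
    k = knots.size
    basis = np.column_stack(
        [CubicSpline(knots, np.eye(k)[:, j], bc_type="natural")(x01) for j in range(k)]
    )
    h = np.diff(knots)
    q = np.zeros((k, k - 2))
    r = np.zeros((k - 2, k - 2))
    for j in range(1, k - 1):
        q[j - 1, j - 1] = 1.0 / h[j - 1]
        q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        q[j + 1, j - 1] = 1.0 / h[j]
        r[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < k - 2:
            r[j - 1, j] = r[j, j - 1] = h[j] / 6.0
    pen = q @ np.linalg.solve(r, q.T)
    return basis, pen


def fit_gam(richness, elevation, basis_dim: int = 5) -> dict:
    """Penalized natural-cubic-spline fit of richness on elevation.

    ``basis_dim`` knots are spread over elevation quantiles; GCV selects
    the smoothing parameter on a fixed log-spaced grid with ties broken
    toward the smoother fit.  Returns explained deviance and the smooth's
    effective degrees of freedom ``edf = tr(hat) − 1``
    (1 = effectively linear, at most ``basis_dim − 1``).
    """
    if basis_dim < 3:
        raise ValidationError("basis_dim must be >= 3")
    y, x = _check_xy(richness, elevation, min_n=basis_dim + 2)
    # affine-invariant internal scale
    x01 = (x - x.min()) / np.ptp(x)
    y_sd = y.std(ddof=1)
    ys = (y - y.mean()) / y_sd
    knots = np.unique(np.quantile(x01, np.linspace(0, 1, basis_dim)))
    if knots.size < 3:
        raise ValidationError("too few distinct elevations for the spline basis")
    basis, pen = _natural_spline_design(x01, knots)

    n = y.size
    bt_b = basis.T @ basis
    bt_y = basis.T @ ys
    best = None
    for lam in LAMBDA_GRID:
        coef = np.linalg.solve(bt_b + lam * pen, bt_y)
        fitted = basis @ coef
        rss = float(np.sum((ys - fitted) ** 2))
        hat_tr = float(np.trace(np.linalg.solve(bt_b + lam * pen, bt_b)))
        gcv = n * rss / (n - hat_tr) ** 2
        # tie-break toward larger lambda (smoother fit)
        if best is None or gcv <= best["gcv"] + 1e-12:
            best = {"gcv": gcv, "rss": rss, "edf": hat_tr - 1.0, "lam": lam,
                    "fitted": fitted}
    tss = float(np.sum(ys**2))
    ed = 1.0 - best["rss"] / tss
    return {"ed": ed, "edf": best["edf"], "lambda": best["lam"],
            "fitted": best["fitted"] * y_sd + y.mean()}


def complexity(ed_gam: float, ed_glm: float) -> float:
    """Departure of a pattern from linearity: (EDgam − EDglm)/EDgam.

    Returns NaN (undefined) when EDgam is below tolerance; raises when the
    nesting invariant EDgam ≥ EDglm is violated beyond numerical noise.
    """
    if ed_gam < ed_glm - 1e-8:
        raise ValidationError(
            f"EDgam ({ed_gam:.6g}) < EDglm ({ed_glm:.6g}): nesting violated"
        )
    if ed_gam <= COMPLEXITY_TOLERANCE:
        return float("nan")
    return float(np.clip((ed_gam - max(ed_glm, 0.0)) / ed_gam, 0.0, 1.0))


def classify_pattern(fit: FitSummary, threshold: float = 0.2, alpha: float = 0.05) -> str:
    """Label a pattern 'declining', 'complex', or 'unresolved'.

    Declining: complexity < threshold together with a significant negative
    linear slope.  Complex: complexity ≥ threshold.  Everything else
    (including undefined complexity) is unresolved.
    """
    c = fit.complexity
    if np.isnan(c):
        return "unresolved"
    if c >= threshold:
        return "complex"
    if fit.glm_slope < 0 and fit.glm_p < alpha:
        return "declining"
    return "unresolved"


def pattern_summary(richness, elevation, basis_dim: int = 5) -> FitSummary:
    """Convenience wrapper: both fits plus the complexity statistic."""
    glm = fit_glm(richness, elevation)
    gam = fit_gam(richness, elevation, basis_dim=basis_dim)
    return FitSummary(
        ed_glm=glm["ed"], ed_gam=gam["ed"], edf=gam["edf"],
        glm_slope=glm["slope"], glm_p=glm["p"],
    )
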