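"""Statistical layer: Pearson chi-square tests, Sidak thresholds, and the
snowball linear-vs-quadratic model comparison.

The snowball prediction is that the number of hybrid incompatibilities grows
faster than linearly with divergence.  The comparison fits the (Ks, region
count) points with a first- and a second-degree polynomial by ordinary least
squares and compares Gaussian maximum-likelihood AIC,

    AIC = 2k - 2*loglik,    k = (#coefficients) + 1  (residual scale),
    loglik = -(n/2) * (log 2*pi + log(rss/n) + 1).

A perfect fit (rss below a floor) makes the Gaussian likelihood unbounded;
such fits are flagged degenerate and reported with AIC = -inf rather than
silently overflowing — the screen's own five-point dataset makes the full
quadratic exactly interpolating, so this case is ordinary, not exotic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaincc

from .regions import SnowballDataset

__all__ = [
    "ChiSquareResult",
    "ModelFit",
    "SnowballComparison",
    "chisq_gof",
    "chisq_homogeneity",
    "sidak_threshold",
    "uniform_expected",
    "fit_poly_gaussian",
    "snowball_compare",
]

DEFAULT_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class ModelFit:
    """OLS polynomial fit summarised under the Gaussian likelihood."""

    degree: int
    coefficients: tuple[float, ...]  # intercept first, ascending powers
    rss: float
    loglik: float
    aic: float
    n: int
    degenerate: bool


@dataclass(frozen=True)
class SnowballComparison:
    linear: ModelFit
    quadratic: ModelFit

    @property
    def preferred_degree(self) -> int:
        return 2 if self.quadratic.aic < self.linear.aic else 1

    @property
    def preferred(self) -> ModelFit:
        return self.quadratic if self.preferred_degree == 2 else self.linear


def _chisq_p(statistic: float, df: int) -> float:
    # upper tail via the regularized upper incomplete gamma; at df=2 this
    # reduces to exp(-x/2)
    return float(gammaincc(df / 2.0, statistic / 2.0))


def chisq_gof(
    observed: Sequence[float], expected: Sequence[float]
) -> ChiSquareResult:
    """Pearson goodness-of-fit test of observed counts against expectation."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and expected must be equal-length, length >= 2")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    if np.any(obs < 0):
        raise ValueError("observed counts must be nonnegative")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return ChiSquareResult(statistic, df, _chisq_p(statistic, df))


def chisq_homogeneity(group_counts: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson homogeneity test on an r x k contingency table (no continuity
    correction).  Zero row or column marginals are an error, not a 0/0."""
    table = np.asarray(group_counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("every row and column marginal must be positive")
    expected = np.outer(rows, cols) / table.sum()
    statistic = float(np.sum((table - expected) ** 2 / expected))
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return ChiSquareResult(statistic, df, _chisq_p(statistic, df))


def sidak_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold controlling the family-wise
    error at ``alpha`` over ``m`` independent comparisons: 1-(1-alpha)^(1/m)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def uniform_expected(total: float, k: int) -> list[float]:
    """Uniform allocation of ``total`` events over ``k`` classes (the null of
    the stage-distribution test: lethals spread evenly across development)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return [total / k] * k


def fit_poly_gaussian(
    data: SnowballDataset,
    degree: int,
    rss_floor: float = DEFAULT_RSS_FLOOR,
    form: Literal["full", "pure"] = "full",
) -> ModelFit:
    """OLS polynomial fit with Gaussian-MLE log-likelihood and AIC.

    ``form="full"`` fits the complete polynomial with intercept;
    ``form="pure"`` fits count = c * x^degree through the origin (sensitivity
    mode).  Requires n > degree + 1 observations and at least degree + 1
    distinct abscissae (degree 1 distinct point for "pure").
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(data.xs, dtype=float)
    y = np.asarray(data.ys, dtype=float)
    n = x.size
    if n <= degree + 1:
        raise ValueError(
            f"need more than {degree + 1} points for a degree-{degree} fit, got {n}"
        )
    n_coef = 1 if form == "pure" else degree + 1
    n_distinct = np.unique(x).size
    if n_distinct < n_coef:
        raise ValueError(
            f"collinear design: {n_distinct} distinct abscissae but "
            f"{n_coef} coefficients to fit"
        )
    if form == "pure":
        design = x[:, None] ** degree
    else:
        design = np.vander(x, n_coef, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    k = n_coef + 1  # coefficients plus the residual scale
    if rss < rss_floor:
        return ModelFit(degree, tuple(coef), rss, math.inf, -math.inf, n, True)
    loglik = -(n / 2.0) * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)
    aic = 2.0 * k - 2.0 * loglik
    return ModelFit(degree, tuple(coef), rss, loglik, aic, n, False)


def snowball_compare(
    data: SnowballDataset,
    rss_floor: float = DEFAULT_RSS_FLOOR,
    form: Literal["full", "pure"] = "full",
) -> SnowballComparison:
    """Fit linear and quadratic growth of incompatibility count with
    divergence; the lower-AIC model is preferred.  A degenerate (exactly
    interpolating) quadratic is preferred with its flag surfaced."""
    linear = fit_poly_gaussian(data, 1, rss_floor, form="full")
    quadratic = fit_poly_gaussian(data, 2, rss_floor, form=form)
    return SnowballComparison(linear, quadratic)
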