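"""Regression and rank-test machinery for phantom cohorts and erosion traces.

Three regression forms cover the relationships measured here: a straight
line, a full quadratic, and a quadratic forced through the origin.  The
zero-intercept form exists for the negative SMI component: when the concave
fraction is 0 the negative component must be 0, so its fit against CF (or
BV/TV) has no constant term.  Group comparisons use the Wilcoxon–Mann–
Whitney rank-sum test, exact for small samples without ties.  No
multiple-comparison adjustment is applied: the intent is to characterize
specific pairwise relationships, collinearity included, not to screen a
table of post-hoc contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["RegressionResult", "fit", "wilcoxon_rank_sum", "MODELS"]

MODELS = ("linear", "quadratic", "quadratic_zero_intercept")


@dataclass
class RegressionResult:
    """An ordinary-least-squares fit.

    ``coefficients`` are ordered (intercept, x[, x^2]) for the models with a
    constant and (x, x^2) for the zero-intercept quadratic.  ``r_squared``
    follows the convention of R's ``lm``: centered total sum of squares when
    an intercept is present, uncentered otherwise.  ``p_value`` is the
    F-test of the fitted model against the trivial one.
    """

    model: str
    coefficients: np.ndarray
    r_squared: float
    p_value: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        X = _design(x, self.model)
        return X @ self.coefficients


def _design(x: np.ndarray, model: str) -> np.ndarray:
    if model == "linear":
        return np.column_stack([np.ones_like(x), x])
    if model == "quadratic":
        return np.column_stack([np.ones_like(x), x, x**2])
    if model == "quadratic_zero_intercept":
        return np.column_stack([x, x**2])
    raise ValueError(f"model must be one of {MODELS}, got {model!r}")


def fit(x, y, model: str = "linear") -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` for one of the three model forms."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    X = _design(x, model)
    if len(x) < X.shape[1] + 1:
        raise ValueError(
            f"need at least {X.shape[1] + 1} observations for model {model!r}, got {len(x)}"
        )
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    res = sm.OLS(y, X).fit()
    p = float(res.f_pvalue)
    if math.isnan(p):  # perfect fit: zero residual variance
        p = 0.0
    return RegressionResult(
        model=model,
        coefficients=np.asarray(res.params, dtype=np.float64),
        r_squared=float(res.rsquared),
        p_value=p,
        n=len(x),
    )


def _rank_sum_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: len(a)].sum())


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney rank-sum test, two-sided.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``sample_a``.  With
    ``n_a + n_b <= 20`` and no ties the p-value is exact, computed by
    enumerating all assignments of ranks to group A; otherwise the normal
    approximation with tie correction (and continuity correction) is used.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    N = n_a + n_b
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < N
    W = _rank_sum_statistic(a, b)

    if N <= 20 and not has_ties:
        ranks = np.arange(1, N + 1)
        mean_W = n_a * (N + 1) / 2.0
        dev = abs(W - mean_W)
        count = 0
        total = 0
        for comb in itertools.combinations(ranks, n_a):
            total += 1
            if abs(sum(comb) - mean_W) >= dev - 1e-12:
                count += 1
        return W, count / total

    # normal approximation with tie correction
    ranks = sps.rankdata(combined)
    mean_W = n_a * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var_W = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    if var_W <= 0:
        return W, 1.0
    z = (abs(W - mean_W) - 0.5) / math.sqrt(var_W)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return W, float(min(p, 1.0))
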