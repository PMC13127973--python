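"""Association statistics: correlations with CIs, Welch t-tests, Cohen's d,
the exploratory correlation matrix, and moderated regressions.

Conventions follow standard psychology reporting: Pearson r with a Fisher-z
95% confidence interval and a t-distributed p on n − 2 df; Welch's t with
Satterthwaite (fractional) df paired with a pooled-SD Cohen's d; moderation
as OLS of y on x, m and their product, all three variables z-standardized
before the product is formed, so coefficients are standardized betas.

Missing data: pairwise-complete deletion for correlations (each matrix cell
has its own n), listwise for regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| > 1")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float  # Cohen's d (pooled SD)


def _pairwise_complete(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_ci(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval.

    Missing values are removed pairwise; requires n >= 4 complete pairs and
    non-zero variance in both vectors. The p-value is two-sided from the t
    distribution with n − 2 df; the CI is tanh(atanh(r) ± z_(1−α/2)/√(n−3)).
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"pearson_ci requires n >= 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if abs(r) < 1.0:
        z = np.arctanh(r)
        half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        ci_low = ci_high = r
    return CorrelationResult(r=r, n=n, ci_low=ci_low, ci_high=ci_high, p=float(p))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled (n-weighted, ddof=1) standard deviation."""
    nx, ny = x.size, y.size
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def welch_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sample Welch t-test with Satterthwaite df and pooled-SD Cohen's d.

    Requires two groups of n >= 2 with non-zero variance in at least one
    group. Positive t/d mean the first group's mean is larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            # degenerate null: identical constant groups
            return TTestResult(t=0.0, df=float(x.size + y.size - 2), p=1.0, d=0.0)
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), d=cohens_d(x, y))


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Paired t-test; d is the pooled-SD standardized mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired test needs two equal-length groups with n >= 2")
    diff = x - y
    if np.var(diff, ddof=1) == 0:
        return TTestResult(t=0.0, df=float(x.size - 1), p=1.0, d=cohens_d(x, y))
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=float(x.size - 1), p=float(res.pvalue), d=cohens_d(x, y))


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    cells: dict  # (row_var, col_var) -> CorrelationResult | None
    formatted: pd.DataFrame  # lower-triangular strings "r***"

    def get(self, a: str, b: str) -> CorrelationResult | None:
        return self.cells.get((a, b)) or self.cells.get((b, a))


def correlation_matrix(
    features: pd.DataFrame,
    variables: Sequence[str],
    holm: bool = False,
) -> CorrelationMatrix:
    """Lower-triangular Pearson matrix with significance stars and per-cell n.

    Each cell uses pairwise-complete deletion, so n varies by cell. A
    constant variable leaves its cells marked unavailable rather than
    failing the whole matrix. ``holm=True`` applies a Holm step-down
    correction to the stars' p-values (off by default — exploratory
    reporting convention).
    """
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    cells: dict[tuple[str, str], CorrelationResult | None] = {}
    order = list(variables)
    for i, row in enumerate(order):
        for j, col in enumerate(order[:i]):
            try:
                cells[(row, col)] = pearson_ci(features[row], features[col])
            except ValueError:
                cells[(row, col)] = None
    if holm:
        keyed = [(k, c) for k, c in cells.items() if c is not None]
        adj = holm_bonferroni([c.p for _, c in keyed])
        for (k, c), p_adj in zip(keyed, adj):
            cells[k] = CorrelationResult(r=c.r, n=c.n, ci_low=c.ci_low, ci_high=c.ci_high, p=p_adj)
    formatted = pd.DataFrame("", index=order, columns=order, dtype=str)
    for (row, col), cell in cells.items():
        formatted.loc[row, col] = (
            "NA" if cell is None else f"{cell.r:.2f}{_stars(cell.p)} (n={cell.n})"
        )
    return CorrelationMatrix(variables=tuple(order), cells=cells, formatted=formatted)


def holm_bonferroni(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


# ---------------------------------------------------------------------------
# Moderated regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModerationFit:
    """OLS fit of y ~ x + m + x·m on standardized variables.

    ``coefficients`` has rows predictor/moderator/interaction with columns
    beta, se, t, p, ci_low, ci_high. A significant interaction indicates the
    x→y association depends on the level of m.
    """

    coefficients: pd.DataFrame
    n: int
    r_squared: float

    @property
    def interaction(self) -> pd.Series:
        return self.coefficients.loc["interaction"]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def moderated_regression(
    y: Sequence[float],
    x: Sequence[float],
    m: Sequence[float],
) -> ModerationFit:
    """Standardized moderation model: z(y) ~ z(x) + z(m) + z(x)·z(m).

    Complete cases only; the product term is formed after standardization,
    so the x and m coefficients are simple slopes at the mean of the other
    variable. Requires n > 4 and a full-rank design.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x) | np.isnan(m))
    y, x, m = y[keep], x[keep], m[keep]
    n = y.size
    if n <= 4:
        raise ValueError(f"moderated regression requires n > 4 complete cases, got {n}")
    zy, zx, zm = _zscore(y), _zscore(x), _zscore(m)
    X = sm.add_constant(np.column_stack([zx, zm, zx * zm]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (x, m or x·m collinear)")
    fit = sm.OLS(zy, X).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = ["predictor", "moderator", "interaction"]
    table = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
        },
        index=rows,
    )
    return ModerationFit(coefficients=table, n=n, r_squared=float(fit.rsquared))
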