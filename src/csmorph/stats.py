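"""Statistical toolkit: Welch's t with a pooled-SD Cohen's d, uncorrected
2x2 chi-square with the phi effect size, Pearson correlation, and simple
linear regression.

Conventions fixed here and used throughout the analysis:

* Welch's t-test (unequal variances, Satterthwaite df), two-sided p.
* Cohen's d uses the classical pooled standard deviation and an absolute
  value: d = |mu1 - mu2| / sqrt(((N1-1)s1^2 + (N2-1)s2^2) / (N1+N2-2)),
  i.e. it is not Welch-adjusted and is always >= 0.
* The chi-square test applies NO Yates continuity correction, and
  phi = sqrt(chi2 / (N1+N2)) with N1+N2 the table total.
* Pearson p-values come from the t transform with n-2 df; regression
  intercept/slope p-values from their standard errors (OLS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps
import statsmodels.api as sm

__all__ = ["WelchResult", "Chi2Result", "CorrRegResult",
           "welch_t_d", "cohens_d_pooled", "chi2_phi", "pearson_r", "ols_fit"]


class DegenerateInputError(ValueError):
    """Inputs admit no meaningful statistic (e.g. two zero-variance samples)."""


@dataclass(frozen=True)
class WelchResult:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    df: float
    p: float
    d: float


@dataclass(frozen=True)
class Chi2Result:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p: float
    phi: float


@dataclass(frozen=True)
class CorrRegResult:
    n: int
    r: float
    p_r: float
    intercept: float
    slope: float
    p_intercept: float
    p_slope: float


def cohens_d_pooled(x, y) -> float:
    """Absolute standardized mean difference with the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    diff = abs(x.mean() - y.mean())
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise DegenerateInputError("zero pooled SD with unequal means")
    return diff / pooled


def welch_t_d(x, y) -> WelchResult:
    """Welch's two-sided t-test plus the pooled-SD effect size d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"each sample needs >= 2 values, got {len(x)} and {len(y)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            t, df, p = 0.0, float(len(x) + len(y) - 2), 1.0
        else:
            raise DegenerateInputError("both variances zero with unequal means")
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    return WelchResult(
        n1=len(x), n2=len(y),
        mean1=float(x.mean()), mean2=float(y.mean()),
        sd1=float(x.std(ddof=1)), sd2=float(y.std(ddof=1)),
        t=t, df=df, p=p, d=cohens_d_pooled(x, y),
    )


def chi2_phi(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Uncorrected Pearson chi-square on the 2x2 table ((a, b), (c, d)).

    Rows are groups (sizes N1 = a+b, N2 = c+d); phi = sqrt(chi2 / (N1+N2)).
    A zero column yields chi2 = 0, phi = 0, p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("each group (row) must contain at least one observation")
    if (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        res = sps.chi2_contingency(table, correction=False)
        chi2, p = float(res.statistic), float(res.pvalue)
    phi = math.sqrt(chi2 / table.sum())
    return Chi2Result(table=((a, b), (c, d)), chi2=chi2, p=p, phi=phi)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment r and two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant variable")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x, y) -> CorrRegResult:
    """Simple linear regression y ~ x with intercept, plus Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("singular design: x is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if np.ptp(y) == 0:
        r, p_r = 0.0, 1.0  # flat response: correlation degenerate, slope 0
    else:
        r, p_r = pearson_r(x, y)
    return CorrRegResult(
        n=len(x), r=r, p_r=p_r,
        intercept=float(model.params[0]), slope=float(model.params[1]),
        p_intercept=float(model.pvalues[0]), p_slope=float(model.pvalues[1]),
    )
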