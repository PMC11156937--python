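"""Rater-agreement statistics: absolute-agreement ICCs and Cohen's d.

Two intraclass-correlation forms are used to compare detector estimates of
the gold-standard outcomes against expert annotation, and to quantify
day-to-day stability of daily %TF:

* ICC(2,1) — two-way random-effects, absolute agreement, single measure
  (Shrout-Fleiss form 2,1): each subject rated by the same set of raters
  (here: expert annotation vs. one model), and a single rating is the unit
  of analysis.
* ICC(A,k) — two-way, absolute agreement, average of k measures
  (McGraw-Wong A,k; here k = 6 recording days): how reliable is the mean
  across k repeated days.

Both are computed from the two-way ANOVA mean squares (rows = subjects,
columns = raters/days); 95% confidence intervals use the F-distribution
method of McGraw & Wong.  The random- vs. mixed-effects distinction changes
interpretation only, not the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError, ValidationError


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    f_value: float
    df1: float
    df2: float
    p_value: float
    form: str
    n: int
    k: int


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (rows x columns, no replication) mean squares.

    Returns (MSR, MSC, MSE, n, k): rows (subjects), columns (raters),
    residual.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D (subjects x raters) array")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValidationError("ICC requires at least 3 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValidationError("missing cells are not supported; restrict to complete rows")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse, n, k


def _single_measure_ci(msr, msc, mse, n, k, alpha=0.05):
    """McGraw-Wong F-based CI for the absolute-agreement single-measure ICC."""
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0 and msc == 0:
        return icc, (icc, icc)
    denom = n * (1 - icc)
    if denom <= 0:  # icc == 1 exactly
        return icc, (icc, icc)
    a = k * icc / denom
    b = 1 + k * icc * (n - 1) / denom
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else np.inf
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return icc, (float(lower), float(upper))


def _check_variance(msr, msc, mse):
    if msr == 0 and msc == 0 and mse == 0:
        raise UndefinedMetricError("ICC undefined: zero total variance in ratings")


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC."""
    msr, msc, mse, n, k = _anova_mean_squares(ratings)
    _check_variance(msr, msc, mse)
    icc, ci = _single_measure_ci(msr, msc, mse, n, k, alpha)
    f = msr / mse if mse > 0 else np.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return ICCResult(float(icc), ci, float(f), df1, df2, p,
                     form="icc_2_1_absolute_single", n=n, k=k)


def icc_a_k(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way, absolute-agreement, mean-of-k-measures ICC (A,k).

    Used for day-to-day stability of daily %TF over the first k = 6
    complete recording days; subjects with fewer days are excluded rather
    than imputed.
    """
    msr, msc, mse, n, k = _anova_mean_squares(ratings)
    _check_variance(msr, msc, mse)
    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    _, (l1, u1) = _single_measure_ci(msr, msc, mse, n, k, alpha)

    def k_transform(r):
        return r * k / (1 + r * (k - 1)) if np.isfinite(r) else r

    ci = (float(k_transform(l1)), float(k_transform(u1)))
    f = msr / mse if mse > 0 else np.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return ICCResult(float(icc_k), ci, float(f), df1, df2, p,
                     form="icc_a_k_absolute_mean", n=n, k=k)


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference with df-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise UndefinedMetricError("Cohen's d undefined: zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
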