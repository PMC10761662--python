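"""Interobserver agreement statistics for rater x subject measurement tables.

Implements the single-rater, absolute-agreement intraclass correlation from
the two-way random-effects model, ICC(2,1),

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

where MSR, MSC and MSE are the subject, rater and residual mean squares of
the two-way ANOVA decomposition of an n-subject x k-rater table.  The 95%
confidence interval follows the F-based approximation of McGraw & Wong
(1996), with a Satterthwaite-style degrees-of-freedom estimate.  Point
estimates are banded on the conventional agreement scale (none-to-slight /
fair / moderate / substantial / almost-perfect).

Also provided: Bland-Altman limits of agreement, the Wilcoxon signed-rank
test (exact null distribution for small samples, tie- and continuity-
corrected normal approximation otherwise), and median/IQR summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pelvimetry")

#: Agreement bands: (upper inclusive bound of the rounded ICC, band name).
#: ICC <= 0 is "no"; printed ranges 0.01-0.20, 0.21-0.40, 0.41-0.60,
#: 0.61-0.80, 0.81-1.00 are treated as closed intervals.
_BANDS = [(0.20, "none-to-slight"), (0.40, "fair"), (0.60, "moderate"),
          (0.80, "substantial"), (1.00, "almost-perfect")]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n: int
    k: int
    flags: tuple[str, ...] = ()


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int
    significant: bool
    method: str = "exact"
    flags: tuple[str, ...] = ()


def band_of(icc: float) -> str:
    """Band an ICC on the conventional agreement scale.

    Values are rounded half-up to two decimals before banding, matching how
    two-decimal published values are assigned to the printed closed ranges;
    values at or below zero indicate no agreement.
    """
    rounded = math.floor(icc * 100 + 0.5) / 100 if icc >= 0 else icc
    if rounded <= 0:
        return "no"
    for upper, name in _BANDS:
        if rounded <= upper + 1e-12:
            return name
    return "almost-perfect"


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way crossed layout without replication."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_two_way_random_absolute(table, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    *table* is an (n subjects) x (k raters) array with no missing cells.
    A table with zero total variance (every cell identical) is defined as
    perfect agreement (ICC 1.0) with a degenerate-variance warning.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 rating table")
    if np.isnan(table).any():
        raise ValueError("missing cells are not allowed; drop incomplete "
                         "subjects first")
    n, k = table.shape
    msr, msc, mse = _anova_mean_squares(table)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.allclose(table, table.flat[0]):
        logger.warning("WARN degenerate rating table (zero variance); "
                       "ICC defined as 1.0")
        return ICCResult(1.0, 1.0, 1.0, band_of(1.0), n, k,
                         flags=("degenerate_variance",))
    icc = (msr - mse) / denom

    # McGraw-Wong F-based CI with Satterthwaite df for the rater term
    if mse > 0:
        fj = msc / mse
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        vn = (k - 1) * (n - 1) * (
            (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2)
        vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
              + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
        v = vn / vd
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
        del a
    else:  # MSE == 0: raters agree exactly on every subject
        lo = hi = icc
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ICCResult(float(icc), lo, hi, band_of(float(icc)), n, k)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement: mean difference and 95% limits of agreement.

    The difference is ``x - y`` (first method minus second); limits are
    mean ± 1.96 x SD of the differences (SD with n-1 denominator).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    diffs = x - y
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(mean_diff=mean_diff,
                             loa_low=mean_diff - 1.96 * sd,
                             loa_high=mean_diff + 1.96 * sd,
                             means=(x + y) / 2.0, diffs=diffs)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic under H0.

    Counts sign assignments by dynamic programming over doubled ranks
    (midranks are multiples of 1/2, so doubling gives integers).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y=None, *, exact_threshold: int = 25
                         ) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's method); absolute differences
    are ranked with midranks for ties.  The exact null distribution is
    enumerated whenever the effective sample size is at most
    *exact_threshold*; larger samples use the normal approximation with tie
    correction and a 0.5 continuity correction.  The reported statistic is
    min(W+, W-).
    """
    x = np.asarray(x, dtype=float).ravel()
    if y is None:
        d = x
    else:
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("paired inputs must have equal length")
        d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("WARN all paired differences are zero; test carries "
                       "no information")
        return PairedTestResult(0.0, 1.0, 0, False, method="degenerate",
                                flags=("all_zero_diffs",))
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= exact_threshold:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        dev = w_plus - mu
        z = (dev - 0.5 * np.sign(dev)) / math.sqrt(sigma2) if dev != 0 else 0.0
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal-approx"
    return PairedTestResult(statistic=statistic, p_value=p, n_effective=n,
                            significant=bool(p < 0.050), method=method)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) via the linear-interpolation quantile rule."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


# -- rating-table plumbing ---------------------------------------------------

def pivot_ratings(df: pd.DataFrame, measurement: str, session=None
                  ) -> np.ndarray:
    """Subjects x raters matrix from a long-format ratings table.

    Expects columns ``case_id``, ``measurement``, ``rater``, ``value_mm``
    and optionally ``session``.  Subjects with any missing rater are dropped
    and logged.
    """
    sub = df[df["measurement"] == measurement]
    if session is not None and "session" in df.columns:
        sub = sub[sub["session"] == session]
    wide = sub.pivot_table(index="case_id", columns="rater",
                           values="value_mm", aggfunc="mean")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("WARN dropping %d subject(s) with missing raters: %s",
                       len(incomplete), list(incomplete))
        wide = wide.dropna()
    return wide.to_numpy(dtype=float)


def agreement_summary(df: pd.DataFrame) -> pd.DataFrame:
    """ICC(2,1) per (measurement, session) from a long ratings table."""
    rows = []
    sessions = (sorted(df["session"].unique()) if "session" in df.columns
                else [None])
    for meas, sess in itertools.product(sorted(df["measurement"].unique()),
                                        sessions):
        table = pivot_ratings(df, meas, session=sess)
        if table.shape[0] < 2 or table.shape[1] < 2:
            logger.warning("WARN %s/%s: too few complete subjects or raters "
                           "for ICC", meas, sess)
            continue
        res = icc_two_way_random_absolute(table)
        rows.append({"measurement": meas, "session": sess, "icc": res.icc,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "band": res.band, "n": res.n, "k": res.k})
    return pd.DataFrame(rows)


def bland_altman_plot(result: BlandAltmanResult, ax=None, title: str = ""):
    """Render the classic Bland-Altman plot (mean vs difference)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    ax.axhline(result.mean_diff, color="black", linestyle="--",
               label=f"mean diff {result.mean_diff:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="red", linestyle="--")
    ax.set_xlabel("mean of pair (mm)")
    ax.set_ylabel("difference (mm)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
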