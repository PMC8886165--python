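"""Reliability and agreement statistics for repeated measurements.

Intra-/inter-rater reliability of the subacromial measurements uses the
single-measure two-way mixed-model intraclass correlation coefficient.
In the default consistency form (ICC(3,1)):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE)

where MSR and MSE are the between-target and residual mean squares of the
two-way (targets x raters) ANOVA with k raters/sessions.  From the ICC,

    SEM = pooled SD * sqrt(1 - ICC)
    MDC = 1.96 * sqrt(2) * SEM

give the standard error of measurement and the minimal detectable change —
the smallest change exceeding measurement noise with 95% confidence.  All
intermediates stay at full precision; rounding is a display concern only.
Agreement between two measurement channels uses Bland-Altman limits of
agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import PairingError, UndefinedICCError

__all__ = [
    "RatingsTable",
    "ReliabilityResult",
    "BlandAltmanResult",
    "anova_mean_squares",
    "icc_two_way_mixed",
    "pooled_sd",
    "sem",
    "mdc",
    "reliability_summary",
    "bland_altman",
    "bland_altman_plot",
]

MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class RatingsTable:
    """Complete m x k matrix of measurements.

    Rows are the rated targets (video clips); columns are raters or
    sessions.  The design must be complete: no missing cells.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2-D matrix")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"need >= 2 rows and >= 2 columns, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("ratings table must be complete (no missing cells)")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    mdc: float
    pooled_sd: float


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


def anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way (rows x columns) ANOVA mean squares (MSR, MSC, MSE)."""
    v = np.asarray(values, dtype=float)
    m, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = m * np.sum((col_means - grand) ** 2)
    sst = np.sum((v - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (m - 1)
    msc = ssc / (k - 1)
    mse = sse / ((m - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_mixed(
    table: RatingsTable | np.ndarray,
    model: str = "consistency",
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Single-measure two-way mixed-model ICC with an F-based confidence interval.

    ``model='consistency'`` (ICC(3,1), the default) ignores systematic
    rater offsets; ``model='agreement'`` (ICC(A,1) under the mixed model)
    penalises them, with a Satterthwaite-approximated interval.

    Raises
    ------
    UndefinedICCError
        When there is no between-target variance (e.g. a constant table),
        so the ratio is meaningless.
    """
    if not isinstance(table, RatingsTable):
        table = RatingsTable(np.asarray(table))
    v = table.values
    m, k = table.m, table.k
    msr, msc, mse = anova_mean_squares(v)
    if msr <= 0:
        raise UndefinedICCError(
            "between-target variance is zero; ICC is undefined"
        )
    alpha = 1.0 - confidence
    if model == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            return float(icc), (float(icc), float(icc))
        df1, df2 = m - 1, (m - 1) * (k - 1)
        f_obs = msr / mse
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif model == "agreement":
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / m) * (msc - mse))
        # McGraw & Wong ICC(A,1) interval, Satterthwaite df for the
        # column+error composite.
        a = (k * icc) / (m * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (m - 1)) / (m * (1 - icc)) if icc < 1 else np.inf
        if not np.isfinite(a) or mse == 0:
            return float(icc), (float(icc), float(icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((m - 1) * (k - 1))
        nu = num / den
        f1 = stats.f.ppf(1 - alpha / 2, m - 1, nu)
        f2 = stats.f.ppf(1 - alpha / 2, nu, m - 1)
        lo = (m * (msr - f1 * mse)) / (
            f1 * (k * msc + (k * m - k - m) * mse) + m * msr
        )
        hi = (m * (f2 * msr - mse)) / (
            k * msc + (k * m - k - m) * mse + m * f2 * msr
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return float(icc), (lo, hi)


def pooled_sd(values: np.ndarray) -> float:
    """Pooled standard deviation across columns: per-column sample
    variances averaged, then square-rooted."""
    v = np.asarray(values, dtype=float)
    return float(np.sqrt(np.mean(np.var(v, axis=0, ddof=1))))


def sem(pooled_sd_value: float, icc: float) -> float:
    """Standard error of measurement: pooled SD * sqrt(1 - ICC)."""
    if pooled_sd_value < 0:
        raise ValueError("pooled SD must be non-negative")
    if icc > 1:
        raise ValueError(f"ICC must be <= 1, got {icc}")
    return float(pooled_sd_value * math.sqrt(1.0 - icc))


def mdc(sem_value: float) -> float:
    """Minimal detectable change: 1.96 * sqrt(2) * SEM."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return float(MDC_FACTOR * sem_value)


def reliability_summary(
    table: RatingsTable | np.ndarray,
    model: str = "consistency",
    confidence: float = 0.95,
) -> ReliabilityResult:
    """ICC + CI, SEM and MDC for one ratings table, all from unrounded
    intermediates."""
    if not isinstance(table, RatingsTable):
        table = RatingsTable(np.asarray(table))
    icc, (lo, hi) = icc_two_way_mixed(table, model=model, confidence=confidence)
    psd = pooled_sd(table.values)
    s = sem(psd, icc)
    return ReliabilityResult(
        icc=icc, ci_low=lo, ci_high=hi, sem=s, mdc=mdc(s), pooled_sd=psd
    )


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Differences d = a - b; limits of agreement are mean(d) +/- 1.96 * SD(d)
    with the sample (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(
            f"paired 1-D sequences of equal length required, got {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise PairingError("need at least 2 pairs")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n_pairs=int(a.size),
    )


def bland_altman_plot(a: np.ndarray, b: np.ndarray, ax=None):
    """Standard Bland-Altman plot: per-pair mean vs difference with the bias
    line and 95% limits of agreement.  Requires matplotlib."""
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=18, alpha=0.8)
    ax.axhline(res.mean_diff, color="k", label=f"bias {res.mean_diff:.3g}")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="gray", linestyle="--")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    ax.legend()
    return ax
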