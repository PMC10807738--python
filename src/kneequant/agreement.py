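"""Method-agreement statistics: ICC(A,1), Bland–Altman, mean absolute error.

The intraclass correlation implemented here is the two-way model,
absolute-agreement, single-measures coefficient — ICC(A,1) in McGraw & Wong's
nomenclature, "two-way mixed, absolute agreement, single measures" in SPSS —
computed from the two-way ANOVA decomposition:

    MSR  between-subject mean square
    MSC  between-rater (method) mean square
    MSE  residual mean square

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with the F-distribution confidence interval of McGraw & Wong (1996).  The
average-measures variant ICC(A,k) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "PairedMeasurements",
    "AgreementSummary",
    "icc_absolute_agreement",
    "bland_altman",
    "mean_absolute_error",
    "summarize_agreement",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two equal-length vectors of one quantity measured by two methods/runs."""

    method1: np.ndarray
    method2: np.ndarray
    labels: np.ndarray | None = None   # optional stratum labels (e.g. severity grade)

    def __post_init__(self) -> None:
        a = np.asarray(self.method1, dtype=float)
        b = np.asarray(self.method2, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("need two 1-D vectors of equal length")
        keep = np.isfinite(a) & np.isfinite(b)     # pairwise deletion
        object.__setattr__(self, "method1", a[keep])
        object.__setattr__(self, "method2", b[keep])
        if self.labels is not None:
            object.__setattr__(self, "labels", np.asarray(self.labels)[keep])

    @property
    def n(self) -> int:
        return len(self.method1)

    @property
    def differences(self) -> np.ndarray:
        return self.method1 - self.method2


@dataclass(frozen=True)
class AgreementSummary:
    icc: float
    icc_ci95: tuple[float, float]
    mean_difference: float
    loa_lower: float       # mean difference − 1.96·SD
    loa_upper: float       # mean difference + 1.96·SD
    mae: float
    mae_sd: float
    n: int


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares for an n-subjects × k-raters table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse


def icc_absolute_agreement(pm: PairedMeasurements, alpha: float = 0.05,
                           average_measures: bool = False
                           ) -> tuple[float, tuple[float, float]]:
    """ICC(A,1) (or ICC(A,k)) with its F-based confidence interval.

    Raises on zero total variance, where the ICC is undefined.  Two identical
    nonconstant columns give exactly 1.0 with a degenerate (1, 1) interval —
    the analytic limit of the formula as the residual variance vanishes.
    """
    if pm.n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    x = np.column_stack([pm.method1, pm.method2])
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("zero total variance: ICC undefined for constant data")
    if np.array_equal(pm.method1, pm.method2):
        # exact agreement: the analytic limit of the formula as MSE, MSC -> 0
        return 1.0, (1.0, 1.0)
    msr, msc, mse = _mean_squares(x)

    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong (1996) CI for ICC(A,1)
    a = k * icc1 / (n * (1 - icc1)) if icc1 != 1.0 else np.inf
    b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 != 1.0 else np.inf
    if np.isinf(a):
        lo1, hi1 = 1.0, 1.0
    else:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi1 = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
    if average_measures:
        def avg(r: float) -> float:
            return 1.0 if r == 1.0 else k * r / (1 + (k - 1) * r)
        icck = (msr - mse) / (msr + (msc - mse) / n)
        return float(icck), (float(avg(lo1)), float(avg(hi1)))
    return float(icc1), (float(lo1), float(hi1))


def bland_altman(pm: PairedMeasurements) -> tuple[float, float, tuple[float, float]]:
    """Mean difference, SD of differences, and 95% limits of agreement."""
    if pm.n < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    d = pm.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


def mean_absolute_error(pm: PairedMeasurements) -> tuple[float, float]:
    """Mean and SD of the absolute paired differences."""
    if pm.n < 1:
        raise ValueError("need at least 1 pair")
    ad = np.abs(pm.differences)
    sd = float(ad.std(ddof=1)) if pm.n > 1 else 0.0
    return float(ad.mean()), sd


def summarize_agreement(pm: PairedMeasurements) -> AgreementSummary:
    icc, ci = icc_absolute_agreement(pm)
    mean, _sd, (lo, hi) = bland_altman(pm)
    mae, mae_sd = mean_absolute_error(pm)
    return AgreementSummary(icc=icc, icc_ci95=ci, mean_difference=mean,
                            loa_lower=lo, loa_upper=hi, mae=mae, mae_sd=mae_sd,
                            n=pm.n)


def bland_altman_plot(pm: PairedMeasurements, ax=None, title: str = ""):
    """Bland–Altman scatter: mean on x, difference on y, green mean line,
    red limit lines."""
    import matplotlib.pyplot as plt

    mean, _sd, (lo, hi) = bland_altman(pm)
    if ax is None:
        _fig, ax = plt.subplots()
    m = (pm.method1 + pm.method2) / 2
    ax.scatter(m, pm.differences, s=10, color="k", alpha=0.6)
    ax.axhline(mean, color="green")
    ax.axhline(lo, color="red", linestyle="--")
    ax.axhline(hi, color="red", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax
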