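"""Agreement statistics between two quantification pipelines.

Covers the validation summaries used to compare an MRI-less pipeline
against the MRI-based standard: ordinary-least-squares R²/slope (with the
slope bias expressed in percent), the intraclass correlation ICC(A,1)
(two-way model, absolute agreement, single rater), and relative variance
summaries (ratio of Centiloid SDs against a baseline pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "VarianceSummary",
    "regression_agreement",
    "icc_absolute_single",
    "relative_variance",
]


@dataclass
class AgreementReport:
    r2: float
    slope: float
    intercept: float
    n: int
    icc: float | None = None

    @property
    def slope_bias_percent(self) -> float:
        """Regression slope bias: (slope - 1) * 100, in percent."""
        return (self.slope - 1.0) * 100.0


@dataclass
class VarianceSummary:
    group_label: str
    n: int
    mean: float
    sd: float
    relative_variance: float


def regression_agreement(x, y) -> AgreementReport:
    """OLS of y on x with R²; slope bias available as (slope - 1) * 100%."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.var(x) <= 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return AgreementReport(r2=float(fit.rvalue ** 2), slope=float(fit.slope),
                           intercept=float(fit.intercept), n=int(x.size))


def icc_absolute_single(ratings) -> float:
    """ICC(A,1): two-way model, absolute agreement, single rater/measurement.

    From the two-way ANOVA mean squares of an n-subjects x k-raters table
    (k = 2 pipelines here):

        ICC(A,1) = (MS_R - MS_E) /
                   (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    where MS_R, MS_C and MS_E are the row (subject), column (rater) and
    residual mean squares.
    """
    data = np.asarray(ratings, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("ratings must be an n x k table with k >= 2")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        raise ValueError("degenerate ratings (no variance); ICC undefined")
    return float((ms_r - ms_e) / denom)


def relative_variance(sd_numerator: float, sd_baseline: float) -> float:
    """Ratio of standard deviations against the baseline pipeline's SD."""
    if sd_baseline <= 0:
        raise ValueError("baseline SD must be positive")
    if sd_numerator < 0:
        raise ValueError("SD cannot be negative")
    return float(sd_numerator) / float(sd_baseline)
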