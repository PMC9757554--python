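"""Test-retest repeatability statistics for paired FSV measurements.

Implements the two-way, absolute-agreement intraclass correlation
(McGraw & Wong's ICC(A,1) and ICC(A,k)) with F-based 95% confidence
intervals, the within-subject coefficient of variation, and Bland-Altman
agreement analysis, plus a report builder that summarises a cohort's
metrics table per group x slab x metric.

Notation: n subjects (eyes), k repeated measurements per subject; from the
two-way ANOVA decomposition MSR, MSC and MSE are the subject (row),
measurement (column) and residual mean squares.  Then

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

and ICC(A,k) equals the Spearman-Brown step-up of ICC(A,1).  Confidence
limits for ICC(A,1) use the F construction with Satterthwaite degrees of
freedom; the ICC(A,k) limits are the Spearman-Brown transform of the
single-measure limits.  Sample statistics use the n-1 denominator
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "PairedCohort",
    "ICCResult",
    "BlandAltmanResult",
    "icc_absolute_agreement",
    "coefficient_of_variation",
    "bland_altman",
    "build_report",
    "RepeatabilityReport",
]

logger = logging.getLogger(__name__)

ICCForm = Literal["single", "average"]
CVMode = Literal["rms", "mean"]


@dataclass(frozen=True)
class PairedCohort:
    """An n x k matrix of one metric: rows = eyes, columns = repeats."""

    values: np.ndarray = field(repr=False)
    metric_name: str = "area"
    group: str = ""
    slab: str = ""
    eye_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValidationError(f"values must be an n x k matrix, got shape {v.shape}")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValidationError(f"need n >= 2 subjects and k >= 2 repeats, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("values must be finite with no missing cells")
        if self.eye_ids is not None and len(self.eye_ids) != n:
            raise ValidationError("eye_ids length must match the number of rows")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    form: ICCForm
    estimate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    n: int = 0
    k: int = 0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between the two repeats: bias = mean(repeat1 - repeat2) and
    conventional 1.96-SD limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)


class _MeanSquares(NamedTuple):
    msr: float
    msc: float
    mse: float
    n: int
    k: int


def _two_way_mean_squares(values: np.ndarray) -> _MeanSquares:
    v = np.asarray(values, dtype=np.float64)
    n, k = v.shape
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    # anchoring the grand mean to the column means keeps MSC and MSE exactly
    # zero for identical repeat columns (perfect agreement stays ICC == 1.0)
    grand = col_means.mean()
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    resid = v - row_means[:, None] - col_means[None, :] + grand
    sse = float((resid ** 2).sum())
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return _MeanSquares(msr, msc, mse, n, k)


def _spearman_brown(r: float, k: int) -> float:
    denom = 1.0 + (k - 1) * r
    if denom == 0:
        return float("-inf")
    return k * r / denom


def _icc_a1_ci(ms: _MeanSquares, r: float, alpha: float) -> tuple[float, float]:
    """F-based confidence limits for ICC(A,1) with Satterthwaite df."""
    msr, msc, mse, n, k = ms
    if r >= 1.0:
        return 1.0, 1.0
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    if den <= 0:
        # no within-cell information at all; interval collapses on the estimate
        return r, r
    v = num / den
    fu = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    fl = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    low = n * (msr - fu * mse) / (fu * (k * msc + (k * n - k - n) * mse) + n * msr)
    high = n * (fl * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fl * msr)
    low, high = float(np.clip(low, -1.0, 1.0)), float(np.clip(high, -1.0, 1.0))
    return min(low, r), max(high, r)


def icc_absolute_agreement(
    cohort: PairedCohort, form: ICCForm = "single", alpha: float = 0.05
) -> ICCResult:
    """Two-way absolute-agreement ICC with its (1 - alpha) confidence interval.

    ``form='single'`` rates one measurement (ICC(A,1)); ``form='average'``
    rates the mean of the k repeats (ICC(A,k)).  Estimates are not truncated
    at zero.  Raises :class:`DegenerateInputError` when the matrix has zero
    total variance.
    """
    if form not in ("single", "average"):
        raise ValidationError(f"form must be 'single' or 'average', got {form!r}")
    ms = _two_way_mean_squares(cohort.values)
    msr, msc, mse, n, k = ms
    if msr == 0.0 and msc == 0.0 and mse == 0.0:
        raise DegenerateInputError("zero total variance: ICC undefined")
    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom_single == 0:
        raise DegenerateInputError("degenerate variance structure: ICC denominator is zero")
    r1 = (msr - mse) / denom_single
    low1, high1 = _icc_a1_ci(ms, r1, alpha)
    if form == "single":
        est, low, high = r1, low1, high1
    else:
        est = _spearman_brown(r1, k)
        low, high = _spearman_brown(low1, k), _spearman_brown(high1, k)
    return ICCResult(
        form=form, estimate=float(est), ci_low=float(low), ci_high=float(high),
        alpha=alpha, n=n, k=k,
    )


def coefficient_of_variation(cohort: PairedCohort, mode: CVMode = "rms") -> float:
    """Within-subject coefficient of variation, as a percentage.

    Per subject, cv_i = sd(repeats_i) / mean(repeats_i) (sample SD).  The
    cohort value is the root-mean-square of the cv_i (``mode='rms'``, the
    test-retest convention) or their arithmetic mean (``mode='mean'``).
    """
    if mode not in ("rms", "mean"):
        raise ValidationError(f"mode must be 'rms' or 'mean', got {mode!r}")
    v = cohort.values
    means = v.mean(axis=1)
    if np.any(means == 0):
        raise DegenerateInputError("a per-subject mean is zero: CV undefined")
    cvs = v.std(axis=1, ddof=1) / means
    if mode == "rms":
        return float(np.sqrt(np.mean(cvs ** 2)) * 100.0)
    return float(np.mean(cvs) * 100.0)


def bland_altman(cohort: PairedCohort) -> BlandAltmanResult:
    """Bland-Altman agreement for a two-repeat cohort (repeat1 - repeat2)."""
    if cohort.k != 2:
        raise ValidationError(f"Bland-Altman requires exactly 2 repeats, got k={cohort.k}")
    v = cohort.values
    diffs = v[:, 0] - v[:, 1]
    means = v.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        means=means, differences=diffs,
    )


class RepeatabilityReport(NamedTuple):
    """Cohort summary (one row per group x slab x metric) plus the per-eye
    Bland-Altman plot data."""

    report: pd.DataFrame
    bland_altman: pd.DataFrame


#: metric name -> column of the metrics table it summarises
DEFAULT_METRICS: dict[str, str] = {"area": "area_mm2", "n_contours": "n_contours"}

REPORT_COLUMNS = [
    "group", "slab", "metric", "n",
    "mean1", "sd1", "min1", "max1",
    "mean2", "sd2", "min2", "max2",
    "icc_single", "icc_single_ci_low", "icc_single_ci_high",
    "icc_average", "icc_average_ci_low", "icc_average_ci_high",
    "cv_percent", "ba_bias", "ba_loa_low", "ba_loa_high",
]


def _pivot_block(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    wide = df.pivot_table(index="eye_id", columns="repeat_index",
                          values=value_col, aggfunc="first")
    incomplete = wide.index[wide.isna().any(axis=1)]
    for eye in incomplete:
        logger.warning("excluding eye %s: missing repeat", eye)
    return wide.dropna()


def build_report(
    metrics: pd.DataFrame,
    metric_columns: dict[str, str] | None = None,
    cv_mode: CVMode = "rms",
    alpha: float = 0.05,
) -> RepeatabilityReport:
    """Summarise a per-scan metrics table into the repeatability report.

    ``metrics`` must carry columns eye_id, group, slab, repeat_index and the
    metric columns (defaults: area_mm2 for 'area' and n_contours).  Eyes
    missing one repeat are excluded from their block with a logged warning;
    a block left with fewer than two eyes is a validation error.
    """
    metric_columns = metric_columns or DEFAULT_METRICS
    required = {"eye_id", "group", "slab", "repeat_index"} | set(metric_columns.values())
    missing = required - set(metrics.columns)
    if missing:
        raise ValidationError(f"metrics table is missing columns {sorted(missing)}")

    rows: list[dict] = []
    ba_rows: list[dict] = []
    for (group, slab), block in metrics.groupby(["group", "slab"], sort=False):
        for metric_name, col in metric_columns.items():
            wide = _pivot_block(block, col)
            if len(wide) < 2:
                raise ValidationError(
                    f"block {group}/{slab}/{metric_name}: fewer than 2 complete eyes"
                )
            values = wide.to_numpy(dtype=np.float64)
            cohort = PairedCohort(
                values=values, metric_name=metric_name, group=str(group),
                slab=str(slab), eye_ids=tuple(map(str, wide.index)),
            )
            single = icc_absolute_agreement(cohort, "single", alpha)
            average = icc_absolute_agreement(cohort, "average", alpha)
            cv = coefficient_of_variation(cohort, cv_mode)
            ba = bland_altman(cohort)
            r1, r2 = values[:, 0], values[:, 1]
            rows.append({
                "group": group, "slab": slab, "metric": metric_name, "n": len(wide),
                "mean1": r1.mean(), "sd1": r1.std(ddof=1), "min1": r1.min(), "max1": r1.max(),
                "mean2": r2.mean(), "sd2": r2.std(ddof=1), "min2": r2.min(), "max2": r2.max(),
                "icc_single": single.estimate,
                "icc_single_ci_low": single.ci_low, "icc_single_ci_high": single.ci_high,
                "icc_average": average.estimate,
                "icc_average_ci_low": average.ci_low, "icc_average_ci_high": average.ci_high,
                "cv_percent": cv,
                "ba_bias": ba.bias, "ba_loa_low": ba.loa_low, "ba_loa_high": ba.loa_high,
            })
            for eye, m, d in zip(wide.index, ba.means, ba.differences):
                ba_rows.append({
                    "group": group, "slab": slab, "metric": metric_name,
                    "eye_id": eye, "mean": m, "difference": d,
                })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    ba_df = pd.DataFrame(
        ba_rows, columns=["group", "slab", "metric", "eye_id", "mean", "difference"]
    )
    return RepeatabilityReport(report=report, bland_altman=ba_df)
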