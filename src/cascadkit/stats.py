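"""Longitudinal efficacy statistics for score tables.

Implements the reporting conventions of a small paired longitudinal study:
mean +/- sample SD summaries, median (IQR) by linear interpolation of order
statistics, a Shapiro-Wilk normality gate choosing between the paired t-test
and the Wilcoxon signed-rank test on paired differences, and per-visit
treatment-response rate tables.

The Wilcoxon signed-rank test is implemented here rather than delegated:
zero differences are dropped (Wilcoxon's original rule), tied absolute
differences are mid-ranked, and for n <= 12 retained pairs the two-sided
p-value is exact over all 2^n sign assignments of the observed mid-ranks
(computed by convolving the rank distribution, so ties are handled exactly);
larger n uses the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .scoring import ResponseCategory, classify_response, percent_improvement

__all__ = [
    "TestMethod",
    "SummaryStats",
    "PairedTestResult",
    "LongitudinalScores",
    "summarize",
    "median_iqr",
    "choose_paired_test",
    "paired_t",
    "wilcoxon_signed_rank",
    "response_rate_table",
]

#: Largest number of retained pairs for which the signed-rank p is exact.
EXACT_WILCOXON_MAX_N = 12


class TestMethod(str, Enum):
    PAIRED_T = "paired_t"
    WILCOXON = "wilcoxon"


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class PairedTestResult:
    method: TestMethod
    statistic: float
    df: int | None
    p_two_sided: float
    n_pairs: int
    normality_p: float | None = None


@dataclass(frozen=True)
class LongitudinalScores:
    """Patients x visit-weeks matrix for one score type."""

    score_name: str
    matrix: pd.DataFrame  # index: patient_id, columns: visit weeks (int)

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ValidationError(f"duplicate patient ids: {dupes}")
        weeks = list(self.matrix.columns)
        if weeks != sorted(weeks):
            object.__setattr__(self, "matrix", self.matrix.sort_index(axis=1))

    @property
    def visit_weeks(self) -> list[int]:
        return list(self.matrix.columns)

    def week(self, visit_week: int) -> pd.Series:
        if visit_week not in self.matrix.columns:
            raise ValidationError(
                f"{self.score_name}: no visit week {visit_week} "
                f"(have {self.visit_weeks})"
            )
        return self.matrix[visit_week]


def _as_array(values: Sequence[float], min_n: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"expected a 1-d sequence, got shape {arr.shape}")
    if arr.size < min_n:
        raise ValidationError(f"need at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("values must be finite")
    return arr


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation of order statistics."""
    arr = _as_array(values)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD (n-1 divisor), and median/quartiles of one variable."""
    arr = _as_array(values)
    med, q1, q3 = median_iqr(arr)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n=int(arr.size), mean=float(np.mean(arr)), sd=sd, median=med, q1=q1, q3=q3
    )


def choose_paired_test(
    differences: Sequence[float], alpha: float = 0.05
) -> tuple[TestMethod, float]:
    """Shapiro-Wilk gate on paired differences.

    Returns (method, normality_p): the paired t-test when normality is not
    rejected at ``alpha``, the Wilcoxon signed-rank test otherwise.  A
    zero-variance difference vector carries no distributional information;
    the gate falls back to Wilcoxon with a warning.
    """
    arr = _as_array(differences, min_n=3)
    if np.ptp(arr) == 0.0:
        warnings.warn(
            "all paired differences are equal; normality test degenerate, "
            "falling back to the Wilcoxon signed-rank test",
            stacklevel=2,
        )
        return TestMethod.WILCOXON, float("nan")
    normality_p = float(sps.shapiro(arr).pvalue)
    method = TestMethod.PAIRED_T if normality_p >= alpha else TestMethod.WILCOXON
    return method, normality_p


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d) / sqrt(n)), df = n-1."""
    xa, ya = _as_array(x, min_n=2), _as_array(y, min_n=2)
    if xa.size != ya.size:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    d = xa - ya
    n = d.size
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(TestMethod.PAIRED_T, 0.0, df, 1.0, n)
        # Zero spread with a nonzero mean: p is below any representable
        # floor; report the floor rather than an exact zero.
        stat = math_inf_signed(mean_d)
        return PairedTestResult(TestMethod.PAIRED_T, stat, df, 1e-15, n)
    t = mean_d / (sd_d / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTestResult(TestMethod.PAIRED_T, float(t), df, p, n)


def math_inf_signed(value: float) -> float:
    return float("inf") if value > 0 else float("-inf")


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by convolution.

    Builds the null distribution of W+ = sum of the mid-ranks of positive
    differences over all 2^n equiprobable sign assignments.  Mid-ranks are
    multiples of 1/2, so the distribution lives on a half-integer grid.
    Two-sidedness is by symmetry of W+ about n(n+1)/4: p = P(|W - mu| >=
    |w_obs - mu|).
    """
    units = np.rint(ranks * 2).astype(int)  # exact on the half-integer grid
    total = int(units.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for u in units:
        shifted = np.zeros_like(dist)
        shifted[u:] = dist[: total + 1 - u]
        dist = dist + shifted
    dist /= dist.sum()
    mu = total / 2.0
    dev = abs(w_plus * 2 - mu)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied magnitudes are mid-ranked.  Exact
    enumeration for up to ``EXACT_WILCOXON_MAX_N`` retained pairs, otherwise
    the normal approximation with tie correction and a 0.5 continuity
    correction toward the null mean.  The reported statistic is W+, the rank
    sum of positive differences.
    """
    xa, ya = _as_array(x, min_n=2), _as_array(y, min_n=2)
    if xa.size != ya.size:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    d = xa - ya
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValidationError(
            "all paired differences are zero; signed-rank test carries no information"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
        return PairedTestResult(TestMethod.WILCOXON, w_plus, None, p, n)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    tie_term = float(((tie_counts**3 - tie_counts) / 2.0).sum())
    sigma2 = (n * (n + 1) * (2 * n + 1) - tie_term) / 24.0
    if sigma2 == 0.0:
        raise ValidationError("degenerate signed-rank variance (all ranks tied away)")
    dev = abs(w_plus - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return PairedTestResult(TestMethod.WILCOXON, w_plus, None, p, n)


def response_rate_table(
    scores: LongitudinalScores, baseline_week: int, target_week: int
) -> Mapping[ResponseCategory, tuple[int, float]]:
    """Per-category response counts and proportions between two visits."""
    baseline = scores.week(baseline_week)
    target = scores.week(target_week)
    missing = sorted(
        set(baseline.index[baseline.isna()]) | set(target.index[target.isna()])
    )
    if missing:
        raise ValidationError(
            f"{scores.score_name}: patients missing week {baseline_week} or "
            f"{target_week}: {missing}"
        )
    categories = [
        classify_response(percent_improvement(b, f)).category
        for b, f in zip(baseline, target)
    ]
    n = len(categories)
    return {
        cat: (categories.count(cat), categories.count(cat) / n)
        for cat in ResponseCategory
    }
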