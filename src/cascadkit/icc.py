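"""Inter-rater reliability: two-way mixed-model intraclass correlation.

The ICC forms follow the McGraw-Wong taxonomy for a complete subjects x
raters table analysed by two-way ANOVA (subjects random, raters fixed):

* consistency, single measure  -- ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
* consistency, average measure -- ICC(3,k) = (MSR - MSE) / MSR
* absolute agreement, single   -- ICC(2,1), adds the rater mean-square term
* absolute agreement, average  -- ICC(2,k)

where MSR, MSC, MSE are the between-subject, between-rater and residual mean
squares.  95% confidence intervals use the exact F bounds for the consistency
forms and the Satterthwaite-approximate F bounds for the agreement forms.

Interpretation bands: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, > 0.9
excellent; boundary values are assigned to the higher band.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "IccModel",
    "IccUnit",
    "IccBand",
    "RatingsMatrix",
    "IccResult",
    "icc_two_way",
    "interpret_icc",
]


class IccModel(str, Enum):
    CONSISTENCY = "consistency"
    AGREEMENT = "agreement"


class IccUnit(str, Enum):
    SINGLE = "single"
    AVERAGE = "average"


class IccBand(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class RatingsMatrix:
    """Complete subjects x raters score table."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    rater_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, k = values.shape
        if n < 2 or k < 2:
            raise ValidationError(
                f"need >= 2 subjects and >= 2 raters, got {n} x {k}"
            )
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValidationError("id lengths do not match the value matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("ratings matrix must be complete and finite")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatingsMatrix":
        """Build from a DataFrame indexed by subject with one column per rater."""
        if frame.isna().any().any():
            raise ValidationError("ratings table has missing cells")
        return cls(
            frame.to_numpy(dtype=float),
            tuple(str(s) for s in frame.index),
            tuple(str(r) for r in frame.columns),
        )


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: IccModel
    unit: IccUnit
    anova_ms: tuple[float, float, float]  # (MS_rows, MS_cols, MS_error)
    degenerate: bool = False
    note: str | None = None


def _mean_squares(values: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way(
    ratings: RatingsMatrix,
    model: IccModel | str = IccModel.CONSISTENCY,
    unit: IccUnit | str = IccUnit.SINGLE,
    confidence: float = 0.95,
) -> IccResult:
    """Two-way mixed-model ICC with a confidence interval.

    The ANOVA mean squares are computed from scratch from the complete
    ratings table; the point estimate and F-based CI follow the chosen
    McGraw-Wong form.  A table with zero between-subject variance cannot
    identify reliability; the result is flagged degenerate.
    """
    model, unit = IccModel(model), IccUnit(unit)
    msr, msc, mse, n, k = _mean_squares(ratings.values)
    ms = (msr, msc, mse)
    alpha = 1.0 - confidence

    if msr == 0.0:
        return IccResult(
            float("nan"), float("nan"), float("nan"), model, unit, ms,
            degenerate=True,
            note="zero between-subject variance; ICC undefined",
        )
    # Residual mean square at floating-point noise level counts as zero.
    if mse <= 1e-12 * msr:
        mse = 0.0
    if msc <= 1e-12 * msr:
        msc = 0.0
    ms = (msr, msc, mse)
    if mse == 0.0 and (model is IccModel.CONSISTENCY or msc == 0.0):
        # Raters agree perfectly (up to a shift irrelevant for consistency).
        return IccResult(1.0, 1.0, 1.0, model, unit, ms)

    if model is IccModel.CONSISTENCY:
        if unit is IccUnit.SINGLE:
            est = (msr - mse) / (msr + (k - 1) * mse)
        else:
            est = (msr - mse) / msr
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        if unit is IccUnit.SINGLE:
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            lo = 1 - 1 / fl
            hi = 1 - 1 / fu
        return IccResult(float(est), float(lo), float(hi), model, unit, ms)

    # Absolute agreement (two-way model with rater variance in the denominator).
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if unit is IccUnit.SINGLE:
        est = single
    else:
        est = (msr - mse) / (msr + (msc - mse) / n)
    # Satterthwaite degrees of freedom for the denominator combination.
    rho = single
    a = k * rho / (n * (1 - rho)) if rho < 1 else float("inf")
    b = 1 + k * rho * (n - 1) / (n * (1 - rho)) if rho < 1 else float("inf")
    if not np.isfinite(a) or not np.isfinite(b):
        v = (n - 1) * (k - 1)
    else:
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
    f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo_single = (
        n * (msr - f_star * mse)
        / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    hi_single = (
        n * (f_star_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_star_u * msr)
    )
    if unit is IccUnit.SINGLE:
        lo, hi = lo_single, hi_single
    else:
        # Spearman-Brown step-up of the single-measure bounds.
        lo = k * lo_single / (1 + (k - 1) * lo_single)
        hi = k * hi_single / (1 + (k - 1) * hi_single)
    return IccResult(float(est), float(lo), float(hi), model, unit, ms)


def icc_report(ratings: RatingsMatrix, confidence: float = 0.95) -> pd.DataFrame:
    """All four ICC forms (model x unit) as one table."""
    rows = []
    for model in IccModel:
        for unit in IccUnit:
            res = icc_two_way(ratings, model, unit, confidence)
            rows.append(
                {
                    "model": model.value,
                    "unit": unit.value,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "band": (
                        interpret_icc(res.estimate).value
                        if np.isfinite(res.estimate)
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)


def interpret_icc(estimate: float) -> IccBand:
    """Reliability band for an ICC estimate (boundaries go to the higher band)."""
    if not np.isfinite(estimate):
        raise ValidationError(f"estimate must be finite, got {estimate}")
    if estimate >= 0.9:
        return IccBand.EXCELLENT
    if estimate >= 0.75:
        return IccBand.GOOD
    if estimate >= 0.5:
        return IccBand.MODERATE
    return IccBand.POOR
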