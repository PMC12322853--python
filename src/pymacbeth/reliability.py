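"""Inter-rater reliability via the intraclass correlation coefficient.

A stakeholder panel's questionnaire responses form a raters x items grid.
Reliability is summarised by the two-way random-effects, absolute-agreement
ICC computed from the two-way ANOVA mean squares (items as targets, raters
as the second factor), by default for the *average* of the raters — the
panel-level figure — with the single-rater form available behind a flag.
Confidence intervals follow the F-distribution construction of McGraw &
Wong, with a Satterthwaite degrees-of-freedom approximation.

Interpretation bands: an ICC below 0.4 indicates poor reliability, above
0.75 good reliability, and anything between is moderate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import DegenerateDataError, InvalidInputError

__all__ = ["RatingMatrix", "ICCResult", "icc", "interpret_icc", "read_ratings_csv"]


@dataclass(frozen=True)
class RatingMatrix:
    """A complete raters x items grid of scores."""

    ratings: np.ndarray  # shape (n_raters, n_items)

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratings, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError("ratings must be a 2-D raters x items grid")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise InvalidInputError("need at least 2 raters and 2 items")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("ratings must be complete and finite")
        object.__setattr__(self, "ratings", arr)

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_items(self) -> int:
        return self.ratings.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate with its confidence interval and interpretation."""

    estimate: float
    ci: tuple[float, float]
    confidence: float
    form: str
    band: str

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "confidence": self.confidence,
            "form": self.form,
            "band": self.band,
        }


def _mean_squares(grid: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares with items as rows, raters as columns."""
    n, k = grid.shape  # items, raters
    grand = grid.mean()
    item_means = grid.mean(axis=1)
    rater_means = grid.mean(axis=0)
    msr = k * np.sum((item_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    resid = grid - item_means[:, None] - rater_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(
    ratings: RatingMatrix, confidence: float = 0.95, average_measures: bool = True
) -> ICCResult:
    """Two-way random-effects, absolute-agreement ICC for a rater panel.

    Parameters
    ----------
    ratings
        Complete raters x items grid.
    confidence
        Two-sided confidence level for the interval.
    average_measures
        If True (default) report the reliability of the panel mean,
        ICC(A,k); otherwise the single-rater form ICC(A,1).

    Raises
    ------
    DegenerateDataError
        If the items show no between-item variance (the ICC is undefined).
    """
    if not 0 < confidence < 1:
        raise InvalidInputError("confidence must be in (0, 1)")
    grid = ratings.ratings.T  # items x raters
    n, k = grid.shape
    msr, msc, mse = _mean_squares(grid)
    if msr <= 0:
        raise DegenerateDataError("no between-item variance; ICC undefined")

    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if average_measures:
        estimate = (msr - mse) / (msr + (msc - mse) / n)
        form = "ICC(A,k): two-way random effects, absolute agreement, average measures"
    else:
        estimate = icc_a1
        form = "ICC(A,1): two-way random effects, absolute agreement, single measures"

    alpha = 1.0 - confidence
    if (msc + mse) <= 1e-12 * msr or icc_a1 >= 1.0 - 1e-12:
        # perfect agreement (up to rounding): all variance is between items
        lo = hi = estimate
    else:
        a = k * icc_a1 / (n * (1 - icc_a1))
        b = 1 + k * icc_a1 * (n - 1) / (n * (1 - icc_a1))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        if average_measures:
            # Spearman-Brown step-up from the single-measures bounds
            lo = lo1 * k / (1 + (k - 1) * lo1)
            hi = hi1 * k / (1 + (k - 1) * hi1)
        else:
            lo, hi = lo1, hi1
    return ICCResult(
        estimate=float(estimate),
        ci=(float(lo), float(hi)),
        confidence=confidence,
        form=form,
        band=interpret_icc(float(estimate)),
    )


def interpret_icc(estimate: float) -> str:
    """Map an ICC estimate to its conventional reliability band."""
    if not np.isfinite(estimate):
        raise InvalidInputError("ICC estimate must be finite")
    if estimate < 0.4:
        return "poor"
    if estimate > 0.75:
        return "good"
    return "moderate"


def read_ratings_csv(path: Union[str, Path]) -> RatingMatrix:
    """Read a raters x items grid (first column = rater id)."""
    df = pd.read_csv(path, index_col=0)
    return RatingMatrix(ratings=df.to_numpy(dtype=float))
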