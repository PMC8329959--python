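"""Observer agreement of texture features via the intraclass correlation.

The default ICC form is two-way random effects, absolute agreement, single
measures -- ICC(2,1) in the Shrout-Fleiss taxonomy -- computed from the
two-way ANOVA mean squares:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

where MSR, MSC and MSE are the between-subject, between-rater and residual
mean squares, n the number of subjects and k the number of raters.  The
consistency form ICC(3,1), which ignores systematic rater offsets, is
available as an alternative.

Agreement categories follow the conventional qualitative bands: 1 is
perfect; 0.81-0.99 almost perfect; 0.61-0.80 substantial; 0.41-0.60
moderate; 0.21-0.40 fair; and <= 0.20 slight.  The printed bands do not
tile the unit interval, so values falling in a gap (e.g. 0.995) are
assigned to the nearest band below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ICCResult", "icc", "categorize_agreement"]

MIN_SUBJECTS = 5

_BANDS = (
    (0.81, "almost perfect agreement"),
    (0.61, "substantial agreement"),
    (0.41, "moderate agreement"),
    (0.21, "fair agreement"),
)


@dataclass(frozen=True)
class ICCResult:
    feature: str
    icc: float | None  # None when undefined (no between-subject variance)
    category: str | None
    n_subjects: int
    n_ratings: int


def _mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = ratings - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(ratings, form: str = "absolute") -> float | None:
    """Single-measure ICC of a subjects x raters matrix.

    ``form="absolute"`` gives ICC(2,1) (two-way random, absolute
    agreement); ``form="consistency"`` gives ICC(3,1).  Returns ``None``
    when the between-subject variance is zero, in which case agreement is
    undefined rather than zero.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = x.shape
    if n < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {n}")
    if k < 2:
        raise ValueError("need at least 2 ratings per subject")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")

    msr, msc, mse = _mean_squares(x)
    if msr == 0:  # no between-subject variance: agreement undefined
        return None

    if form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form: {form!r}")
    if denom == 0:
        return None
    return float((msr - mse) / denom)


def categorize_agreement(value: float) -> str:
    """Qualitative agreement band for an ICC value (total on (-inf, 1])."""
    if value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value >= 1.0 - 1e-12:  # tolerate fp round-off at the boundary
        return "perfect agreement"
    for lower, label in _BANDS:
        if value >= lower:
            return label
    return "slight agreement"
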