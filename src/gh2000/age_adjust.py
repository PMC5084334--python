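"""Residual age adjustment of a score by centred simple linear regression.

The score Y is regressed on age x, E(Y) = a + b*x, by ordinary least
squares; the centred residual

    Y* = Y - b_hat * (x - center)

removes the age trend while preserving the score mean when ``center`` is the
sample mean age.  Two properties make this the natural correction: the
re-fitted slope of Y* on x is exactly zero (residual orthogonality), and any
rescaling of the age axis (including norming by its standard deviation)
yields the identical adjustment, so nothing further is gained by
transforming age first.

Computations use two-pass centred moments (deviations from the mean) to
avoid catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "AgeEffect",
    "AgeEffectRegression",
    "fit_age_effect",
    "adjust",
    "refit_slope_of_adjusted",
    "scale_invariance_check",
]


@dataclass(frozen=True)
class AgeEffect:
    """An estimated residual age slope of a score, with its OLS standard error."""

    label: str
    slope: float  # score units / year
    slope_se: float
    intercept: float
    n: int
    mean_age: float
    mean_score: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n >= 3 required (slope SE needs n-2 >= 1)")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not (self.slope_se >= 0):
            raise ValueError("slope_se must be non-negative")


def _as_vectors(scores, ages) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(scores, dtype=float).ravel()
    x = np.asarray(ages, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: {y.size} scores vs {x.size} ages")
    return y, x


class AgeEffectRegression(BaseEstimator, RegressorMixin):
    """OLS regression of a score on age, exposing the centred-residual adjustment.

    Parameters
    ----------
    center : "mean" or float
        Centring constant for :meth:`adjust`.  ``"mean"`` uses the fitted
        sample's mean age (mean-preserving); a fixed reference age (e.g.
        25.09 years for the male elite-athlete population) reproduces a
        published adjustment.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_ : float
        Least-squares line ``intercept_ + slope_ * age``.
    slope_se_ : float
        Classical homoskedastic OLS standard error, ``sqrt((RSS/(n-2))/Sxx)``.
    mean_age_, mean_score_, n_ : sample summaries.
    center_ : float
        Resolved centring constant.
    """

    def __init__(self, center: float | str = "mean"):
        self.center = center

    def fit(self, X, y):
        y, x = _as_vectors(y, np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0] if np.ndim(X) == 2 else X)
        n = x.size
        if n < 3:
            raise ValueError("need at least 3 observations")
        xbar = x.mean()
        ybar = y.mean()
        dx = x - xbar
        dy = y - ybar
        sxx = float(dx @ dx)
        if sxx == 0.0:
            raise ValueError("degenerate design: all ages identical")
        slope = float(dx @ dy) / sxx
        intercept = ybar - slope * xbar
        resid = dy - slope * dx
        rss = float(resid @ resid)
        # rss can go microscopically negative-of-zero on exact fits
        slope_se = float(np.sqrt(max(rss, 0.0) / (n - 2) / sxx))
        self.slope_ = slope
        self.intercept_ = float(intercept)
        self.slope_se_ = slope_se
        self.n_ = int(n)
        self.mean_age_ = float(xbar)
        self.mean_score_ = float(ybar)
        self.center_ = float(xbar) if self.center == "mean" else float(self.center)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x

    def adjust(self, scores, ages, center: float | None = None) -> np.ndarray:
        """Centred residual: ``scores - slope_*(ages - center)``."""
        y, x = _as_vectors(scores, ages)
        c = self.center_ if center is None else float(center)
        return y - self.slope_ * (x - c)

    def to_effect(self, label: str = "") -> AgeEffect:
        return AgeEffect(
            label=label,
            slope=self.slope_,
            slope_se=self.slope_se_,
            intercept=self.intercept_,
            n=self.n_,
            mean_age=self.mean_age_,
            mean_score=self.mean_score_,
        )


def fit_age_effect(scores, ages, label: str = "") -> AgeEffect:
    """OLS age slope of a score with its standard error and sample summaries."""
    model = AgeEffectRegression().fit(np.asarray(ages, dtype=float), np.asarray(scores, dtype=float))
    return model.to_effect(label)


def adjust(scores, ages, slope: float, center: float) -> np.ndarray:
    """Elementwise ``scores - slope*(ages - center)``."""
    y, x = _as_vectors(scores, ages)
    if not np.isfinite(center):
        raise ValueError("center must be finite")
    return y - slope * (x - center)


def refit_slope_of_adjusted(adjusted, ages) -> float:
    """OLS slope of adjusted scores on age.

    Zero (to floating tolerance) when the adjustment used this sample's own
    fitted slope; linear in the residual slope otherwise.
    """
    return fit_age_effect(adjusted, ages).slope


def scale_invariance_check(scores, ages, a: float) -> float:
    """Max |difference| between adjusting against ``a*ages`` and raw ages.

    Fitting the slope on the rescaled axis gives slope/a, so the adjustment
    ``Y - (slope/a)*(a*x - a*xbar)`` is algebraically identical to the raw
    one; the return value is the floating-point discrepancy (contract:
    <= 1e-10 on well-scaled data).
    """
    if a == 0:
        raise ValueError("scale factor must be nonzero")
    y, x = _as_vectors(scores, ages)
    raw = fit_age_effect(y, x)
    raw_adj = adjust(y, x, raw.slope, raw.mean_age)
    scaled = fit_age_effect(y, a * x)
    scaled_adj = adjust(y, a * x, scaled.slope, scaled.mean_age)
    return float(np.max(np.abs(scaled_adj - raw_adj)))
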