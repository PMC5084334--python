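"""Fixed-effect inverse-variance pooling of assay-specific age effects.

Each of the six assay pairs yields its own estimate of the residual age
slope of the male score.  Treating the pairs like studies in a meta-analysis,
the summary slope is the inverse-variance weighted mean

    pooled = sum(w_i * slope_i) / sum(w_i),   w_i = 1 / SE_i^2

with pooled SE = (sum w_i)^(-1/2), and Cochran's homogeneity statistic

    Q = sum (slope_i - pooled)^2 / SE_i^2  ~  chi^2(k-1)

tests whether one common adjustment is justified across assay pairs.  Only
the fixed-effect model is provided: the observed heterogeneity of the
published per-pair slopes is non-significant, which is what motivates a
single generic adjustment in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator

from .age_adjust import AgeEffect

__all__ = [
    "PooledEffect",
    "FixedEffectMeta",
    "pool_fixed_effect",
    "homogeneity_test",
    "summary_rows",
]


@dataclass(frozen=True)
class PooledEffect:
    """Fixed-effect meta-analytic summary of k slope estimates."""

    pooled_slope: float
    pooled_se: float
    weights: tuple[float, ...]  # absolute weights 1/SE^2, input order
    k: int
    chi_square: float  # Cochran's Q; 0.0 when k == 1
    df: int  # k - 1
    p_value: float  # upper tail; 1.0 when k == 1


def _chi2_upper_tail(q: float, df: int) -> float:
    # regularized upper incomplete gamma Q(df/2, q/2)
    return float(special.gammaincc(df / 2.0, q / 2.0))


class FixedEffectMeta(BaseEstimator):
    """Inverse-variance fixed-effect pooling, sklearn-style.

    ``fit(slopes, ses)`` consumes per-group effect estimates and their
    standard errors; fitted attributes mirror :class:`PooledEffect`.
    """

    def fit(self, slopes, ses):
        b = np.asarray(slopes, dtype=float).ravel()
        se = np.asarray(ses, dtype=float).ravel()
        if b.size == 0:
            raise ValueError("no effects to pool")
        if b.shape != se.shape:
            raise ValueError("slopes and standard errors must have equal length")
        if np.any(se <= 0):
            raise ValueError("all standard errors must be positive")
        w = 1.0 / se**2
        self.k_ = int(b.size)
        self.weights_ = w
        self.pooled_slope_ = float((w * b).sum() / w.sum())
        self.pooled_se_ = float(w.sum() ** -0.5)
        if self.k_ >= 2:
            self.chi_square_ = float(((b - self.pooled_slope_) ** 2 * w).sum())
            self.df_ = self.k_ - 1
            self.p_value_ = _chi2_upper_tail(self.chi_square_, self.df_)
        else:
            self.chi_square_, self.df_, self.p_value_ = 0.0, 0, 1.0
        return self

    def to_pooled(self) -> PooledEffect:
        return PooledEffect(
            pooled_slope=self.pooled_slope_,
            pooled_se=self.pooled_se_,
            weights=tuple(float(w) for w in self.weights_),
            k=self.k_,
            chi_square=self.chi_square_,
            df=self.df_,
            p_value=self.p_value_,
        )


def pool_fixed_effect(effects: Sequence[AgeEffect]) -> PooledEffect:
    """Pool age effects by inverse-variance weighting, with homogeneity test."""
    effects = list(effects)
    model = FixedEffectMeta().fit(
        [e.slope for e in effects], [e.slope_se for e in effects]
    )
    return model.to_pooled()


def homogeneity_test(effects: Sequence[AgeEffect], pooled_slope: float) -> tuple[float, int, float]:
    """Cochran's Q about a given pooled slope: (chi_square, df, p_value)."""
    effects = list(effects)
    k = len(effects)
    if k < 2:
        raise ValueError("homogeneity requires at least 2 effects")
    b = np.array([e.slope for e in effects])
    se = np.array([e.slope_se for e in effects])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    q = float(((b - pooled_slope) ** 2 / se**2).sum())
    df = k - 1
    return q, df, _chi2_upper_tail(q, df)


def summary_rows(
    effects: Sequence[AgeEffect], pooled: PooledEffect, ci_level: float = 0.95
) -> list[dict]:
    """Forest-table rows: one per effect plus the pooled summary row.

    Each row carries label, slope, ``lower``/``upper`` (slope ± z·SE at the
    given confidence level) and the relative weight (summing to 1 over the
    individual effects; the summary row's relative weight is 1).
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    total_w = sum(pooled.weights)
    rows = []
    for effect, w in zip(effects, pooled.weights, strict=True):
        rows.append(
            {
                "label": effect.label,
                "slope": effect.slope,
                "se": effect.slope_se,
                "lower": effect.slope - z * effect.slope_se,
                "upper": effect.slope + z * effect.slope_se,
                "rel_weight": w / total_w,
                "n": effect.n,
            }
        )
    rows.append(
        {
            "label": "pooled (fixed effect)",
            "slope": pooled.pooled_slope,
            "se": pooled.pooled_se,
            "lower": pooled.pooled_slope - z * pooled.pooled_se,
            "upper": pooled.pooled_slope + z * pooled.pooled_se,
            "rel_weight": 1.0,
            "n": sum(e.n for e in effects),
        }
    )
    return rows
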