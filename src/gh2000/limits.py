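"""Decision limits for the score distributions of clean athletes.

The anti-doping decision limit for a score variant is

    DL = mean + z*s + u

where mean and s (n-1 denominator) are the moments of the clean-athlete
score distribution, z is the one-sided standard-normal quantile at the
accepted false-positive rate (3.72 at 1 in 10,000, 2-dp convention), and u
is a sample-uncertainty term inflating the limit for finite-sample
estimation error,

    u = sqrt( s^2/n * (1 + z^2/n) ).

Caveat: evaluating this u formula at the published per-pair (s, n) does
*not* reproduce the published u column (e.g. 0.0406 vs the printed 0.1872
for s=1.2412, n=947 — a consistent factor of about 4.6 across rows; the
originating derivation is in the decision-limit literature and is not
restated here).  The formula is implemented literally and the discrepancy is
surfaced, not silently reconciled; ``u_override`` lets the published DLs be
reproduced exactly from their printed components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "DecisionLimitSummary",
    "DecisionLimitModel",
    "false_positive_multiplier",
    "sample_uncertainty",
    "decision_limit",
    "summarize",
]


@dataclass(frozen=True)
class DecisionLimitSummary:
    """One decision-limit table row; ``dl == mean + z*sd + u`` by construction."""

    label: str
    n: int
    mean: float
    sd: float
    mean_plus_zs: float
    u: float
    dl: float
    z: float


def false_positive_multiplier(rate: float) -> float:
    """One-sided standard-normal upper quantile at the false-positive rate."""
    if not (0.0 < rate < 0.5):
        raise ValueError("false-positive rate must lie strictly between 0 and 0.5")
    return float(stats.norm.isf(rate))


def sample_uncertainty(sd: float, n: int, z: float = 3.72) -> float:
    """Finite-sample uncertainty term u = sqrt(s^2/n * (1 + z^2/n))."""
    if n < 2:
        raise ValueError("n >= 2 required")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return math.sqrt(sd * sd / n * (1.0 + z * z / n))


def decision_limit(mean: float, sd: float, u: float, z: float = 3.72) -> float:
    """DL = mean + z*sd + u."""
    if sd < 0 or u < 0:
        raise ValueError("sd and u must be non-negative")
    return mean + z * sd + u


class DecisionLimitModel(BaseEstimator):
    """Estimate a decision limit from a vector of clean-athlete scores.

    Parameters
    ----------
    z : float
        Quantile multiplier (default 3.72, the 2-dp one-sided normal quantile
        for a 1-in-10,000 false-positive rate).
    u_override : float, optional
        Use this uncertainty term instead of the formula value; needed to
        reproduce published tables whose printed u differs from the printed
        formula (see module docstring).
    """

    def __init__(self, z: float = 3.72, u_override: float | None = None):
        self.z = z
        self.u_override = u_override

    def fit(self, X, y=None):
        scores = np.asarray(X, dtype=float).ravel()
        scores = scores[~np.isnan(scores)]
        n = scores.size
        if n < 2:
            raise ValueError("need at least 2 scores")
        self.n_ = int(n)
        self.mean_ = float(scores.mean())
        self.sd_ = float(scores.std(ddof=1))
        self.u_ = (
            sample_uncertainty(self.sd_, self.n_, self.z)
            if self.u_override is None
            else float(self.u_override)
        )
        self.mean_plus_zs_ = self.mean_ + self.z * self.sd_
        self.dl_ = decision_limit(self.mean_, self.sd_, self.u_, self.z)
        return self

    def to_summary(self, label: str = "") -> DecisionLimitSummary:
        return DecisionLimitSummary(
            label=label,
            n=self.n_,
            mean=self.mean_,
            sd=self.sd_,
            mean_plus_zs=self.mean_plus_zs_,
            u=self.u_,
            dl=self.dl_,
            z=self.z,
        )


def summarize(
    scores, label: str = "", z: float = 3.72, u_override: float | None = None
) -> DecisionLimitSummary:
    """Decision-limit summary (n, mean, sd, mean+z·s, u, DL) of a score vector."""
    return DecisionLimitModel(z=z, u_override=u_override).fit(scores).to_summary(label)
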