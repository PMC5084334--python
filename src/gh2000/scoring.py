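"""The GH-2000 discriminant score and its age-adjusted variant.

The score combines the two GH-sensitive serum markers in a sex-specific
linear discriminant,

    score = b0 + b1*log(IGF-I) + b2*log(P-III-NP) + b3/age [+ b_age*age]

with natural logarithms (the log base is a documented convention of this
package; the log-linear marker models of the GH-2000 literature use natural
logs).  The published male score shows a residual positive linear age trend;
the age-adjusted score subtracts ``pooled_slope * (age - reference_age)``,
which can equivalently be folded into the coefficients: the intercept gains
``pooled_slope * reference_age`` and a linear age term ``-pooled_slope``
appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .records import AthleteRecord, Sex

__all__ = [
    "ScoreCoefficients",
    "AgeAdjustment",
    "published_coefficients",
    "compute_score",
    "compute_scores",
    "apply_adjustment",
    "fold_adjustment",
    "GH2000Score",
]


@dataclass(frozen=True)
class ScoreCoefficients:
    """Coefficients of the discriminant score for one sex.

    ``beta3`` multiplies 1/age (score·years); ``beta_age`` multiplies age
    itself (score/year) and is zero for the unadjusted published sets.
    """

    sex: Sex
    beta0: float
    beta1: float  # log(IGF-I) coefficient, > 0 in the published sets
    beta2: float  # log(P-III-NP) coefficient, > 0 in the published sets
    beta3: float  # 1/age coefficient
    beta_age: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        values = (self.beta0, self.beta1, self.beta2, self.beta3, self.beta_age)
        if not all(math.isfinite(v) for v in values):
            raise ValueError("score coefficients must be finite")


@dataclass(frozen=True)
class AgeAdjustment:
    """A residual age correction: subtract ``pooled_slope*(age - reference_age)``."""

    pooled_slope: float
    reference_age: float

    def __post_init__(self) -> None:
        if not (self.reference_age > 0):
            raise ValueError("reference_age must be positive")


_PUBLISHED = {
    (Sex.MALE, False): ScoreCoefficients(
        Sex.MALE, -6.586, 2.100, 2.905, -101.737, 0.0, label="published male"
    ),
    (Sex.FEMALE, False): ScoreCoefficients(
        Sex.FEMALE, -8.459, 2.195, 2.454, -73.666, 0.0, label="published female"
    ),
    # Printed age-adjusted male set; the intercept is the printed 3-dp
    # rounding of -6.586 + 0.032*25.09 = -5.78312.
    (Sex.MALE, True): ScoreCoefficients(
        Sex.MALE, -5.783, 2.100, 2.905, -101.737, -0.032, label="published male adjusted"
    ),
}


def published_coefficients(sex: Sex | str, adjusted: bool = False) -> ScoreCoefficients:
    """Return a published coefficient set.

    The age-adjusted set exists only for the male score; the female score
    shows no residual age effect, so requesting an adjusted female set is an
    error.
    """
    sex = Sex(sex)
    if adjusted and sex is Sex.FEMALE:
        raise ValueError(
            "no adjusted female coefficient set exists: the female score shows "
            "no residual age effect"
        )
    return _PUBLISHED[(sex, adjusted)]


def compute_score(record: AthleteRecord, coeffs: ScoreCoefficients) -> float:
    """Evaluate the discriminant score for one record.

    Requires both markers present and positive, positive age, and matching
    record/coefficient sex.
    """
    if record.sex is not coeffs.sex:
        raise ValueError(f"record sex {record.sex.value!r} does not match coefficients for {coeffs.sex.value!r}")
    if record.igf1_ugL is None or record.p3np_ugL is None:
        raise ValueError(f"record {record.athlete_id}: marker missing, score undefined")
    if record.igf1_ugL <= 0 or record.p3np_ugL <= 0 or record.age_years <= 0:
        raise ValueError(f"record {record.athlete_id}: markers and age must be positive")
    return (
        coeffs.beta0
        + coeffs.beta1 * math.log(record.igf1_ugL)
        + coeffs.beta2 * math.log(record.p3np_ugL)
        + coeffs.beta3 / record.age_years
        + coeffs.beta_age * record.age_years
    )


def compute_scores(
    igf1: np.ndarray, p3np: np.ndarray, age: np.ndarray, coeffs: ScoreCoefficients
) -> np.ndarray:
    """Vectorised score; NaN markers propagate to NaN scores."""
    igf1 = np.asarray(igf1, dtype=float)
    p3np = np.asarray(p3np, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if np.any(igf1[~np.isnan(igf1)] <= 0) or np.any(p3np[~np.isnan(p3np)] <= 0):
        raise ValueError("marker concentrations must be positive where present")
    with np.errstate(invalid="ignore"):
        return (
            coeffs.beta0
            + coeffs.beta1 * np.log(igf1)
            + coeffs.beta2 * np.log(p3np)
            + coeffs.beta3 / age
            + coeffs.beta_age * age
        )


def apply_adjustment(score, age, adj: AgeAdjustment):
    """Age-correct score(s): ``score - pooled_slope*(age - reference_age)``.

    Accepts scalars or arrays; at ``age == reference_age`` the score is
    unchanged.
    """
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    out = score - adj.pooled_slope * (age - adj.reference_age)
    return float(out) if out.ndim == 0 else out


def fold_adjustment(coeffs: ScoreCoefficients, adj: AgeAdjustment) -> ScoreCoefficients:
    """Fold an age correction into the coefficient set.

    Subtracting ``slope*(age - ref)`` is the same as adding ``slope*ref`` to
    the intercept and ``-slope`` to the linear age coefficient, so the folded
    set evaluates identically to compute-then-adjust (to floating tolerance;
    full precision, not the printed 3-dp intercept).
    """
    if coeffs.beta_age != 0.0:
        raise ValueError("coefficient set already carries a linear age term; refusing to refold")
    return replace(
        coeffs,
        beta0=coeffs.beta0 + adj.pooled_slope * adj.reference_age,
        beta_age=-adj.pooled_slope,
        label=(coeffs.label + " + age-adjustment").strip(),
    )


class GH2000Score(BaseEstimator, TransformerMixin):
    """Stateless transformer computing the score from a cohort DataFrame.

    Parameters
    ----------
    sex : {"male", "female"}
        Which published coefficient set to use (ignored when ``coefficients``
        is given).
    adjusted : bool
        Use the published age-adjusted male set.
    coefficients : ScoreCoefficients, optional
        Explicit coefficient override.

    ``transform`` takes a DataFrame with columns ``igf1_ugL``, ``p3np_ugL``,
    ``age_years`` and returns the score as a 1-d array; rows with a missing
    marker yield NaN.
    """

    def __init__(self, sex: str = "male", adjusted: bool = False, coefficients: ScoreCoefficients | None = None):
        self.sex = sex
        self.adjusted = adjusted
        self.coefficients = coefficients

    def _coeffs(self) -> ScoreCoefficients:
        if self.coefficients is not None:
            return self.coefficients
        return published_coefficients(self.sex, self.adjusted)

    def fit(self, X=None, y=None):
        self._coeffs()  # validate parameters
        return self

    def transform(self, X) -> np.ndarray:
        coeffs = self._coeffs()
        return compute_scores(
            X["igf1_ugL"].to_numpy(dtype=float),
            X["p3np_ugL"].to_numpy(dtype=float),
            X["age_years"].to_numpy(dtype=float),
            coeffs,
        )
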