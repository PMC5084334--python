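"""End-to-end helpers chaining the score, regression, pooling and limit steps.

These operate on the long-format cohort DataFrame (one row per athlete x
assay pair) produced by :meth:`CohortTable.to_frame` and group by assay
pair, dropping rows that miss either marker — which is why per-pair sample
sizes differ within one cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .age_adjust import AgeEffect, adjust, fit_age_effect
from .limits import DecisionLimitSummary, summarize
from .pooling import PooledEffect, pool_fixed_effect
from .records import ASSAY_PAIRS, CohortTable, Sex
from .scoring import AgeAdjustment, ScoreCoefficients, compute_scores, published_coefficients

__all__ = [
    "score_frame",
    "age_effects_by_pair",
    "pooled_age_effect",
    "decision_table",
]


def _frame(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return cohort.to_frame() if isinstance(cohort, CohortTable) else cohort


def score_frame(
    cohort: CohortTable | pd.DataFrame,
    coefficients: dict[Sex, ScoreCoefficients] | None = None,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Append a ``gh2000_score`` column, sex by sex.

    Female records never receive the published adjusted set (no female age
    effect exists); when ``adjusted`` is requested they are scored with the
    unadjusted female coefficients, i.e. pass through unchanged.
    """
    df = _frame(cohort).copy()
    scores = np.full(len(df), np.nan)
    for sex in Sex:
        mask = (df["sex"] == sex.value).to_numpy()
        if not mask.any():
            continue
        if coefficients is not None:
            coeffs = coefficients[sex]
        else:
            coeffs = published_coefficients(sex, adjusted and sex is Sex.MALE)
        sub = df.loc[mask]
        scores[mask] = compute_scores(
            sub["igf1_ugL"].to_numpy(dtype=float),
            sub["p3np_ugL"].to_numpy(dtype=float),
            sub["age_years"].to_numpy(dtype=float),
            coeffs,
        )
    df["gh2000_score"] = scores
    return df


def _complete_pairs(df: pd.DataFrame):
    df = df.dropna(subset=["igf1_ugL", "p3np_ugL"])
    for pair in ASSAY_PAIRS:
        sub = df[
            (df["p3np_assay"] == pair.p3np_assay.value)
            & (df["igf1_assay"] == pair.igf1_assay.value)
        ]
        if len(sub):
            yield pair, sub


def age_effects_by_pair(
    scored: pd.DataFrame, score_column: str = "gh2000_score", min_n: int = 3
) -> list[AgeEffect]:
    """Per-assay-pair OLS age slopes of the score, in canonical pair order."""
    effects = []
    for pair, sub in _complete_pairs(scored.dropna(subset=[score_column])):
        if len(sub) < min_n:
            continue
        effects.append(
            fit_age_effect(
                sub[score_column].to_numpy(dtype=float),
                sub["age_years"].to_numpy(dtype=float),
                label=pair.label,
            )
        )
    return effects


def pooled_age_effect(
    scored: pd.DataFrame, score_column: str = "gh2000_score"
) -> tuple[PooledEffect, list[AgeEffect]]:
    """Fit per-pair age effects and pool them by inverse variance."""
    effects = age_effects_by_pair(scored, score_column)
    return pool_fixed_effect(effects), effects


def decision_table(
    scored: pd.DataFrame,
    adjustment: AgeAdjustment | None = None,
    z: float = 3.72,
    score_column: str = "gh2000_score",
) -> list[DecisionLimitSummary]:
    """Decision-limit summaries per assay pair, unadjusted and (optionally) adjusted.

    When an adjustment is given, each pair contributes two rows labelled
    ``<pair> unadjusted`` and ``<pair> adjusted``.
    """
    rows: list[DecisionLimitSummary] = []
    for pair, sub in _complete_pairs(scored.dropna(subset=[score_column])):
        scores = sub[score_column].to_numpy(dtype=float)
        ages = sub["age_years"].to_numpy(dtype=float)
        rows.append(summarize(scores, f"{pair.label} unadjusted", z=z))
        if adjustment is not None:
            adj_scores = adjust(scores, ages, adjustment.pooled_slope, adjustment.reference_age)
            rows.append(summarize(adj_scores, f"{pair.label} adjusted", z=z))
    return rows
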