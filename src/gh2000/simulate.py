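"""Synthetic elite-athlete cohorts with known ground truth.

The real multi-event athlete databases behind the published score tables are
not public, so this generator emulates their structure: ages drawn from a
truncated Gaussian centred near 25.09 years; log marker levels linear in
reciprocal age with additive Gaussian noise; six assay-pair score variants
produced by per-assay offsets and per-variant measurement noise around a
shared latent marker level, so the variants are positively correlated via
the latent level only — each variant is treated as an independent
realisation from the universe of assay combinations, mirroring the
meta-analytic view that motivates pooling the six age effects; per-assay
missingness so per-pair sample sizes differ; and a configurable injected
residual age effect in the male score.

The injected effect is a score-scale perturbation: the term
``beta_true * (age - age_mean)`` is split evenly between the two log markers
(half/(2*b1) to log IGF-I, half/(2*b2) to log P-III-NP, with b1, b2 the male
discriminant marker coefficients), so the male score computed with the
published unadjusted coefficients carries exactly the injected residual
linear age slope in expectation while each marker's distortion stays small.
Female cohorts are generated with zero injected slope and marker age
coefficients that the female discriminant's 1/age term cancels exactly.

Defaults are tuned to reproduce the published score-moment ranges (per-pair
score sd about 1.2-1.4, means spanning about 4.2-6.5, per-pair n in
[940, 1000] at n=1000), not real marker distributions; in particular the
assay-specific noise dominates the shared latent term, so the six score
variants are only weakly correlated (see docs/methods.md for why and what
that implies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records import ASSAY_PAIRS, AssayPair, AthleteRecord, CohortTable, Igf1Assay, P3npAssay, Sex

__all__ = [
    "MarkerModel",
    "AssayModel",
    "SimulationParams",
    "GroundTruth",
    "simulate_cohort",
    "default_daegu_like_params",
]

# Marker coefficients of the published male / female discriminants, used to
# (a) allocate the injected score-scale perturbation to the markers and
# (b) choose reciprocal-age marker coefficients the score's 1/age term cancels.
_MALE_B1, _MALE_B2, _MALE_B3 = 2.100, 2.905, -101.737
_FEMALE_B1, _FEMALE_B2, _FEMALE_B3 = 2.195, 2.454, -73.666


@dataclass(frozen=True)
class MarkerModel:
    """log(marker) = intercept + recip_age_coef / age + noise."""

    intercept: float
    recip_age_coef: float
    latent_sd: float  # shared across assays measuring this marker

    def __post_init__(self) -> None:
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be non-negative")


@dataclass(frozen=True)
class AssayModel:
    """Per-assay measurement model: additive log-scale offset + extra noise."""

    offset: float
    noise_sd: float
    missing_rate: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulationParams:
    n: int = 1000
    sex: Sex = Sex.MALE
    age_mean: float = 25.09
    age_sd: float = 3.0
    age_min: float = 18.0
    age_max: float = 40.0
    igf1_model: MarkerModel = MarkerModel(4.54, 24.22, 0.04)
    p3np_model: MarkerModel = MarkerModel(0.6065, 17.51, 0.03)
    igf1_assays: dict[Igf1Assay, AssayModel] = field(
        default_factory=lambda: {
            Igf1Assay.LCMS: AssayModel(0.0, 0.40, 0.025),
            Igf1Assay.IMMUNOTECH: AssayModel(-0.052, 0.42, 0.015),
            Igf1Assay.IDS: AssayModel(-0.262, 0.40, 0.015),
        }
    )
    p3np_assays: dict[P3npAssay, AssayModel] = field(
        default_factory=lambda: {
            P3npAssay.SIEMENS: AssayModel(0.63, 0.30, 0.012),
            P3npAssay.ORION: AssayModel(0.0, 0.31, 0.004),
        }
    )
    injected_residual_slope: float = 0.032  # score units / year
    assay_pairs: tuple[AssayPair, ...] = ASSAY_PAIRS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n >= 10 required")
        if not (0 < self.age_min < self.age_max):
            raise ValueError("need 0 < age_min < age_max")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if not self.assay_pairs:
            raise ValueError("at least one assay pair required")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative parameters of a simulated cohort, recorded verbatim."""

    injected_residual_slope: float
    injection: str  # how the slope was injected
    sex: str
    age_mean: float
    igf1_model: MarkerModel
    p3np_model: MarkerModel
    igf1_assays: dict[str, AssayModel]
    p3np_assays: dict[str, AssayModel]
    seed: int


def default_daegu_like_params(
    sex: Sex | str = Sex.MALE, n: int = 1000, seed: int = 0
) -> SimulationParams:
    """Parameters emulating the male reference cohort's summary structure.

    n=1000 with per-assay missingness gives per-pair counts in [940, 1000];
    marker and noise levels give per-pair score sd of about 1.2-1.4 and
    means spanning roughly 4.2-6.5 across the six pairs.  Female cohorts get
    zero injected slope (the female score shows no residual age effect) and
    marker reciprocal-age coefficients matched to the female discriminant.
    """
    sex = Sex(sex)
    if sex is Sex.MALE:
        return SimulationParams(n=n, sex=sex, seed=seed)
    # Scale the reciprocal-age coefficients so the female score's 1/age term
    # cancels the marker age trends exactly: b1*c1 + b2*c2 = -b3.
    male = SimulationParams()
    scale = -_FEMALE_B3 / (
        _FEMALE_B1 * male.igf1_model.recip_age_coef
        + _FEMALE_B2 * male.p3np_model.recip_age_coef
    )
    return SimulationParams(
        n=n,
        sex=sex,
        igf1_model=MarkerModel(
            male.igf1_model.intercept,
            male.igf1_model.recip_age_coef * scale,
            male.igf1_model.latent_sd,
        ),
        p3np_model=MarkerModel(
            male.p3np_model.intercept,
            male.p3np_model.recip_age_coef * scale,
            male.p3np_model.latent_sd,
        ),
        injected_residual_slope=0.0,
        seed=seed,
    )


def _truncated_normal(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    a = (params.age_min - params.age_mean) / params.age_sd
    b = (params.age_max - params.age_mean) / params.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=params.age_mean, scale=params.age_sd, size=params.n, random_state=rng
    )


def simulate_cohort(params: SimulationParams) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort; identical params (incl. seed) give identical tables.

    One record per athlete per requested assay pair is emitted, with athlete
    ids ``<sex-letter><index>.<pair-label>``; each variant draws its own
    measurement noise around the athlete's shared latent marker levels,
    while missingness is per assay and therefore shared across the pairs
    using that assay.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    ages = np.round(_truncated_normal(rng, params), 6)

    b1, b2 = (_MALE_B1, _MALE_B2) if params.sex is Sex.MALE else (_FEMALE_B1, _FEMALE_B2)
    latent_igf1 = (
        params.igf1_model.intercept
        + params.igf1_model.recip_age_coef / ages
        + params.igf1_model.latent_sd * rng.standard_normal(n)
    )
    latent_p3np = (
        params.p3np_model.intercept
        + params.p3np_model.recip_age_coef / ages
        + params.p3np_model.latent_sd * rng.standard_normal(n)
    )
    # Injected residual age effect, split evenly between the two log markers
    # so the score gains exactly beta_true*(age - age_mean).
    drift = params.injected_residual_slope * (ages - params.age_mean)
    latent_igf1 += drift / (2.0 * b1)
    latent_p3np += drift / (2.0 * b2)

    # Missingness is a property of the assay (shared by every variant using
    # it); measurement noise is drawn independently per score variant, so
    # cross-variant correlation comes only from the shared latent level.
    igf1_miss = {a: rng.random(n) < params.igf1_assays[a].missing_rate for a in Igf1Assay}
    p3np_miss = {a: rng.random(n) < params.p3np_assays[a].missing_rate for a in P3npAssay}

    prefix = "M" if params.sex is Sex.MALE else "F"
    width = len(str(n))
    ages = np.round(ages, 6)
    records: list[AthleteRecord] = []
    for pair in params.assay_pairs:
        igf_model = params.igf1_assays[pair.igf1_assay]
        p3_model = params.p3np_assays[pair.p3np_assay]
        igf_vals = np.round(
            np.exp(latent_igf1 + igf_model.offset + igf_model.noise_sd * rng.standard_normal(n)), 6
        )
        p3_vals = np.round(
            np.exp(latent_p3np + p3_model.offset + p3_model.noise_sd * rng.standard_normal(n)), 6
        )
        for i in range(n):
            records.append(
                AthleteRecord(
                    athlete_id=f"{prefix}{i + 1:0{width}d}.{pair.label}",
                    sex=params.sex,
                    age_years=float(ages[i]),
                    igf1_ugL=None if igf1_miss[pair.igf1_assay][i] else float(igf_vals[i]),
                    p3np_ugL=None if p3np_miss[pair.p3np_assay][i] else float(p3_vals[i]),
                    igf1_assay=pair.igf1_assay,
                    p3np_assay=pair.p3np_assay,
                )
            )
    table = CohortTable(
        records=records,
        provenance=f"simulated(sex={params.sex.value}, n={n}, seed={params.seed})",
    )
    truth = GroundTruth(
        injected_residual_slope=params.injected_residual_slope,
        injection="score-scale perturbation beta*(age-age_mean), split evenly across log markers",
        sex=params.sex.value,
        age_mean=params.age_mean,
        igf1_model=params.igf1_model,
        p3np_model=params.p3np_model,
        igf1_assays={a.value: m for a, m in params.igf1_assays.items()},
        p3np_assays={a.value: m for a, m in params.p3np_assays.items()},
        seed=params.seed,
    )
    return table, truth
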