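"""Published constants of the GH-2000 biomarker methodology.

Everything here is a printed value from the methodology literature: the
sex-specific discriminant coefficients, the six assay-pair age-effect
estimates with their standard errors, the summary age slope and male
reference age, and the descriptive decision-limit table for the six score
variants (unadjusted and age-adjusted).
"""

from __future__ import annotations

from .records import ASSAY_PAIRS, AssayPair, Igf1Assay, P3npAssay

__all__ = [
    "POOLED_AGE_SLOPE",
    "REFERENCE_AGE_MALE",
    "DECISION_Z",
    "FALSE_POSITIVE_RATE",
    "PUBLISHED_AGE_EFFECTS",
    "PUBLISHED_DECISION_TABLE",
]

#: Summary (inverse-variance pooled) residual age slope of the male score,
#: score units per year, as printed.  Pooling the rounded per-pair estimates
#: below gives 0.0325; the printed value was computed from unrounded inputs.
POOLED_AGE_SLOPE = 0.032

#: Mean age of the male elite-athlete reference population, years.
REFERENCE_AGE_MALE = 25.09

#: Standard-normal quantile used in the decision limit, 2-dp convention for
#: the 1-in-10,000 one-sided false-positive rate (exact quantile 3.7190).
DECISION_Z = 3.72

FALSE_POSITIVE_RATE = 1e-4

#: Per-assay-pair residual age slopes of the male score and their standard
#: errors (score units / year), with the per-pair sample sizes of the
#: reference cohort.  Keys are (P-III-NP assay, IGF-I assay) pairs.
PUBLISHED_AGE_EFFECTS: dict[AssayPair, tuple[float, float]] = {
    AssayPair(P3npAssay.SIEMENS, Igf1Assay.LCMS): (0.0418, 0.0082),
    AssayPair(P3npAssay.SIEMENS, Igf1Assay.IMMUNOTECH): (0.0261, 0.0086),
    AssayPair(P3npAssay.SIEMENS, Igf1Assay.IDS): (0.0359, 0.0070),
    AssayPair(P3npAssay.ORION, Igf1Assay.LCMS): (0.0363, 0.0077),
    AssayPair(P3npAssay.ORION, Igf1Assay.IMMUNOTECH): (0.0202, 0.0085),
    AssayPair(P3npAssay.ORION, Igf1Assay.IDS): (0.0318, 0.0077),
}

#: Printed descriptive statistics and decision limits for the six score
#: variants.  Per pair: {"unadjusted" | "adjusted": (n, mean, s, mean+3.72s,
#: u, DL)}.  The printed u column does not equal the printed
#: sample-uncertainty formula evaluated at (s, n) — see
#: :func:`gh2000.limits.sample_uncertainty` — so it is carried verbatim here.
PUBLISHED_DECISION_TABLE: dict[AssayPair, dict[str, tuple[int, float, float, float, float, float]]] = {
    AssayPair(P3npAssay.SIEMENS, Igf1Assay.LCMS): {
        "unadjusted": (947, 6.5393, 1.2412, 11.1566, 0.1872, 11.34),
        "adjusted": (947, 6.5382, 1.2424, 11.1599, 0.1874, 11.35),
    },
    AssayPair(P3npAssay.SIEMENS, Igf1Assay.IMMUNOTECH): {
        "unadjusted": (971, 6.4292, 1.3189, 11.3355, 0.1965, 11.53),
        "adjusted": (971, 6.4287, 1.3284, 11.3703, 0.1979, 11.57),
    },
    AssayPair(P3npAssay.SIEMENS, Igf1Assay.IDS): {
        "unadjusted": (970, 5.9935, 1.1925, 10.4296, 0.1777, 10.61),
        "adjusted": (970, 5.9931, 1.1954, 10.4400, 0.1782, 10.62),
    },
    AssayPair(P3npAssay.ORION, Igf1Assay.LCMS): {
        "unadjusted": (966, 4.7062, 1.2902, 9.5057, 0.1927, 9.70),
        "adjusted": (966, 4.7047, 1.2976, 9.5318, 0.1938, 9.73),
    },
    AssayPair(P3npAssay.ORION, Igf1Assay.IMMUNOTECH): {
        "unadjusted": (999, 4.5984, 1.3925, 9.7785, 0.2045, 9.98),
        "adjusted": (999, 4.5984, 1.4077, 9.8350, 0.2068, 10.04),
    },
    AssayPair(P3npAssay.ORION, Igf1Assay.IDS): {
        "unadjusted": (992, 4.1614, 1.2522, 8.8196, 0.1846, 9.00),
        "adjusted": (992, 4.1611, 1.2610, 8.8520, 0.1859, 9.04),
    },
}

assert set(PUBLISHED_AGE_EFFECTS) == set(ASSAY_PAIRS)
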