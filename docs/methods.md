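# Methods

## The score and its age adjustment

The GH-2000 score is a sex-specific linear discriminant in log IGF-I,
log P-III-NP and reciprocal age.  All logarithms are natural: the source
literature writes "log" without a base, and the log-linear marker models the
discriminant was built on use natural logs; this is a documented package
convention, and custom coefficient sets can be supplied through the config
file if another calibration is needed.  Marker units are fixed as µg/L
(numerically identical to ng/mL); no unit-conversion layer exists because
the published coefficients presuppose the assay calibrations of the source
studies.

The male score's residual age trend is removed by the centred residual

    Y* = Y − β̂ (x − x̄),

where β̂ is the OLS slope of score on age.  Three exact identities make this
the canonical correction, and all three are enforced as tests rather than
assumed: (1) the re-fitted slope of Y* on age is zero (residual
orthogonality — asserted more generally for multi-covariate designs:
least-squares residuals are orthogonal to every design column); (2) centring
at the sample mean age preserves the score mean; (3) rescaling the age axis
by any nonzero a (including norming by sd(x)) changes β̂ to β̂/a and leaves
the adjustment identical, so transformed-age variants add nothing.

Slope standard errors use the classical homoskedastic OLS formula
√((RSS/(n−2))/Σ(xᵢ−x̄)²); no robust variant is offered, since the age effect
being corrected is structural, not an artefact of outliers.  Centring
defaults to the sample mean age for de-novo analyses and to the published
male reference age 25.09 years when reproducing the published adjustment.
Centred moments are computed from deviations about the mean (two-pass),
avoiding cancellation on large-mean data.  Degenerate designs (constant
ages, n < 3) are hard errors.

## Pooling the six assay-pair effects

Each of the six assay pairs (Siemens/Orion P-III-NP × LC-MS/Immunotech/IDS
IGF-I) yields its own score scale and its own age slope.  A single generic
correction uses fixed-effect inverse-variance pooling, β̄ = Σwᵢβ̂ᵢ/Σwᵢ with
wᵢ = 1/SEᵢ² and pooled SE (Σwᵢ)^(−1/2), plus Cochran's Q = Σ(β̂ᵢ−β̄)²/SEᵢ²
against χ²(k−1), with the upper-tail p computed via the regularised
incomplete gamma function.  Only the fixed-effect model is provided: the
observed heterogeneity of the published per-pair slopes is non-significant,
which is precisely the justification for a single shared adjustment; a
random-effects estimator would be the wrong tool for the question the
package answers.  Forest-table output assumes 95% confidence intervals by
default (configurable); reporting precision follows the published
convention (slopes 4 dp, χ² 2 dp, p 3 dp).

The canonical pooled slope is the published 0.032.  Pooling the *rounded*
published per-pair estimates gives 0.0325 and Q = 4.42 (vs the printed 4.37);
the printed values were evidently computed from unrounded inputs, so exact
reproduction from the printed table is impossible and the
`reproduce-published` tolerances (±0.002 on β̄, ±0.15 on Q) reflect rounding
propagation, not estimation uncertainty.

Folding β̄ and reference age x̄ into a coefficient set adds β̄·x̄ to the
intercept and −β̄ as a linear age coefficient.  Full precision gives
−6.586 + 0.032·25.09 = −5.78312; the published registry keeps the printed
3-dp −5.783.  Both are available, and fold-then-compute agrees with
compute-then-apply to 1e−9 everywhere (property-tested).

## Decision limits

DL = ȳ + z·s + u with z = 3.72, the 2-dp convention for the one-sided
normal quantile at a 1-in-10,000 false-positive rate (exact 3.7190;
configurable, including via a false-positive rate).  s uses the n−1
denominator.  The finite-sample uncertainty term is implemented literally as
printed, u = √(s²/n (1 + z²/n)).

**Known inconsistency, surfaced deliberately.**  Evaluating that formula at
the published per-pair (s, n) gives u ≈ 0.040, whereas the published table
prints u ≈ 0.187 for the same row — a consistent factor of ≈4.6 across all
twelve rows.  The derivation behind the printed column lives in earlier
decision-limit literature not restated in the source of these tables, so the
package does not guess at a reconciliation: the formula stays literal, the
`reproduce-published` report carries one MISMATCH row per table row, and a
`u_override` argument (plus the verbatim published-u table) lets the printed
DLs be reproduced exactly from printed components.

## The synthetic cohort generator

No real athlete database is public, so the generator emulates the reference
cohort's *structure* with transparent ground truth:

- **Ages**: truncated Gaussian, mean 25.09 y, sd 3.0 y, support [18, 40].
  The published summaries give only the mean; sd and bounds are package choices for
  a plausible elite-athlete range (truncation shifts the realised mean to
  ≈25.16, well inside sampling noise at n = 1000).
- **Markers**: log(marker) = a + b/age + ε.  For males
  (a, b) = (4.54, 24.22) for IGF-I and (0.6065, 17.51) for P-III-NP, chosen
  so that (i) 2.100·b₁ + 2.905·b₂ ≈ 101.737, making the score's 1/age term
  cancel the marker age trends (the clean score is age-flat apart from the
  injected effect), and (ii) median marker levels are physiologically
  plausible (IGF-I ≈ 250 µg/L, Orion P-III-NP ≈ 3.7 µg/L at age 25).  Female
  cohorts rescale b so the female discriminant's 1/age term cancels exactly,
  and inject no age effect.
- **Assay variants**: per-assay log-scale offsets reproduce the published
  spread of per-pair score means (Siemens ≈ +0.63 on log P-III-NP, IDS
  ≈ −0.26 and Immunotech ≈ −0.05 on log IGF-I); per-assay missingness rates
  (0.4–2.5%) give per-pair sample sizes in [940, 1000] at n = 1000.  Noise
  sds (≈0.40 IGF-I, ≈0.30 P-III-NP per variant, latent 0.04/0.03) put every
  per-pair score sd in ≈1.20–1.30, inside the published 1.19–1.41 range.
- **Injected age effect**: the ground-truth residual slope β_true (default
  0.032 score units/year) is a score-scale perturbation
  β_true·(age − 25.09) split evenly between the two log markers
  (d/(2β₁) and d/(2β₂)), so the male score acquires exactly the injected
  slope in expectation while each marker's distortion stays small.  The
  split is recorded verbatim in the `GroundTruth` object.
- **Correlation structure**: each score variant draws its own measurement
  noise around the athlete's shared latent marker level, so the six variants
  correlate only through that latent term (weakly, by default).  This
  mirrors the meta-analytic view that motivates pooling — each assay
  combination treated as an independent realisation from a universe of
  combinations — and it is what makes the fixed-effect pooled SE
  approximately valid on simulated data.  Real assays of the same analyte on
  the same serum sample correlate far more strongly; under such correlation
  the fixed-effect pooled SE understates the true uncertainty of the pooled
  slope (the shared component does not average away) and Cochran's Q becomes
  under-dispersed.  Passing simulation checks therefore validate the
  pooling *machinery*, not the independence assumption on real multi-assay
  data — a limitation shared with the original analysis.
- **Determinism**: one `numpy` Generator seeded from `SimulationParams.seed`
  drives every draw in a fixed order; identical parameters give
  byte-identical cohort files.  Ages and markers are rounded to 6 dp to
  match the CSV dialect's lossless fixed-precision round trip.

## Problem sizes

The heavier checks run at deliberately modest scale, chosen as adequate for
their Monte-Carlo tolerances: the pooled-slope coverage and homogeneity
calibration use 500 cohorts of n = 1000 across all six pairs (coverage
tolerance ≥99% at 3 pooled SEs; rejection rate 5% ± 3 MC SEs); the
Anderson–Darling null calibration uses 500 samples of n = 5000 and a
2000-sample uniformity check at n = 500; single-pair ground-truth recovery
uses 120–200 replicates.

## Anderson–Darling diagnostics

The composite-normality case (both parameters estimated) is the conventional
choice when no variant is specified: A² against the Gaussian with sample
mean and sd, Stephens' small-sample modification A*² = A²(1 + 0.75/n +
2.25/n²), and the D'Agostino–Stephens piecewise-exponential p-value
approximation.  The statistic is location-scale invariant; the p-value is
approximately uniform under the null (KS distance < 0.05 at n = 500,
checked by simulation).  Probability-plot coordinates use plotting positions
(i − 0.3)/(n + 0.4) — a documented convention, not a published choice.
The published per-cohort A² values and p-values belong to the unavailable
real cohort and are not reproduction targets; the simulation-level claim —
that the centred adjustment does not disturb normality — is what the tests
assert.

## Known limitations

- The adjustment and its constants apply to the male elite-athlete
  population only; female scores pass through unchanged in batch pipelines
  (requesting a female adjusted coefficient set directly is an error).
- The generator reproduces published score *moments*, not real marker
  physiology, assay cross-calibration, or doped-athlete distributions; the
  positive class is out of scope.
- Published per-cohort means/sds, scatterplots and normality p-values cannot
  be reproduced without the real databases; only quantities reachable from
  printed inputs are checked exactly.
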