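import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gh2000 import (
    AgeAdjustment,
    AthleteRecord,
    GH2000Score,
    Igf1Assay,
    P3npAssay,
    ScoreCoefficients,
    Sex,
    apply_adjustment,
    compute_score,
    compute_scores,
    fold_adjustment,
    published_coefficients,
)


def _male(igf1=200.0, p3np=5.0, age=25.0) -> AthleteRecord:
    return AthleteRecord("M1", Sex.MALE, age, igf1, p3np, Igf1Assay.LCMS, P3npAssay.SIEMENS)


class TestPublishedCoefficients:
    def test_male_unadjusted(self):
        c = published_coefficients("male")
        assert (c.beta0, c.beta1, c.beta2, c.beta3, c.beta_age) == (
            -6.586, 2.100, 2.905, -101.737, 0.0)

    def test_female_unadjusted(self):
        c = published_coefficients(Sex.FEMALE)
        assert (c.beta0, c.beta1, c.beta2, c.beta3) == (-8.459, 2.195, 2.454, -73.666)

    def test_male_adjusted(self):
        c = published_coefficients("male", adjusted=True)
        assert (c.beta0, c.beta_age) == (-5.783, -0.032)

    def test_adjusted_female_is_an_error(self):
        with pytest.raises(ValueError, match="female"):
            published_coefficients("female", adjusted=True)


class TestComputeScore:
    def test_hand_evaluated_male_example(self):
        # -6.586 + 2.100*ln(200) + 2.905*ln(5) - 101.737/25
        assert compute_score(_male(), published_coefficients("male")) == pytest.approx(
            5.1464, abs=1e-3)

    def test_intercept_only_set_returns_intercept(self):
        c = ScoreCoefficients(Sex.MALE, 3.14, 0.0, 0.0, 0.0)
        assert compute_score(_male(), c) == pytest.approx(3.14)

    @given(age=st.floats(18, 40), igf1=st.floats(50, 800), p3np=st.floats(1, 30))
    @settings(derandomize=True, max_examples=50)
    def test_adjusted_minus_unadjusted_is_affine_in_age(self, age, igf1, p3np):
        # published sets differ by exactly (−5.783 − (−6.586)) − 0.032*age
        rec = _male(igf1, p3np, age)
        diff = compute_score(rec, published_coefficients("male", adjusted=True)) - compute_score(
            rec, published_coefficients("male"))
        assert diff == pytest.approx(0.803 - 0.032 * age, abs=1e-9)

    def test_score_strictly_increasing_in_each_marker(self):
        c = published_coefficients("male")
        base = compute_score(_male(), c)
        assert compute_score(_male(igf1=201), c) > base
        assert compute_score(_male(p3np=5.1), c) > base

    @pytest.mark.parametrize("kw", [{"igf1": -1.0}, {"p3np": 0.0}, {"age": -5.0}])
    def test_nonpositive_inputs_raise(self, kw):
        rec = _male(
            kw.get("igf1", 200.0), kw.get("p3np", 5.0), kw.get("age", 25.0))
        with pytest.raises(ValueError):
            compute_score(rec, published_coefficients("male"))

    def test_sex_mismatch_raises(self):
        with pytest.raises(ValueError, match="sex"):
            compute_score(_male(), published_coefficients("female"))

    def test_missing_marker_raises_scalar_but_nan_vectorised(self):
        rec = AthleteRecord("M1", Sex.MALE, 25.0, None, 5.0, Igf1Assay.LCMS, P3npAssay.SIEMENS)
        with pytest.raises(ValueError, match="missing"):
            compute_score(rec, published_coefficients("male"))
        out = compute_scores([np.nan], [5.0], [25.0], published_coefficients("male"))
        assert np.isnan(out[0])


class TestAdjustment:
    def test_vanishes_at_reference_age(self):
        adj = AgeAdjustment(0.032, 25.09)
        assert apply_adjustment(5.0, 25.09, adj) == pytest.approx(5.0)

    def test_ten_years_older_loses_ten_slopes(self):
        assert apply_adjustment(5.0, 35.09, AgeAdjustment(0.032, 25.09)) == pytest.approx(4.68)

    def test_zero_slope_is_identity(self):
        ages = np.array([18.0, 25.0, 39.0])
        out = apply_adjustment(np.array([1.0, 2.0, 3.0]), ages, AgeAdjustment(0.0, 25.09))
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])


class TestFoldAdjustment:
    def test_fold_reproduces_published_adjusted_intercept(self):
        folded = fold_adjustment(published_coefficients("male"), AgeAdjustment(0.032, 25.09))
        assert folded.beta0 == pytest.approx(-5.78312, abs=1e-9)
        assert round(folded.beta0, 3) == -5.783
        assert folded.beta_age == -0.032

    def test_zero_slope_fold_is_identity(self):
        c = published_coefficients("male")
        folded = fold_adjustment(c, AgeAdjustment(0.0, 25.09))
        assert (folded.beta0, folded.beta_age) == (c.beta0, 0.0)

    def test_refolding_adjusted_set_is_an_error(self):
        with pytest.raises(ValueError, match="refold"):
            fold_adjustment(published_coefficients("male", adjusted=True),
                            AgeAdjustment(0.032, 25.09))

    @given(
        age=st.floats(18, 40), igf1=st.floats(50, 800), p3np=st.floats(1, 30),
        slope=st.floats(-0.1, 0.1), ref=st.floats(18, 35),
    )
    @settings(derandomize=True, max_examples=100)
    def test_fold_then_compute_equals_compute_then_apply(self, age, igf1, p3np, slope, ref):
        rec = _male(igf1, p3np, age)
        coeffs = published_coefficients("male")
        adj = AgeAdjustment(slope, ref)
        folded_score = compute_score(rec, fold_adjustment(coeffs, adj))
        applied = apply_adjustment(compute_score(rec, coeffs), age, adj)
        assert folded_score == pytest.approx(applied, abs=1e-9)


class TestTransformer:
    def test_transform_matches_scalar_scores(self, scored_male_frame):
        df = scored_male_frame.dropna(subset=["igf1_ugL", "p3np_ugL"]).head(20)
        out = GH2000Score(sex="male").fit().transform(df)
        np.testing.assert_allclose(out, df["gh2000_score"].to_numpy(), atol=1e-12)

    def test_sklearn_param_round_trip(self):
        est = GH2000Score(sex="male", adjusted=True)
        assert GH2000Score(**est.get_params()).get_params() == est.get_params()
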