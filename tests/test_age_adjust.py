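import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from gh2000 import (
    AgeEffectRegression,
    adjust,
    fit_age_effect,
    refit_slope_of_adjusted,
    scale_invariance_check,
)


def _sample(rng, n=200, slope=0.05):
    ages = rng.uniform(18, 40, n)
    scores = 4.0 + slope * ages + rng.normal(0, 1.2, n)
    return scores, ages


class TestFit:
    def test_three_point_least_squares_by_hand(self):
        effect = fit_age_effect([1.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert effect.slope == pytest.approx(1.5)
        assert effect.intercept == pytest.approx(-1 / 3)
        assert effect.slope_se == pytest.approx(0.2887, abs=1e-4)
        assert effect.n == 3 and effect.mean_age == pytest.approx(2.0)

    def test_exact_line_has_zero_se(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        effect = fit_age_effect(x, x)
        assert effect.slope == pytest.approx(1.0)
        assert effect.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_has_zero_slope(self):
        assert fit_age_effect([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]).slope == pytest.approx(0.0)

    def test_matches_numpy_polyfit(self, rng):
        scores, ages = _sample(rng)
        effect = fit_age_effect(scores, ages)
        slope, intercept = np.polyfit(ages, scores, 1)
        assert effect.slope == pytest.approx(slope, rel=1e-10)
        assert effect.intercept == pytest.approx(intercept, rel=1e-10)

    def test_constant_ages_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_age_effect([1.0, 2.0, 3.0], [25.0, 25.0, 25.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fit_age_effect([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_age_effect([1.0, 2.0], [1.0, 2.0])


class TestAdjust:
    def test_hand_example_centred_residual(self):
        out = adjust([1.0, 3.0, 4.0], [1.0, 2.0, 3.0], slope=1.5, center=2.0)
        np.testing.assert_allclose(out, [2.5, 3.0, 2.5])

    def test_zero_slope_is_identity(self):
        y = [1.0, 3.0, 4.0]
        np.testing.assert_allclose(adjust(y, [1.0, 2.0, 3.0], 0.0, 2.0), y)

    def test_mean_preserved_when_centred_at_mean_age(self, rng):
        scores, ages = _sample(rng)
        effect = fit_age_effect(scores, ages)
        adjusted = adjust(scores, ages, effect.slope, ages.mean())
        assert adjusted.mean() == pytest.approx(scores.mean(), abs=1e-10)

    @given(
        y=arrays(float, 30, elements=st.floats(-10, 10)),
        slope=st.floats(-1, 1),
    )
    @settings(derandomize=True, max_examples=50)
    def test_mean_preservation_holds_for_any_slope(self, y, slope):
        ages = np.linspace(18, 40, 30)
        adjusted = adjust(y, ages, slope, ages.mean())
        assert adjusted.mean() == pytest.approx(np.mean(y), abs=1e-8)


class TestResidualOrthogonality:
    def test_own_slope_adjustment_has_zero_reslope(self, rng):
        scores, ages = _sample(rng)
        effect = fit_age_effect(scores, ages)
        adjusted = adjust(scores, ages, effect.slope, ages.mean())
        assert abs(refit_slope_of_adjusted(adjusted, ages)) < 1e-10

    def test_zero_slope_adjustment_keeps_original_slope(self, rng):
        scores, ages = _sample(rng)
        effect = fit_age_effect(scores, ages)
        assert refit_slope_of_adjusted(adjust(scores, ages, 0.0, 25.0), ages) == pytest.approx(
            effect.slope)

    def test_half_slope_adjustment_halves_the_slope(self, rng):
        scores, ages = _sample(rng)
        effect = fit_age_effect(scores, ages)
        half = adjust(scores, ages, effect.slope / 2, ages.mean())
        assert refit_slope_of_adjusted(half, ages) == pytest.approx(
            effect.slope / 2, abs=1e-10)

    def test_residuals_orthogonal_to_every_design_column(self, rng):
        # two-covariate general-linear-model residuals: orthogonal to each column
        n = 150
        X = np.column_stack([np.ones(n), rng.uniform(18, 40, n), rng.normal(size=n)])
        y = X @ np.array([2.0, 0.05, -0.3]) + rng.normal(0, 1.0, n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8


class TestScaleInvariance:
    def test_unit_scale_is_exactly_zero(self, rng):
        scores, ages = _sample(rng)
        assert scale_invariance_check(scores, ages, 1.0) == 0.0

    @pytest.mark.parametrize("a_kind", ["norming", -3.7, 0.01, 250.0])
    def test_any_nonzero_rescaling_changes_nothing(self, rng, a_kind):
        scores, ages = _sample(rng)
        a = 1.0 / ages.std(ddof=1) if a_kind == "norming" else a_kind
        assert scale_invariance_check(scores, ages, a) <= 1e-10

    def test_zero_scale_rejected(self, rng):
        scores, ages = _sample(rng)
        with pytest.raises(ValueError, match="nonzero"):
            scale_invariance_check(scores, ages, 0.0)


class TestEstimatorInterface:
    def test_fit_predict_and_center_resolution(self, rng):
        scores, ages = _sample(rng)
        model = AgeEffectRegression(center=25.09).fit(ages, scores)
        assert model.center_ == 25.09
        pred = model.predict([25.0])
        assert pred[0] == pytest.approx(model.intercept_ + 25.0 * model.slope_)
        np.testing.assert_allclose(
            model.adjust(scores, ages), scores - model.slope_ * (ages - 25.09))

    def test_parameter_recovery_within_three_se(self):
        # injected slope recovered within 3 SE in >= 99% of seeds
        hits = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed)
            ages = r.uniform(18, 40, 1000)
            scores = 4.0 + 0.032 * ages + r.normal(0, 1.25, 1000)
            e = fit_age_effect(scores, ages)
            hits += abs(e.slope - 0.032) <= 3 * e.slope_se
        assert hits / reps >= 0.99
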