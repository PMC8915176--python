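import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberpom.birefringence import BirefringenceResult
from fiberpom.calibration_prediction import (
    FiberSummary,
    diameter_only_baseline,
    fit_strength_model,
    predict_strength,
    summarize_fiber,
)
from fiberpom.morphometry import MorphometryResult


def frame(mean_diam, mean_int, n_axis=100, area=1000.0):
    morph = MorphometryResult(
        fiber_area=area,
        mean_diameter=mean_diam,
        sd_diameter=0.1,
        min_diameter=mean_diam * 0.9,
        threshold_used=148,
        n_axis_samples=n_axis,
    )
    biref = BirefringenceResult(
        mean_intensity_full=mean_int,
        sd_intensity_full=1.0,
        mean_intensity_bright=None,
        n_segments=0,
        mean_segment_area=None,
        min_segment_area=None,
        max_segment_area=None,
        bright_fraction=0.0,
    )
    return morph, biref


def make_summaries(ni, strength, setup="setup1"):
    return [
        FiberSummary(
            fiber_id=f"f{i}",
            mean_diameter=4.0,
            mean_intensity=4.0 * ni[i],
            normalized_intensity=ni[i],
            n_frames=1,
            measured_strength=None if strength is None else strength[i],
            setup=setup,
        )
        for i in range(len(ni))
    ]


class TestSummarizeFiber:
    def test_single_frame_ratio(self):
        s = summarize_fiber("x", [frame(4.0, 120.0)])
        assert s.normalized_intensity == pytest.approx(30.0)

    def test_equal_weight_pooling_hand_arithmetic(self):
        s = summarize_fiber("x", [frame(4.0, 100.0), frame(6.0, 140.0)])
        assert s.mean_diameter == pytest.approx(5.0)
        assert s.mean_intensity == pytest.approx(120.0)
        assert s.normalized_intensity == pytest.approx(24.0)

    def test_pixel_weighted_pooling_matches_population_oracle(self):
        # oracle: pool the actual pixel populations, then take plain means
        rng = np.random.default_rng(0)
        pix_a = rng.integers(80, 120, size=5000).astype(float)  # 10x the pixels
        pix_b = rng.integers(150, 200, size=500).astype(float)
        oracle_mean = np.concatenate([pix_a, pix_b]).mean()
        s = summarize_fiber(
            "x",
            [
                frame(4.0, pix_a.mean(), n_axis=100, area=5000.0),
                frame(4.0, pix_b.mean(), n_axis=100, area=500.0),
            ],
        )
        assert s.mean_intensity == pytest.approx(oracle_mean)

    def test_unweighted_mode(self):
        s = summarize_fiber(
            "x", [frame(4.0, 100.0, area=5000.0), frame(6.0, 140.0, area=500.0)],
            weighting="frames",
        )
        assert s.mean_intensity == pytest.approx(120.0)

    def test_empty_input(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_fiber("x", [])


class TestFit:
    def test_noise_free_line_recovered_exactly(self):
        ni = np.linspace(10, 50, 10)
        model = fit_strength_model(make_summaries(ni, 5.0 + 2.0 * ni))
        assert model.intercept == pytest.approx(5.0, abs=1e-8)
        assert model.slope == pytest.approx(2.0, abs=1e-9)
        assert model.pearson_r_abs == pytest.approx(1.0)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert model.model_form == "linear"

    def test_absolute_r_for_negative_association(self):
        ni = np.linspace(10, 50, 10)
        model = fit_strength_model(make_summaries(ni, 200.0 - 2.0 * ni))
        assert model.slope == pytest.approx(-2.0, abs=1e-9)
        assert model.pearson_r_abs == pytest.approx(1.0)

    def test_quadratic_retained_when_curvature_is_real(self):
        ni = np.linspace(10, 50, 40)
        rng = np.random.default_rng(1)
        y = 5 + 2 * ni + 0.5 * ni**2 + rng.normal(0, 1, ni.size)
        model = fit_strength_model(make_summaries(ni, y))
        assert model.model_form == "quadratic"
        assert model.lr_test_p < 0.05
        assert model.quad_coef == pytest.approx(0.5, abs=0.05)

    def test_degenerate_predictor_and_small_n(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_strength_model(make_summaries(np.full(5, 10.0), np.arange(5.0) + 1))
        with pytest.raises(ValueError, match="at least 3"):
            fit_strength_model(make_summaries(np.array([1.0, 2.0]), np.array([1.0, 2.0])))

    def test_residuals_orthogonal_to_predictor(self):
        rng = np.random.default_rng(3)
        ni = rng.uniform(10, 50, 30)
        y = 5 + 2 * ni + rng.normal(0, 10, 30)
        model = fit_strength_model(make_summaries(ni, y), allow_quadratic_check=False)
        resid = y - model.predict(ni)
        scale = len(y) * np.abs(ni).max() * np.abs(y).max()
        assert abs(np.dot(resid, ni)) < 1e-8 * scale
        assert abs(resid.sum()) < 1e-8 * scale  # intercept column too

    @given(a=st.floats(0.1, 10), b=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_abs_r_invariant_under_affine_predictor_maps(self, a, b):
        rng = np.random.default_rng(7)
        ni = rng.uniform(10, 50, 20)
        y = 5 + 2 * ni + rng.normal(0, 10, 20)
        base = fit_strength_model(make_summaries(ni, y), allow_quadratic_check=False)
        mapped = fit_strength_model(make_summaries(a * ni + b, y), allow_quadratic_check=False)
        assert mapped.pearson_r_abs == pytest.approx(base.pearson_r_abs, abs=1e-9)


class TestPredict:
    def _model(self):
        ni = np.linspace(10, 50, 10)
        return fit_strength_model(make_summaries(ni, 5.0 + 2.0 * ni))

    def test_line_evaluation(self):
        model = self._model()
        report = predict_strength(model, make_summaries(np.array([10.0, 20.0, 30.0]), None))
        np.testing.assert_allclose(report.predicted_strength, [25.0, 45.0, 65.0])

    def test_percent_difference_hand_arithmetic(self):
        pred = np.array([10.0, 20.0])
        meas = np.array([10.0, 25.0])
        pct = np.abs(pred - meas) / meas * 100
        np.testing.assert_allclose(pct, [0.0, 20.0])
        assert pct.mean() == pytest.approx(10.0)

    def test_self_prediction_on_noise_free_data(self):
        ni = np.linspace(10, 50, 10)
        summaries = make_summaries(ni, 5.0 + 2.0 * ni)
        report = predict_strength(self._model(), summaries)
        assert report.mean_percent_difference == pytest.approx(0.0, abs=1e-9)
        assert report.pearson_r_abs_pred_vs_meas == pytest.approx(1.0)

    def test_prediction_monotone_in_ni_for_positive_slope(self):
        model = self._model()
        ni = np.sort(np.random.default_rng(0).uniform(5, 60, 15))
        report = predict_strength(model, make_summaries(ni, None))
        assert np.all(np.diff(report.predicted_strength) >= 0)

    def test_cross_setup_prediction_refused_without_override(self):
        model = self._model()  # setup1
        other = make_summaries(np.array([10.0, 20.0, 30.0]), None, setup="setup2")
        with pytest.raises(ValueError, match="cross_setup"):
            predict_strength(model, other)
        report = predict_strength(model, other, allow_cross_setup=True)
        assert len(report.predicted_strength) == 3


class TestDiameterBaseline:
    def test_noise_free_diameter_law_gives_r_one(self):
        d = np.linspace(3.1, 5.0, 10)
        summaries = [
            FiberSummary(
                fiber_id=f"f{i}",
                mean_diameter=d[i],
                mean_intensity=100.0,
                normalized_intensity=100.0 / d[i],
                n_frames=1,
                measured_strength=300.0 - 40.0 * d[i],
                setup="setup1",
            )
            for i in range(10)
        ]
        model, report = diameter_only_baseline(summaries)
        assert model.predictor == "mean_diameter"
        assert model.pearson_r_abs == pytest.approx(1.0)
        assert report.mean_percent_difference == pytest.approx(0.0, abs=1e-8)

    def test_constant_diameter_is_degenerate(self):
        summaries = make_summaries(np.linspace(10, 50, 5), np.linspace(30, 170, 5))
        with pytest.raises(ValueError, match="zero variance"):
            diameter_only_baseline(summaries)  # mean_diameter fixed at 4.0 in helper

    def test_ni_model_beats_diameter_when_truth_is_ni(self):
        from fiberpom.synthetic_fibergen import generate_cohort

        cohort = generate_cohort(40, seed=11, diameter_slope=-2.0)
        ni_model = fit_strength_model(cohort.summaries)
        d_model, _ = diameter_only_baseline(cohort.summaries)
        assert ni_model.pearson_r_abs > d_model.pearson_r_abs
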