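import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_yen as skimage_yen

from fiberpom.segmentation import (
    NoFiberError,
    ThresholdSpec,
    segment_bright_areas,
    segment_fiber,
    yen_threshold,
)

from conftest import make_band_image, random_histograms, yen_criterion_exhaustive


class TestYenThreshold:
    def test_matches_exhaustive_oracle_on_random_histograms(self):
        for hist in random_histograms(100, seed=42):
            assert yen_threshold(hist) == yen_criterion_exhaustive(hist)

    def test_two_isolated_modes_are_split(self):
        hist = np.zeros(256, dtype=int)
        hist[50], hist[200] = 500, 1500
        t = yen_threshold(hist)
        assert 50 < t <= 200
        assert (50 < t) and (200 >= t)  # dark class {i < t} holds 50, bright holds 200

    def test_separates_noisy_fiber_background_modes(self):
        # fiber-like mixture: ~19% dark pixels (a 12-px band in a 64-row frame).
        # Yen's criterion sits near the lower tail of the dominant bright mode,
        # so the dark (fiber) class is recovered essentially pure while a few
        # percent of background tail pixels fall below the threshold.
        rng = np.random.default_rng(7)
        dark = rng.normal(60, 5, 15000)
        bright = rng.normal(220, 5, 65000)
        img = np.clip(np.round(np.concatenate([dark, bright])), 0, 255).astype(int)
        t = yen_threshold(np.bincount(img, minlength=256))
        assert 60 < t < 220
        dark_px = np.clip(np.round(dark), 0, 255)
        bright_px = np.clip(np.round(bright), 0, 255)
        assert (dark_px < t).mean() > 0.99
        assert (bright_px >= t).mean() > 0.90

    def test_single_valued_image_is_an_error(self):
        hist = np.zeros(256, dtype=int)
        hist[77] = 1000
        with pytest.raises(ValueError, match="no threshold separates"):
            yen_threshold(hist)

    def test_agrees_with_skimage_cross_check(self):
        # skimage scores splits at bin centers (foreground strictly above);
        # our convention shifts the returned level by one, hence the band.
        for hist in random_histograms(50, seed=3):
            ours = yen_threshold(hist)
            theirs = skimage_yen(hist=(hist, np.arange(256)))
            assert theirs <= ours <= theirs + 1


class TestSegmentFiber:
    def test_band_area_recovered_with_fixed_threshold(self):
        img = make_band_image(band_rows=slice(26, 38))  # 12 px wide band
        mask = segment_fiber(img, ThresholdSpec("fixed", 148))
        truth = 12 * img.shape[1]
        assert abs(mask.area_px - truth) / truth < 0.02
        assert mask.threshold_used == 148

    def test_small_speck_filtered_out(self):
        img = make_band_image()
        img[5:6, 10:15] = 60  # 5-px dark speck far from the band
        mask = segment_fiber(img, ThresholdSpec("fixed", 148), min_area_px=50)
        assert not mask.mask[5, 10:15].any()
        assert mask.mask[30, :].all()

    def test_widest_component_wins_over_larger_blob(self):
        img = np.full((64, 400), 220, dtype=np.uint8)
        img[30:33, :] = 60  # thin full-width fiber: 1200 px, extent 400
        img[0:28, 5:55] = 60  # disconnected blob: 1400 px, extent 50
        mask = segment_fiber(img, ThresholdSpec("fixed", 148))
        assert mask.mask[31, 399]
        assert not mask.mask[5, 5]

    def test_holes_are_filled(self):
        img = make_band_image()
        img[30:32, 100:110] = 220  # bright hole inside the fiber
        mask = segment_fiber(img, ThresholdSpec("fixed", 148))
        assert mask.mask[30, 105]

    def test_uniform_image_raises_no_fiber(self):
        img = np.full((64, 400), 220, dtype=np.uint8)
        with pytest.raises(NoFiberError):
            segment_fiber(img, ThresholdSpec("fixed", 148))

    def test_fixed_mode_is_bit_deterministic(self):
        img = make_band_image(noise_sd=5, seed=11)
        m1 = segment_fiber(img, ThresholdSpec("fixed", 148))
        m2 = segment_fiber(img, ThresholdSpec("fixed", 148))
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_auto_yen_segments_synthetic_fiber(self):
        img = make_band_image(noise_sd=5, seed=2)
        mask = segment_fiber(img, ThresholdSpec("auto_yen"))
        truth = 12 * img.shape[1]
        assert abs(mask.area_px - truth) / truth < 0.02

    @given(t1=st.integers(1, 254), t2=st.integers(1, 254))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_shrinks_foreground(self, t1, t2):
        t1, t2 = sorted((t1, t2))
        img = make_band_image(noise_sd=20, seed=5)
        assert not ((img < t1) & ~(img < t2)).any()


class TestThresholdSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "fixed"},
            {"mode": "fixed", "fixed_value": 300},
            {"mode": "auto_yen", "fixed_value": 148},
            {"mode": "bogus"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThresholdSpec(**kwargs)


class TestBrightAreas:
    def _fiber(self):
        img = make_band_image()
        return segment_fiber(img, ThresholdSpec("fixed", 148))

    def test_uniform_dark_pom_gives_empty_mask(self):
        fiber = self._fiber()
        pom = np.zeros(fiber.mask.shape, dtype=np.uint8)
        bright = segment_bright_areas(pom, fiber, 100)
        assert bright.mask.sum() == 0

    def test_uniform_bright_pom_equals_fiber_mask(self):
        fiber = self._fiber()
        pom = np.full(fiber.mask.shape, 255, dtype=np.uint8)
        bright = segment_bright_areas(pom, fiber, 100)
        np.testing.assert_array_equal(bright.mask, fiber.mask)

    def test_patch_pixels_clipped_to_fiber(self):
        fiber = self._fiber()
        pom = np.zeros(fiber.mask.shape, dtype=np.uint8)
        pom[20:45, 50:70] = 200  # patch taller than the fiber band
        bright = segment_bright_areas(pom, fiber, 100)
        expected = (fiber.mask & (pom > 100)).sum()
        assert bright.mask.sum() == expected == 12 * 20
        assert not (bright.mask & ~fiber.mask).any()

    def test_shape_mismatch(self):
        fiber = self._fiber()
        with pytest.raises(ValueError, match="does not match"):
            segment_bright_areas(np.zeros((3, 3), np.uint8), fiber, 100)
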