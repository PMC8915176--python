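import numpy as np
import pytest

from fiberpom.image_io import PixelCalibration
from fiberpom.segmentation import FiberMask


@pytest.fixture
def calib():
    return PixelCalibration(microns_per_pixel=1.0)


@pytest.fixture
def band_mask():
    """Horizontal band of width 11 px in a 64x400 frame, as a FiberMask."""
    mask = np.zeros((64, 400), dtype=bool)
    mask[26:37, :] = True
    return FiberMask(mask=mask, threshold_used=148)


def make_band_image(
    shape=(64, 400),
    band_rows=slice(26, 38),
    fiber_level=60,
    background_level=220,
    noise_sd=0.0,
    seed=0,
):
    """Dark horizontal band on a bright background, 8-bit."""
    img = np.full(shape, float(background_level))
    img[band_rows, :] = fiber_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sd, shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def yen_criterion_exhaustive(histogram):
    """Independent exhaustive oracle for Yen's threshold.

    For every candidate split T in 1..255 the entropic-correlation criterion
    is computed from scratch with direct sums (no cumulative arrays); the
    lowest maximizing T is returned.
    """
    h = [int(v) for v in histogram]
    n = sum(h)
    best_t, best_val = None, -np.inf
    for t in range(1, 256):
        c1 = sum(h[:t])
        c2 = n - c1
        s1 = sum(v * v for v in h[:t])
        s2 = sum(v * v for v in h[t:])
        if c1 == 0 or c2 == 0 or s1 == 0 or s2 == 0:
            continue
        val = 2 * np.log(c1 * c2) - (np.log(s1) + np.log(s2))
        if val > best_val:
            best_val, best_t = val, t
    return best_t


def random_histograms(n, seed):
    """A varied batch of 256-bin histograms for oracle comparisons."""
    rng = np.random.default_rng(seed)
    hists = []
    for _ in range(n):
        kind = rng.integers(3)
        if kind == 0:  # dense random counts
            h = rng.integers(0, 1000, size=256)
        elif kind == 1:  # sparse
            h = np.zeros(256, dtype=int)
            idx = rng.choice(256, size=rng.integers(2, 20), replace=False)
            h[idx] = rng.integers(1, 500, size=len(idx))
        else:  # noisy bimodal
            lo, hi = sorted(rng.choice(np.arange(20, 236), size=2, replace=False))
            x = np.concatenate(
                [
                    rng.normal(lo, rng.uniform(2, 10), size=rng.integers(200, 2000)),
                    rng.normal(hi, rng.uniform(2, 10), size=rng.integers(200, 2000)),
                ]
            )
            h = np.bincount(np.clip(np.round(x), 0, 255).astype(int), minlength=256)
        if np.count_nonzero(h) < 2:
            h[[40, 200]] += 1
        hists.append(h)
    return hists
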