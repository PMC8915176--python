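"""Fiber and bright-area segmentation.

Two-stage segmentation: (1) the fiber region is found in the brightfield
frame, where the fiber is dark on a bright background, with either Yen's
entropic thresholding or a fixed user threshold; (2) within that region the
birefringent ("bright") areas of the POM frame are the pixels strictly above
a second cut-off.  Both comparisons are strict: fiber pixels satisfy
``brightfield < threshold`` and bright pixels satisfy ``pom > cut-off``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

#: Fixed brightfield threshold used with the primary microscope configuration.
DEFAULT_BF_THRESHOLD_SETUP1 = 148
#: Fixed brightfield threshold for the second (older) microscope configuration.
DEFAULT_BF_THRESHOLD_SETUP2 = 103
#: Default POM bright-area cut-off (8-bit scale); always recorded in output.
DEFAULT_BRIGHT_THRESHOLD = 100

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


class NoFiberError(ValueError):
    """No connected component survived thresholding and area filtering."""

    def __init__(self, threshold: int):
        self.threshold = threshold
        super().__init__(f"no fiber detected at threshold {threshold}")


@dataclass(frozen=True)
class ThresholdSpec:
    """Brightfield threshold choice: Yen's automatic method or a fixed value."""

    mode: Literal["auto_yen", "fixed"]
    fixed_value: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.fixed_value is None:
                raise ValueError("fixed mode requires fixed_value")
            if not 0 <= self.fixed_value <= 255:
                raise ValueError("fixed_value must be in [0, 255]")
        elif self.mode == "auto_yen":
            if self.fixed_value is not None:
                raise ValueError("fixed_value is only valid in fixed mode")
        else:
            raise ValueError(f"unknown threshold mode {self.mode!r}")


@dataclass
class FiberMask:
    """Binary fiber region of one frame plus the threshold that produced it."""

    mask: np.ndarray
    threshold_used: int
    source_frame: tuple[str, int] = ("", 0)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class BrightAreaMask:
    """Bright (birefringent) pixels inside a fiber mask."""

    mask: np.ndarray
    bright_threshold: int
    parent: FiberMask

    def __post_init__(self) -> None:
        if self.mask.shape != self.parent.mask.shape:
            raise ValueError("bright mask and parent fiber mask shapes differ")
        if np.any(self.mask & ~self.parent.mask):
            raise AssertionError("bright pixels found outside the fiber mask")


def yen_threshold(histogram: np.ndarray) -> int:
    """Integer threshold maximizing Yen's entropic-correlation criterion.

    ``histogram`` is the 256-bin intensity histogram of an 8-bit image.  A
    candidate threshold ``T`` splits the levels into a dark class {i < T}
    and a bright class {i >= T} (matching the strict comparisons used for
    segmentation), scored by the entropic-correlation criterion

        TC(T) = 2 ln[P(T) (1 - P(T))] - ln[S1(T) S2(T)]

    with ``P`` the dark-class probability and ``S1``/``S2`` the sums of
    squared bin probabilities in the dark and bright classes.  The maximizing
    ``T`` is returned, ties broken toward the lower level.  Raises if fewer
    than two bins are occupied, since then no threshold separates foreground
    from background.
    """
    hist = np.asarray(histogram)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.count_nonzero(hist) < 2:
        raise ValueError("no threshold separates foreground from background")

    # Integer cumulative sums keep plateaus exactly flat, so the lower-level
    # tie-break is well defined; normalization by N only shifts TC by a
    # constant and is dropped.
    h = hist.astype(np.int64)
    c = np.cumsum(h)
    n = c[-1]
    s1 = np.cumsum(h * h)
    s2 = np.cumsum((h * h)[::-1])[::-1]  # s2[t] = sum_{i >= t} h_i^2

    # crit[k] scores threshold T = k + 1 (dark class = levels 0..k)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = 2.0 * np.log(c[:-1] * (n - c[:-1])) - (np.log(s1[:-1]) + np.log(s2[1:]))
    crit[~np.isfinite(crit)] = -np.inf
    return int(np.argmax(crit)) + 1  # argmax keeps the first (lowest) maximizer


def resolve_threshold(brightfield: np.ndarray, spec: ThresholdSpec) -> int:
    """Turn a ThresholdSpec into a concrete intensity level for one frame."""
    if spec.mode == "fixed":
        return int(spec.fixed_value)  # type: ignore[arg-type]
    hist = np.bincount(brightfield.ravel(), minlength=256)[:256]
    return yen_threshold(hist)


def segment_fiber(
    brightfield: np.ndarray,
    spec: ThresholdSpec,
    min_area_px: int = 50,
    source_frame: tuple[str, int] = ("", 0),
) -> FiberMask:
    """Segment the dark fiber from the bright background of one frame.

    Pixels strictly below the threshold are foreground.  Holes are filled,
    components smaller than ``min_area_px`` are discarded, and of the
    survivors the one with the largest horizontal extent (tie: larger area)
    is kept — fibers traverse the frame horizontally, while dust and local
    shadows do not.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    threshold = resolve_threshold(brightfield, spec)
    fg = brightfield < threshold
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=_EIGHT_CONN)
    if n == 0:
        raise NoFiberError(threshold)

    objects = ndimage.find_objects(labels)
    best_label = 0
    best_key = (-1, -1)
    for lab, sl in enumerate(objects, start=1):
        area = int((labels[sl] == lab).sum())
        if area < min_area_px:
            continue
        extent = sl[1].stop - sl[1].start
        key = (extent, area)
        if key > best_key:
            best_key = key
            best_label = lab
    if best_label == 0:
        raise NoFiberError(threshold)
    return FiberMask(
        mask=labels == best_label, threshold_used=threshold, source_frame=source_frame
    )


def segment_bright_areas(
    pom: np.ndarray,
    fiber: FiberMask,
    bright_threshold: int = DEFAULT_BRIGHT_THRESHOLD,
) -> BrightAreaMask:
    """Bright birefringent areas: fiber pixels with POM intensity above cut-off.

    No morphological cleanup is applied, so segments may be single pixels.
    """
    if pom.shape != fiber.mask.shape:
        raise ValueError(
            f"POM shape {pom.shape} does not match fiber mask {fiber.mask.shape}"
        )
    bright = fiber.mask & (pom > bright_threshold)
    return BrightAreaMask(mask=bright, bright_threshold=int(bright_threshold), parent=fiber)
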