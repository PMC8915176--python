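"""Birefringence quantification from the POM frame.

At fixed exposure the POM pixel intensity inside the fiber is a proxy for
local structural alignment (birefringence).  Per frame this module reports
the full-fiber intensity mean/SD, the mean intensity of the bright areas, a
decomposition of the bright mask into 8-connected segments with per-segment
area and intensity, and a generic set of bright-fraction combination
parameters.  Statistics that are undefined when no bright pixel exists are
reported as ``None`` (nulls in CSV), never as 0, so they cannot bias
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .image_io import PixelCalibration
from .segmentation import BrightAreaMask, FiberMask


@dataclass
class BrightSegment:
    """One 8-connected bright area inside the fiber."""

    segment_id: int
    area: float  # um^2
    mean_intensity: float
    centroid: tuple[float, float]  # (row, col) in pixels


@dataclass
class BirefringenceResult:
    """Per-frame POM intensity and bright-segment statistics."""

    mean_intensity_full: float
    sd_intensity_full: float
    mean_intensity_bright: float | None
    n_segments: int
    mean_segment_area: float | None  # um^2
    min_segment_area: float | None
    max_segment_area: float | None
    bright_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_intensity_full <= 255.0:
            raise ValueError("mean_intensity_full out of 8-bit range")
        if not 0.0 <= self.bright_fraction <= 1.0:
            raise ValueError("bright_fraction must be in [0, 1]")
        if self.n_segments > 0:
            assert self.min_segment_area <= self.mean_segment_area <= self.max_segment_area


def intensity_stats(pom: np.ndarray, fiber: FiberMask) -> tuple[float, float]:
    """Mean and sample SD of POM intensity over fiber pixels only."""
    if pom.shape != fiber.mask.shape:
        raise ValueError("POM and fiber mask shapes differ")
    values = pom[fiber.mask].astype(float)
    if values.size == 0:
        raise ValueError("empty fiber mask")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def analyze_bright_segments(
    bright: BrightAreaMask,
    pom: np.ndarray,
    calibration: PixelCalibration,
) -> tuple[list[BrightSegment], BirefringenceResult]:
    """Enumerate 8-connected bright segments and assemble the frame result.

    An empty bright mask is not an error: it yields ``n_segments = 0``,
    ``bright_fraction = 0`` and ``None`` for the bright-only statistics.
    """
    fiber = bright.parent
    mean_full, sd_full = intensity_stats(pom, fiber)
    px_area = calibration.microns_per_pixel**2

    labels = label(bright.mask, connectivity=2)
    segments = [
        BrightSegment(
            segment_id=p.label,
            area=p.area * px_area,
            mean_intensity=float(p.intensity_mean),
            centroid=tuple(p.centroid),
        )
        for p in regionprops(labels, intensity_image=pom)
    ]

    n_bright = int(bright.mask.sum())
    if segments:
        areas = np.array([s.area for s in segments])
        seg_mean, seg_min, seg_max = float(areas.mean()), float(areas.min()), float(areas.max())
        mean_bright = float(pom[bright.mask].mean())
    else:
        seg_mean = seg_min = seg_max = None
        mean_bright = None

    result = BirefringenceResult(
        mean_intensity_full=mean_full,
        sd_intensity_full=sd_full,
        mean_intensity_bright=mean_bright,
        n_segments=len(segments),
        mean_segment_area=seg_mean,
        min_segment_area=seg_min,
        max_segment_area=seg_max,
        bright_fraction=n_bright / fiber.area_px,
    )
    return segments, result


def combination_parameters(
    result: BirefringenceResult,
    morph_mean_diameter: float,
    fiber_area: float,
) -> dict[str, float | None]:
    """Generic bright-fraction combination parameters.

    This is a non-canonical convenience set combining the per-frame outputs;
    the headline strength predictor (intensity normalized by diameter at the
    fiber level) lives in :mod:`fiberpom.calibration_prediction`.
    """
    bf = result.bright_fraction
    return {
        "bright_fraction": bf,
        "bright_fraction_x_mean_bright": (
            bf * result.mean_intensity_bright
            if result.mean_intensity_bright is not None
            else None
        ),
        "total_intensity_x_area": result.mean_intensity_full * fiber_area,
        "intensity_over_diameter": result.mean_intensity_full / morph_mean_diameter,
    }
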