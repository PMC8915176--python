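"""Fiber morphology from the segmented mask.

The local diameter is measured everywhere along the fiber: the Euclidean
distance transform (EDT) of the mask gives each fiber pixel its distance to
the nearest background pixel, and twice the EDT value sampled on the medial
axis (topological skeleton) is the local width.  Summaries are the per-frame
outputs: fiber area, mean/SD/minimum diameter and the threshold used.

Axis pixels within one local diameter of the left/right frame borders are
excluded because the EDT there reflects the frame truncating the fiber, not
the fiber itself; short skeleton spurs caused by boundary noise are pruned
before measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis

from .image_io import PixelCalibration
from .segmentation import FiberMask


@dataclass
class DiameterProfile:
    """Local diameter sampled at every medial-axis pixel."""

    positions: np.ndarray  # (n, 2) array of (row, col) axis pixels
    local_diameter: np.ndarray  # um, same length

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.local_diameter):
            raise ValueError("positions and local_diameter lengths differ")
        if len(self.local_diameter) and not np.all(self.local_diameter > 0):
            raise ValueError("all local diameters must be positive")

    @property
    def n_axis_samples(self) -> int:
        return len(self.local_diameter)


@dataclass
class MorphometryResult:
    """Per-frame morphology outputs."""

    fiber_area: float  # um^2
    mean_diameter: float  # um
    sd_diameter: float  # um
    min_diameter: float  # um
    threshold_used: int
    n_axis_samples: int

    def __post_init__(self) -> None:
        if self.min_diameter > self.mean_diameter + 1e-12:
            raise ValueError("min_diameter cannot exceed mean_diameter")
        if self.sd_diameter < 0 or self.fiber_area <= 0:
            raise ValueError("invalid morphometry values")


def _prune_spurs(skeleton: np.ndarray, prune_px: int) -> np.ndarray:
    """Iteratively strip skeleton endpoints to remove spurs up to prune_px long."""
    skel = skeleton.copy()
    kernel = np.ones((3, 3), dtype=int)
    for _ in range(prune_px):
        neighbors = ndimage.convolve(skel.astype(int), kernel, mode="constant") - skel
        endpoints = skel & (neighbors <= 1)
        if not endpoints.any():
            break
        remaining = skel & ~endpoints
        if not remaining.any():  # keep at least the skeleton core
            break
        skel = remaining
    return skel


def diameter_profile(
    mask: FiberMask,
    calibration: PixelCalibration,
    prune_px: int = 10,
) -> DiameterProfile:
    """Local fiber diameter (2x EDT) at every medial-axis pixel, in um.

    Raises if the mask is empty or no axis pixel survives pruning and the
    left/right border exclusion.
    """
    m = mask.mask
    if not m.any():
        raise ValueError("empty fiber mask")

    edt = ndimage.distance_transform_edt(m)
    skel = medial_axis(m)
    skel = _prune_spurs(skel, prune_px)
    if not skel.any():
        raise ValueError("skeleton empty after spur pruning")

    rows, cols = np.nonzero(skel)
    diam_px = 2.0 * edt[rows, cols]
    width = m.shape[1]
    keep = (cols >= diam_px) & (cols <= width - 1 - diam_px)
    if not keep.any():
        raise ValueError("no axis samples away from the frame borders")
    rows, cols, diam_px = rows[keep], cols[keep], diam_px[keep]

    order = np.lexsort((rows, cols))  # deterministic: by column, then row
    positions = np.column_stack([rows[order], cols[order]])
    return DiameterProfile(
        positions=positions,
        local_diameter=diam_px[order] * calibration.microns_per_pixel,
    )


def summarize_morphology(
    profile: DiameterProfile,
    mask: FiberMask,
    calibration: PixelCalibration,
) -> MorphometryResult:
    """Reduce a diameter profile and mask to the per-frame morphology outputs.

    SD is the sample (n-1) standard deviation; it is 0 for a single sample.
    """
    d = profile.local_diameter
    if len(d) == 0:
        raise ValueError("empty diameter profile")
    return MorphometryResult(
        fiber_area=mask.area_px * calibration.microns_per_pixel**2,
        mean_diameter=float(np.mean(d)),
        sd_diameter=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        min_diameter=float(np.min(d)),
        threshold_used=mask.threshold_used,
        n_axis_samples=len(d),
    )
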