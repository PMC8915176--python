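"""Ground-truthed synthetic micrographs and calibration cohorts.

Renders brightfield/POM frame pairs that emulate the acquisition geometry of
the real data: a dark fiber band crossing a bright background horizontally
in brightfield, and the same fiber bright on a dark background under crossed
polarizers, with optional bright patches standing in for the patchy
birefringence real recombinant fibers show along their length.  Every render
carries an analytic :class:`GroundTruth` computed from the specification
itself — never from the rendered pixels or the pipeline's own segmentation —
so segmentation, morphometry and birefringence can be validated end to end
without external data.

Edges are hard (no anti-aliasing) by default so mask-recovery tests have an
exact truth; noise is additive Gaussian clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .calibration_prediction import FiberSummary
from .image_io import ImagePair, PixelCalibration

WidthProfile = Callable[[np.ndarray], np.ndarray]  # x (um) -> width (um)
Centerline = Callable[[np.ndarray], np.ndarray]  # x (um) -> vertical offset (um)


def constant_width(width_um: float) -> WidthProfile:
    return lambda x: np.full_like(np.asarray(x, dtype=float), width_um)


def linear_taper(width_start_um: float, width_end_um: float, length_um: float) -> WidthProfile:
    def profile(x):
        t = np.clip(np.asarray(x, dtype=float) / length_um, 0.0, 1.0)
        return width_start_um + (width_end_um - width_start_um) * t

    return profile


def sinusoidal_width(mean_um: float, amplitude_um: float, period_um: float) -> WidthProfile:
    def profile(x):
        return mean_um + amplitude_um * np.sin(2 * np.pi * np.asarray(x, dtype=float) / period_um)

    return profile


@dataclass
class BrightPatch:
    """A longitudinal interval of elevated POM intensity (one birefringent segment)."""

    start_um: float
    end_um: float
    level: int

    def __post_init__(self) -> None:
        if self.end_um <= self.start_um:
            raise ValueError("patch must have positive length")
        if not 0 <= self.level <= 255:
            raise ValueError("patch level must be an 8-bit intensity")


@dataclass
class FiberSpec:
    """Analytic description of one synthetic fiber frame."""

    width_profile: WidthProfile
    centerline: Centerline | None = None  # default: straight, mid-frame
    bf_fiber_level: int = 60
    bf_background_level: int = 220
    pom_base_level: int = 30
    pom_background_level: int = 8
    patches: list[BrightPatch] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bf_fiber_level < self.bf_background_level:
            raise ValueError("brightfield fiber must be darker than the background")
        for lvl in (
            self.bf_fiber_level,
            self.bf_background_level,
            self.pom_base_level,
            self.pom_background_level,
        ):
            if not 0 <= lvl <= 255:
                raise ValueError("intensity levels must be in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Analytic truth for one rendered pair (independent of noise and pipeline)."""

    mask: np.ndarray  # bool, true fiber pixels
    mean_diameter_um: float
    min_diameter_um: float
    mean_pom_intensity: float  # noiseless mean over the true mask
    patch_inventory: list[dict]  # per-patch: area_px, area_um2, level, columns


def render_pair(
    spec: FiberSpec,
    shape: tuple[int, int],
    calibration: PixelCalibration,
    fiber_id: str = "synthetic",
    frame_index: int = 0,
) -> tuple[ImagePair, GroundTruth]:
    """Render one brightfield/POM pair with its analytic ground truth.

    The fiber is rasterized column by column: at column x the band is
    ``round(width(x) / scale)`` pixels tall, centered on the centerline.
    Determinism: identical spec (including seed) gives bit-identical images.
    """
    h, w = shape
    upp = calibration.microns_per_pixel
    cols = np.arange(w)
    x_um = (cols + 0.5) * upp
    width_um = np.asarray(spec.width_profile(x_um), dtype=float)
    if np.any(width_um <= 0):
        raise ValueError("width profile must be positive everywhere")
    n_px = np.maximum(np.round(width_um / upp).astype(int), 1)
    if n_px.max() > h:
        raise ValueError("fiber wider than frame")

    if spec.centerline is None:
        cy = np.full(w, h / 2.0)
    else:
        cy = h / 2.0 + np.asarray(spec.centerline(x_um), dtype=float) / upp
    top = np.round(cy - n_px / 2.0).astype(int)
    if top.min() < 0 or (top + n_px).max() > h:
        raise ValueError("fiber does not fit inside the frame vertically")

    mask = np.zeros((h, w), dtype=bool)
    rows_grid = np.arange(h)[:, None]
    mask = (rows_grid >= top[None, :]) & (rows_grid < (top + n_px)[None, :])

    # Noiseless fields
    bf = np.full((h, w), float(spec.bf_background_level))
    bf[mask] = spec.bf_fiber_level
    pom_cols = np.full(w, float(spec.pom_base_level))
    inventory = []
    for patch in spec.patches:
        in_patch = (x_um >= patch.start_um) & (x_um < patch.end_um)
        pom_cols[in_patch] = patch.level
        area_px = int(n_px[in_patch].sum())
        inventory.append(
            {
                "area_px": area_px,
                "area_um2": area_px * upp**2,
                "level": patch.level,
                "n_columns": int(in_patch.sum()),
            }
        )
    pom = np.full((h, w), float(spec.pom_background_level))
    pom += (np.broadcast_to(pom_cols, (h, w)) - spec.pom_background_level) * mask

    truth = GroundTruth(
        mask=mask,
        mean_diameter_um=float(np.mean(n_px) * upp),
        min_diameter_um=float(np.min(n_px) * upp),
        mean_pom_intensity=float(pom[mask].mean()),
        patch_inventory=inventory,
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        bf = bf + rng.normal(0.0, spec.noise_sd, size=bf.shape)
        pom = pom + rng.normal(0.0, spec.noise_sd, size=pom.shape)
    bf8 = np.clip(np.round(bf), 0, 255).astype(np.uint8)
    pom8 = np.clip(np.round(pom), 0, 255).astype(np.uint8)

    pair = ImagePair(
        fiber_id=fiber_id,
        frame_index=frame_index,
        brightfield=bf8,
        pom=pom8,
        calibration=calibration,
    )
    return pair, truth


@dataclass
class Cohort:
    """A synthetic calibration cohort with known generating model."""

    summaries: list[FiberSummary]
    true_strengths: np.ndarray  # MPa, noiseless part not included; these are measured
    specs: list[FiberSpec]
    ni: np.ndarray
    diameters: np.ndarray


def generate_cohort(
    n_fibers: int,
    strength_model: tuple[float, float, float] = (20.0, 3.0, 26.0),
    diameter_range: tuple[float, float] = (3.1, 5.0),
    ni_range: tuple[float, float] = (10.0, 50.0),
    seed: int = 0,
    diameter_slope: float = 0.0,
    setup: str = "setup1",
) -> Cohort:
    """Sample a cohort with strength linear in normalized intensity (NI).

    strength_i = intercept + slope * NI_i + diameter_slope * d_i + N(0, sd).
    NI and diameter are sampled independently and uniformly over their
    ranges.  Defaults emulate the thin-fiber study population: diameters in
    the 3.1-5.0 um band where diameter alone is a poor strength predictor,
    NI spanning 10-50 intensity-units/um, and noise sized so the population
    |r| between NI and strength is about 0.8.  Each fiber also gets a
    renderable :class:`FiberSpec` whose constant POM level reproduces its NI
    exactly (mean intensity = NI x diameter, which must stay within 8 bits).
    """
    if n_fibers < 3:
        raise ValueError("a cohort needs at least 3 fibers")
    d_lo, d_hi = diameter_range
    ni_lo, ni_hi = ni_range
    if not (0 < d_lo < d_hi) or not (0 < ni_lo < ni_hi):
        raise ValueError("invalid diameter or NI range")
    intercept, slope, noise_sd = strength_model
    if noise_sd < 0:
        raise ValueError("strength noise SD must be >= 0")

    rng = np.random.default_rng(seed)
    d = rng.uniform(d_lo, d_hi, n_fibers)
    ni = rng.uniform(ni_lo, ni_hi, n_fibers)
    strength = intercept + slope * ni + diameter_slope * d + rng.normal(0.0, noise_sd, n_fibers)

    summaries = []
    specs = []
    for i in range(n_fibers):
        mean_int = ni[i] * d[i]
        summaries.append(
            FiberSummary(
                fiber_id=f"sim{i:03d}",
                mean_diameter=float(d[i]),
                mean_intensity=float(mean_int),
                normalized_intensity=float(ni[i]),
                n_frames=1,
                measured_strength=float(strength[i]),
                setup=setup,
            )
        )
        specs.append(
            FiberSpec(
                width_profile=constant_width(float(d[i])),
                pom_base_level=int(round(min(mean_int, 255.0))),
                noise_sd=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return Cohort(
        summaries=summaries,
        true_strengths=strength,
        specs=specs,
        ni=ni,
        diameters=d,
    )
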