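"""Engineering stress-strain analysis of single-fiber tensile tests.

Force-displacement records are converted to engineering stress and strain
using the image-derived mean diameter for the cross-section: the fiber is
assumed circular with area A = pi d^2 / 4 (fibers with a longitudinal groove
have a smaller true area, so the reported stress is an underestimate), and
strain is grip displacement over the initial gauge length (10 mm by
default).  The ultimate strength is the stress at the last recorded point
before fracture, where fracture is detected as the force dropping below a
configurable fraction of its running maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GAUGE_LENGTH_MM = 10.0
DEFAULT_DROP_FRACTION = 0.5


@dataclass
class TensileRecord:
    """One fiber's force-displacement record."""

    fiber_id: str
    displacement: np.ndarray  # mm, non-decreasing
    force: np.ndarray  # N
    gauge_length: float = DEFAULT_GAUGE_LENGTH_MM  # mm

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape or self.displacement.size < 2:
            raise ValueError("displacement and force must be equal-length series (n >= 2)")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")
        if self.gauge_length <= 0:
            raise ValueError("gauge_length must be positive")


@dataclass
class StressStrainCurve:
    """Engineering stress-strain curve truncated at fracture."""

    fiber_id: str
    strain: np.ndarray  # dimensionless
    stress: np.ndarray  # MPa
    ultimate_strength: float  # MPa
    strain_at_break: float
    diameter_used: float  # um
    fracture_detected: bool = True
    drop_fraction: float = field(default=DEFAULT_DROP_FRACTION, repr=False)


def cross_section_area_m2(diameter_um: float) -> float:
    """Circular cross-section area in m^2 from a diameter in um."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d_m = diameter_um * 1e-6
    return math.pi * d_m**2 / 4.0


def engineering_stress_strain(
    record: TensileRecord,
    mean_diameter: float,
    drop_fraction: float = DEFAULT_DROP_FRACTION,
) -> StressStrainCurve:
    """Engineering stress-strain curve and ultimate strength for one fiber.

    stress_i = F_i / (pi d^2 / 4) in MPa, strain_i = displacement_i / gauge.
    Fracture is the first sample whose force falls below ``drop_fraction`` of
    the running maximum of the preceding samples; the ultimate strength is
    the stress immediately before that sample and the curve is truncated
    there.  If no such drop occurs the final sample is used with a warning.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in (0, 1)")
    if np.all(record.force == 0):
        raise ValueError("all-zero force record")

    area = cross_section_area_m2(mean_diameter)
    stress = record.force / area / 1e6  # Pa -> MPa
    strain = record.displacement / record.gauge_length

    running_max = np.maximum.accumulate(record.force)
    drops = np.nonzero(record.force[1:] < drop_fraction * running_max[:-1])[0]
    if drops.size:
        break_idx = int(drops[0])  # last sample before the detected drop
        detected = True
    else:
        break_idx = len(stress) - 1
        detected = False
        logger.warning(
            "fiber %s: no fracture drop detected; using the final sample",
            record.fiber_id,
        )

    return StressStrainCurve(
        fiber_id=record.fiber_id,
        strain=strain[: break_idx + 1],
        stress=stress[: break_idx + 1],
        ultimate_strength=float(stress[break_idx]),
        strain_at_break=float(strain[break_idx]),
        diameter_used=float(mean_diameter),
        fracture_detected=detected,
        drop_fraction=drop_fraction,
    )


def read_tensile_csv(
    path: str | Path,
    fiber_id: str | None = None,
    gauge_length: float = DEFAULT_GAUGE_LENGTH_MM,
    force_unit: str = "N",
) -> list[TensileRecord]:
    """Read force-displacement records from CSV.

    Expected columns: ``displacement_mm`` and ``force_N`` (or ``force_mN``
    with ``force_unit='mN'``); an optional ``fiber_id`` column gives long
    format with several fibers per file.
    """
    df = pd.read_csv(path)
    force_col = f"force_{force_unit}"
    for col in ("displacement_mm", force_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    scale = 1e-3 if force_unit == "mN" else 1.0

    if "fiber_id" in df.columns:
        groups = [(str(k), g) for k, g in df.groupby("fiber_id", sort=True)]
    else:
        groups = [(fiber_id or Path(path).stem, df)]
    return [
        TensileRecord(
            fiber_id=fid,
            displacement=g["displacement_mm"].to_numpy(),
            force=g[force_col].to_numpy() * scale,
            gauge_length=gauge_length,
        )
        for fid, g in groups
    ]
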