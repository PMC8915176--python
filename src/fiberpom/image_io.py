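"""Reading and validating micrograph pairs, pixel calibration, and result tables.

A measurement consists of co-registered brightfield/POM (polarized optical
microscopy) frame pairs of a single fiber: the fiber is dark on a bright
background in brightfield and bright on a dark background between crossed
polarizers.  Typically ~6 sequential frame pairs cover one fiber, each frame
spanning roughly 1400 um of fiber length.  The camera pixel size is never
encoded in the image files, so a :class:`PixelCalibration` must always be
supplied by the user.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default filename convention: ``<fiber>_f<frame>_<bf|pom>.<tif|tiff|png>``
DEFAULT_PAIRING_PATTERN = (
    r"(?P<fiber>.+)_f(?P<frame>\d+)_(?P<modality>bf|pom)\.(tif|tiff|png)$"
)

# Rec. 601 luminance weights used for optional color -> grayscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PixelCalibration:
    """Physical scale of the image grid.

    Parameters
    ----------
    microns_per_pixel:
        Edge length of one pixel in micrometers; must be positive.
    bit_depth:
        Bit depth of the working intensity scale (8 for this pipeline).
    """

    microns_per_pixel: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )
        if self.bit_depth <= 0:
            raise ValueError(f"bit_depth must be positive, got {self.bit_depth}")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class ImagePair:
    """One brightfield/POM frame pair of a single field of view."""

    fiber_id: str
    frame_index: int
    brightfield: np.ndarray
    pom: np.ndarray
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.brightfield.shape != self.pom.shape:
            raise ValueError(
                "brightfield and pom must share one field of view: shapes "
                f"{self.brightfield.shape} vs {self.pom.shape}"
            )
        for name in ("brightfield", "pom"):
            arr = getattr(self, name)
            if arr.ndim != 2:
                raise ValueError(f"{name} must be a 2-D grayscale grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape


@dataclass
class FiberSeries:
    """Ordered frame pairs covering consecutive sections of one fiber."""

    fiber_id: str
    pairs: list[ImagePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("a FiberSeries needs at least one ImagePair")
        calibs = {p.calibration for p in self.pairs}
        if len(calibs) > 1:
            raise ValueError("all pairs in a series must share one calibration")
        indices = [p.frame_index for p in self.pairs]
        if len(set(indices)) != len(indices):
            raise ValueError(f"duplicate frame_index in series {self.fiber_id!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def _load_grayscale(path: Path, allow_color: bool) -> np.ndarray:
    """Read one image and return an 8-bit single-channel grid."""
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not allow_color:
            raise ValueError(
                f"{path}: multi-channel image; pass allow_color=True for "
                "Rec.601 luminance conversion"
            )
        arr = arr[..., :3].astype(float) @ _LUMA_WEIGHTS
        arr = np.floor(arr + 0.5)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        # 65535 / 257 = 255 exactly, so full-range 16-bit maps onto full-range
        # 8-bit and the fixed 8-bit thresholds stay meaningful.
        warnings.warn(
            f"{path}: 16-bit input rescaled to 8-bit (divide by 257, round half up)",
            stacklevel=3,
        )
        return np.floor(arr / 257.0 + 0.5).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(f"{path}: unsupported bit depth / intensity range")
        return np.floor(arr + 0.5).astype(np.uint8)
    raise ValueError(f"{path}: unsupported bit depth (dtype {arr.dtype})")


def load_image_pair(
    brightfield_path: str | Path,
    pom_path: str | Path,
    calibration: PixelCalibration,
    *,
    fiber_id: str = "",
    frame_index: int = 0,
    allow_color: bool = False,
) -> ImagePair:
    """Load one brightfield/POM pair and validate it as a single field of view.

    Both files must decode to grayscale grids of equal shape.  16-bit inputs
    are linearly rescaled to 8-bit (divide by 257, round half up) with a
    warning; color inputs are rejected unless ``allow_color`` requests the
    Rec. 601 luminance conversion.
    """
    bf = _load_grayscale(Path(brightfield_path), allow_color)
    pom = _load_grayscale(Path(pom_path), allow_color)
    if bf.shape != pom.shape:
        raise ValueError(
            f"shape mismatch between brightfield {bf.shape} and POM {pom.shape}"
        )
    return ImagePair(
        fiber_id=fiber_id or Path(brightfield_path).stem,
        frame_index=frame_index,
        brightfield=bf,
        pom=pom,
        calibration=calibration,
    )


def scan_pairs(
    directory: str | Path,
    pairing_pattern: str = DEFAULT_PAIRING_PATTERN,
) -> dict[str, list[tuple[int, Path, Path]]]:
    """Match paired filenames without decoding any image.

    Returns ``{fiber_id: [(frame_index, bf_path, pom_path), ...]}`` with
    frames sorted by index.  The pattern must expose named groups ``fiber``,
    ``frame`` and ``modality`` (``bf`` or ``pom``).  Every brightfield frame
    must have exactly one POM counterpart; orphans and duplicates are hard
    errors.  The result is deterministic and independent of directory
    listing order.
    """
    directory = Path(directory)
    rx = re.compile(pairing_pattern)
    found: dict[tuple[str, int, str], Path] = {}
    for path in sorted(directory.iterdir()):
        m = rx.match(path.name)
        if m is None:
            continue
        key = (m.group("fiber"), int(m.group("frame")), m.group("modality"))
        if key in found:
            raise ValueError(f"duplicate frame: {path.name} collides with {found[key].name}")
        found[key] = path

    frames = sorted({(f, i) for f, i, _ in found})
    orphans = [
        f"{fiber} frame {idx} missing {mod}"
        for fiber, idx in frames
        for mod in ("bf", "pom")
        if (fiber, idx, mod) not in found
    ]
    if orphans:
        raise ValueError("unpaired frames: " + "; ".join(orphans))
    if not frames:
        logger.warning("no image pairs found in %s", directory)

    grouped: dict[str, list[tuple[int, Path, Path]]] = {}
    for fiber, idx in frames:
        grouped.setdefault(fiber, []).append(
            (idx, found[(fiber, idx, "bf")], found[(fiber, idx, "pom")])
        )
    return dict(sorted(grouped.items()))


def discover_series(
    directory: str | Path,
    calibration: PixelCalibration,
    pairing_pattern: str = DEFAULT_PAIRING_PATTERN,
    *,
    allow_color: bool = False,
) -> list[FiberSeries]:
    """Scan a directory and assemble loaded fiber series from paired filenames.

    See :func:`scan_pairs` for the pairing contract.
    """
    grouped = scan_pairs(directory, pairing_pattern)
    return [
        FiberSeries(
            fiber_id=fid,
            pairs=[
                load_image_pair(
                    bf, pom, calibration, fiber_id=fid, frame_index=idx, allow_color=allow_color
                )
                for idx, bf, pom in frames
            ],
        )
        for fid, frames in grouped.items()
    ]


def write_results_table(
    records: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Iterable[str] | None = None,
) -> None:
    """Write per-frame or per-fiber result rows as CSV with stable columns.

    An empty record list yields a header-only CSV when ``columns`` is given.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=list(columns) if columns else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)
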