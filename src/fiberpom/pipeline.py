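"""Run orchestration: analyze, simulate, calibrate, predict, tensile.

Thin plumbing over the library modules: frame pairs are discovered and
segmented, morphology and birefringence metrics are written per frame,
fiber-level summaries and a JSON run manifest (configuration hash,
thresholds, frame counts) accompany every run.  Per-fiber failures are
logged and skipped — a run returns exit status 2 when any fiber failed and
0 only when everything completed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .birefringence import analyze_bright_segments
from .calibration_prediction import (
    FiberSummary,
    StrengthModel,
    fit_strength_model,
    predict_strength,
    summarize_fiber,
)
from .image_io import (
    DEFAULT_PAIRING_PATTERN,
    FiberSeries,
    PixelCalibration,
    load_image_pair,
    scan_pairs,
    write_results_table,
)
from .mechanics import (
    DEFAULT_DROP_FRACTION,
    DEFAULT_GAUGE_LENGTH_MM,
    engineering_stress_strain,
    read_tensile_csv,
)
from .morphometry import diameter_profile, summarize_morphology
from .segmentation import (
    DEFAULT_BRIGHT_THRESHOLD,
    ThresholdSpec,
    segment_bright_areas,
    segment_fiber,
)
from .synthetic_fibergen import FiberSpec, generate_cohort, render_pair

logger = logging.getLogger(__name__)

FRAME_COLUMNS = [
    "fiber_id",
    "frame_index",
    "area_um2",
    "mean_diam_um",
    "sd_diam_um",
    "min_diam_um",
    "threshold_used",
    "n_axis_samples",
    "mean_int_full",
    "sd_int_full",
    "mean_int_bright",
    "n_segments",
    "seg_area_mean_um2",
    "seg_area_min_um2",
    "seg_area_max_um2",
    "bright_fraction",
    "bright_threshold",
]

SUMMARY_COLUMNS = [
    "fiber_id",
    "n_frames",
    "mean_diameter_um",
    "mean_intensity",
    "normalized_intensity",
    "setup",
]


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input_dir: str
    output_dir: str
    microns_per_pixel: float = 1.0
    bf_threshold: int | str = 148  # intensity level, or "auto" for Yen
    bright_threshold: int = DEFAULT_BRIGHT_THRESHOLD
    min_area_px: int = 50
    prune_px: int = 10
    pooling: str = "samples"  # or "frames"
    pairing_pattern: str = DEFAULT_PAIRING_PATTERN
    setup: str = "setup1"
    seed: int = 0

    def threshold_spec(self) -> ThresholdSpec:
        if self.bf_threshold == "auto":
            return ThresholdSpec(mode="auto_yen")
        return ThresholdSpec(mode="fixed", fixed_value=int(self.bf_threshold))

    def calibration(self) -> PixelCalibration:
        return PixelCalibration(microns_per_pixel=self.microns_per_pixel)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def analyze_series(series: FiberSeries, config: RunConfig) -> tuple[list[dict], FiberSummary]:
    """Analyze all frames of one fiber and pool them into a summary."""
    spec = config.threshold_spec()
    records: list[dict] = []
    frames = []
    for pair in series.pairs:
        fiber_mask = segment_fiber(
            pair.brightfield,
            spec,
            min_area_px=config.min_area_px,
            source_frame=(pair.fiber_id, pair.frame_index),
        )
        profile = diameter_profile(fiber_mask, pair.calibration, prune_px=config.prune_px)
        morph = summarize_morphology(profile, fiber_mask, pair.calibration)
        bright = segment_bright_areas(pair.pom, fiber_mask, config.bright_threshold)
        _, biref = analyze_bright_segments(bright, pair.pom, pair.calibration)
        frames.append((morph, biref))
        records.append(
            {
                "fiber_id": pair.fiber_id,
                "frame_index": pair.frame_index,
                "area_um2": morph.fiber_area,
                "mean_diam_um": morph.mean_diameter,
                "sd_diam_um": morph.sd_diameter,
                "min_diam_um": morph.min_diameter,
                "threshold_used": morph.threshold_used,
                "n_axis_samples": morph.n_axis_samples,
                "mean_int_full": biref.mean_intensity_full,
                "sd_int_full": biref.sd_intensity_full,
                "mean_int_bright": biref.mean_intensity_bright,
                "n_segments": biref.n_segments,
                "seg_area_mean_um2": biref.mean_segment_area,
                "seg_area_min_um2": biref.min_segment_area,
                "seg_area_max_um2": biref.max_segment_area,
                "bright_fraction": biref.bright_fraction,
                "bright_threshold": config.bright_threshold,
            }
        )
    summary = summarize_fiber(
        series.fiber_id, frames, setup=config.setup, weighting=config.pooling
    )
    return records, summary


def run_analyze(config: RunConfig) -> int:
    """Analyze every discoverable fiber series under ``config.input_dir``.

    Writes ``frames.csv``, ``fibers.csv`` and ``manifest.json`` into
    ``config.output_dir``.  Returns 0 on full success, 2 when some fibers
    failed (logged and skipped), and raises on fatal configuration errors.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grouped = scan_pairs(config.input_dir, config.pairing_pattern)
    calibration = config.calibration()
    frame_rows: list[dict] = []
    summary_rows: list[dict] = []
    failures: dict[str, str] = {}
    frame_counts: dict[str, int] = {}
    for fiber_id, frames_on_disk in grouped.items():
        try:
            series = FiberSeries(
                fiber_id=fiber_id,
                pairs=[
                    load_image_pair(bf, pom, calibration, fiber_id=fiber_id, frame_index=idx)
                    for idx, bf, pom in frames_on_disk
                ],
            )
            records, summary = analyze_series(series, config)
        except Exception as exc:  # noqa: BLE001 - per-fiber isolation is the contract
            logger.error("fiber %s failed: %s", fiber_id, exc)
            failures[fiber_id] = str(exc)
            continue
        frame_rows.extend(records)
        frame_counts[series.fiber_id] = len(records)
        summary_rows.append(
            {
                "fiber_id": summary.fiber_id,
                "n_frames": summary.n_frames,
                "mean_diameter_um": summary.mean_diameter,
                "mean_intensity": summary.mean_intensity,
                "normalized_intensity": summary.normalized_intensity,
                "setup": summary.setup,
            }
        )

    write_results_table(frame_rows, out / "frames.csv", columns=FRAME_COLUMNS)
    write_results_table(summary_rows, out / "fibers.csv", columns=SUMMARY_COLUMNS)
    manifest = {
        "fiberpom_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "n_fibers_analyzed": len(summary_rows),
        "frames_per_fiber": frame_counts,
        "failed_fibers": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return 2 if failures else 0


def save_model(model: StrengthModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(model), indent=2, sort_keys=True))


def load_model(path: str | Path) -> StrengthModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no model file at {path}")
    return StrengthModel(**json.loads(path.read_text()))


def summaries_from_csv(path: str | Path, strengths_csv: str | Path | None = None) -> list[FiberSummary]:
    """Load fiber summaries (and optionally merge measured strengths) from CSV."""
    df = pd.read_csv(path)
    if strengths_csv is not None:
        strengths = pd.read_csv(strengths_csv)
        if "measured_strength_MPa" not in strengths.columns:
            raise ValueError(f"{strengths_csv}: missing column 'measured_strength_MPa'")
        df = df.merge(strengths[["fiber_id", "measured_strength_MPa"]], on="fiber_id", how="left")
    out = []
    for row in df.itertuples(index=False):
        strength = getattr(row, "measured_strength_MPa", None)
        if strength is not None and pd.isna(strength):
            strength = None
        setup = getattr(row, "setup", None)
        out.append(
            FiberSummary(
                fiber_id=str(row.fiber_id),
                mean_diameter=float(row.mean_diameter_um),
                mean_intensity=float(row.mean_intensity),
                normalized_intensity=float(row.mean_intensity) / float(row.mean_diameter_um),
                n_frames=int(getattr(row, "n_frames", 1)),
                measured_strength=None if strength is None else float(strength),
                setup=None if setup is None or pd.isna(setup) else str(setup),
            )
        )
    return out


def run_calibrate(
    summary_csv: str | Path,
    strengths_csv: str | Path,
    model_out: str | Path,
    allow_quadratic_check: bool = True,
) -> StrengthModel:
    summaries = summaries_from_csv(summary_csv, strengths_csv)
    model = fit_strength_model(summaries, allow_quadratic_check=allow_quadratic_check)
    save_model(model, model_out)
    return model


def run_predict(
    model_path: str | Path,
    summary_csv: str | Path,
    report_out: str | Path,
    strengths_csv: str | Path | None = None,
    allow_cross_setup: bool = False,
):
    model = load_model(model_path)
    summaries = summaries_from_csv(summary_csv, strengths_csv)
    report = predict_strength(model, summaries, allow_cross_setup=allow_cross_setup)
    write_results_table(
        report.rows,
        report_out,
        columns=[
            "fiber_id",
            "predicted_strength_MPa",
            "measured_strength_MPa",
            "percent_difference",
        ],
    )
    return report


def run_tensile(
    tensile_csv: str | Path,
    diameters: dict[str, float] | float,
    out_csv: str | Path,
    gauge_length: float = DEFAULT_GAUGE_LENGTH_MM,
    force_unit: str = "N",
    drop_fraction: float = DEFAULT_DROP_FRACTION,
) -> pd.DataFrame:
    """Turn tensile records into per-fiber ultimate strengths.

    ``diameters`` maps fiber_id to mean diameter in um (or one value for all).
    """
    records = read_tensile_csv(tensile_csv, gauge_length=gauge_length, force_unit=force_unit)
    rows = []
    for rec in records:
        d = diameters if isinstance(diameters, (int, float)) else diameters[rec.fiber_id]
        curve = engineering_stress_strain(rec, d, drop_fraction=drop_fraction)
        rows.append(
            {
                "fiber_id": rec.fiber_id,
                "ultimate_strength_MPa": curve.ultimate_strength,
                "strain_at_break": curve.strain_at_break,
                "diameter_used_um": curve.diameter_used,
                "fracture_detected": curve.fracture_detected,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df


def run_simulate(
    out_dir: str | Path,
    n_fibers: int = 3,
    frames_per_fiber: int = 6,
    shape: tuple[int, int] = (128, 1400),
    microns_per_pixel: float = 1.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    strength_model: tuple[float, float, float] = (20.0, 3.0, 26.0),
) -> Path:
    """Write a synthetic dataset laid out exactly as ``run_analyze`` expects.

    TIFF pairs named ``fiber###_f#_{bf,pom}.tif``, a ground-truth JSON, and a
    ``strengths.csv`` with the cohort's measured strengths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calib = PixelCalibration(microns_per_pixel=microns_per_pixel)
    cohort = generate_cohort(n_fibers, strength_model=strength_model, seed=seed)
    truth: dict[str, dict] = {}
    for i, base_spec in enumerate(cohort.specs):
        fid = f"fiber{i:03d}"
        frame_truth = []
        for j in range(frames_per_fiber):
            spec = FiberSpec(
                width_profile=base_spec.width_profile,
                pom_base_level=base_spec.pom_base_level,
                noise_sd=noise_sd,
                seed=base_spec.seed + j,
            )
            pair, gt = render_pair(spec, shape, calib, fiber_id=fid, frame_index=j)
            tifffile.imwrite(out / f"{fid}_f{j}_bf.tif", pair.brightfield)
            tifffile.imwrite(out / f"{fid}_f{j}_pom.tif", pair.pom)
            frame_truth.append(
                {
                    "frame_index": j,
                    "mean_diameter_um": gt.mean_diameter_um,
                    "min_diameter_um": gt.min_diameter_um,
                    "mean_pom_intensity": gt.mean_pom_intensity,
                }
            )
        truth[fid] = {
            "true_diameter_um": float(cohort.diameters[i]),
            "true_normalized_intensity": float(cohort.ni[i]),
            "measured_strength_MPa": float(cohort.true_strengths[i]),
            "frames": frame_truth,
        }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    pd.DataFrame(
        {
            "fiber_id": list(truth),
            "measured_strength_MPa": [truth[f]["measured_strength_MPa"] for f in truth],
        }
    ).to_csv(out / "strengths.csv", index=False)
    return out
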