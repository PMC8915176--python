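"""Fiber-level aggregation, strength calibration and blind prediction.

The strength predictor is the normalized intensity NI: the fiber's pooled
mean POM intensity divided by its pooled mean diameter (intensity units per
um).  Pooling across a fiber's frames is weighted — diameters by the number
of medial-axis samples per frame, intensities by the fiber pixel count per
frame — so every measured pixel counts once regardless of how the fiber was
split into frames (unweighted frame means are available as an option).

Calibration fits ordinary least squares of measured strength on NI; a nested
quadratic model is compared by a likelihood-ratio test (statistic
n ln(RSS_lin / RSS_quad), chi-square with 1 df) and the linear form is
retained unless the test rejects at the 5% level.  Pearson correlations are
reported as absolute values: the magnitude, regardless of sign, is what
measures the degree of association.  Because POM intensity depends on the
exposure settings of one acquisition configuration, a fitted model carries a
setup tag and refuses to predict for summaries from another setup unless
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .birefringence import BirefringenceResult
from .morphometry import MorphometryResult


@dataclass
class FiberSummary:
    """Fiber-level pooled metrics and, for calibration fibers, the measured strength."""

    fiber_id: str
    mean_diameter: float  # um
    mean_intensity: float  # 8-bit intensity units
    normalized_intensity: float  # intensity units per um
    n_frames: int
    measured_strength: float | None = None  # MPa
    setup: str | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        expected = self.mean_intensity / self.mean_diameter
        if not np.isclose(self.normalized_intensity, expected, rtol=1e-9):
            raise ValueError("normalized_intensity must equal mean_intensity / mean_diameter")


@dataclass
class StrengthModel:
    """Fitted calibration mapping a predictor to engineering strength (MPa)."""

    intercept: float
    slope: float
    n_fit: int
    pearson_r_abs: float
    residual_sd: float
    model_form: Literal["linear", "quadratic"]
    lr_test_p: float | None
    predictor: str = "normalized_intensity"
    setup: str | None = None
    quad_coef: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pearson_r_abs <= 1.0 + 1e-12:
            raise ValueError("pearson_r_abs must lie in [0, 1]")
        if self.n_fit < 3:
            raise ValueError("a fit needs at least 3 fibers")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slope * x
        if self.model_form == "quadratic" and self.quad_coef is not None:
            y = y + self.quad_coef * x**2
        return y


@dataclass
class PredictionReport:
    """Per-fiber predictions and, when measurements exist, the agreement summary."""

    fiber_ids: list[str]
    predicted_strength: np.ndarray  # MPa
    measured_strength: np.ndarray | None = None
    percent_difference: np.ndarray | None = None  # |pred - meas| / meas * 100
    mean_percent_difference: float | None = None
    pearson_r_abs_pred_vs_meas: float | None = None
    rows: list[dict] = field(default_factory=list)


def summarize_fiber(
    fiber_id: str,
    frames: Sequence[tuple[MorphometryResult, BirefringenceResult]],
    measured_strength: float | None = None,
    setup: str | None = None,
    weighting: Literal["samples", "frames"] = "samples",
) -> FiberSummary:
    """Pool per-frame metrics to one fiber summary.

    With ``weighting='samples'`` (default) the mean diameter is weighted by
    each frame's number of axis samples and the mean intensity by each
    frame's fiber area; ``'frames'`` averages the frame means unweighted.
    """
    if not frames:
        raise ValueError("empty frame list")
    morphs = [m for m, _ in frames]
    biref = [b for _, b in frames]
    diam = np.array([m.mean_diameter for m in morphs])
    inten = np.array([b.mean_intensity_full for b in biref])
    if weighting == "samples":
        w_d = np.array([m.n_axis_samples for m in morphs], dtype=float)
        w_i = np.array([m.fiber_area for m in morphs], dtype=float)
    elif weighting == "frames":
        w_d = w_i = np.ones(len(frames))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    mean_d = float(np.average(diam, weights=w_d))
    mean_i = float(np.average(inten, weights=w_i))
    return FiberSummary(
        fiber_id=fiber_id,
        mean_diameter=mean_d,
        mean_intensity=mean_i,
        normalized_intensity=mean_i / mean_d,
        n_frames=len(frames),
        measured_strength=measured_strength,
        setup=setup,
    )


def _predictor_values(summaries: Sequence[FiberSummary], predictor: str) -> np.ndarray:
    return np.array([getattr(s, predictor) for s in summaries], dtype=float)


def fit_strength_model(
    summaries: Sequence[FiberSummary],
    allow_quadratic_check: bool = True,
    predictor: str = "normalized_intensity",
) -> StrengthModel:
    """OLS calibration of strength on a predictor with a quadratic LR check.

    All fibers must carry a measured strength.  The quadratic alternative is
    rejected unless the likelihood-ratio test statistic n ln(RSS_lin /
    RSS_quad), referred to chi-square(1), gives p < 0.05 — with no
    significant benefit the simpler model is kept.
    """
    with_strength = [s for s in summaries if s.measured_strength is not None]
    if len(with_strength) < 3:
        raise ValueError("need at least 3 fibers with measured strength")
    x = _predictor_values(with_strength, predictor)
    y = np.array([s.measured_strength for s in with_strength], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate predictor: {predictor} has zero variance")

    setups = {s.setup for s in with_strength}
    if len(setups) > 1:
        raise ValueError(f"calibration fibers span multiple setups: {sorted(map(str, setups))}")

    n = len(x)
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    lr_p = None
    form: Literal["linear", "quadratic"] = "linear"
    quad_coef = None
    if allow_quadratic_check and n > 3:
        quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
        rss_lin, rss_quad = float(lin.ssr), float(quad.ssr)
        if rss_quad > 0 and rss_lin > 0:
            lr_stat = n * np.log(rss_lin / rss_quad)
            lr_p = float(stats.chi2.sf(lr_stat, df=1))
            if lr_p < 0.05:
                form = "quadratic"
                quad_coef = float(quad.params[2])
                lin = quad  # coefficients below come from the retained model

    r = stats.pearsonr(x, y).statistic if np.ptp(y) > 0 else 0.0
    dof = n - (3 if form == "quadratic" else 2)
    return StrengthModel(
        intercept=float(lin.params[0]),
        slope=float(lin.params[1]),
        n_fit=n,
        pearson_r_abs=abs(float(r)),
        residual_sd=float(np.sqrt(lin.ssr / dof)) if dof > 0 else 0.0,
        model_form=form,
        lr_test_p=lr_p,
        predictor=predictor,
        setup=with_strength[0].setup,
        quad_coef=quad_coef,
    )


def predict_strength(
    model: StrengthModel,
    summaries: Sequence[FiberSummary],
    allow_cross_setup: bool = False,
) -> PredictionReport:
    """Predict strength for new fibers; compare with measurements when present.

    The percent difference is |predicted - measured| / measured x 100 and the
    reported summary is its mean over fibers (a mean absolute percentage
    error), alongside the absolute Pearson correlation between predicted and
    measured strength.
    """
    if not summaries:
        raise ValueError("no fibers to predict")
    foreign = {s.setup for s in summaries} - {model.setup}
    if foreign and not allow_cross_setup:
        raise ValueError(
            f"summaries from setup(s) {sorted(map(str, foreign))} cannot be predicted "
            f"with a model calibrated on setup {model.setup!r}; POM intensity scales "
            "are exposure-specific (pass allow_cross_setup=True to override)"
        )

    x = _predictor_values(summaries, model.predictor)
    pred = model.predict(x)
    ids = [s.fiber_id for s in summaries]

    measured = np.array(
        [np.nan if s.measured_strength is None else s.measured_strength for s in summaries]
    )
    have_meas = ~np.isnan(measured)
    pct = mean_pct = r_abs = None
    meas_out = None
    if have_meas.all():
        meas_out = measured
        pct = np.abs(pred - measured) / measured * 100.0
        mean_pct = float(pct.mean())
        if len(pred) > 2 and np.ptp(pred) > 0 and np.ptp(measured) > 0:
            r_abs = abs(float(stats.pearsonr(pred, measured).statistic))

    rows = [
        {
            "fiber_id": ids[i],
            "predicted_strength_MPa": float(pred[i]),
            "measured_strength_MPa": float(measured[i]) if have_meas[i] else None,
            "percent_difference": float(pct[i]) if pct is not None else None,
        }
        for i in range(len(ids))
    ]
    return PredictionReport(
        fiber_ids=ids,
        predicted_strength=pred,
        measured_strength=meas_out,
        percent_difference=pct,
        mean_percent_difference=mean_pct,
        pearson_r_abs_pred_vs_meas=r_abs,
        rows=rows,
    )


def diameter_only_baseline(
    summaries: Sequence[FiberSummary],
    allow_quadratic_check: bool = False,
) -> tuple[StrengthModel, PredictionReport]:
    """Reference model using the mean diameter as the sole predictor.

    Fitted and self-evaluated on the same fibers, for comparison against the
    normalized-intensity model.
    """
    model = fit_strength_model(
        summaries, allow_quadratic_check=allow_quadratic_check, predictor="mean_diameter"
    )
    report = predict_strength(model, summaries)
    return model, report
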