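# Methods

`fiberpom` implements a semi-automated image-analysis procedure for
predicting the tensile strength of wet-spun recombinant protein (spider-silk
type) fibers from light micrographs, without destroying the fiber. This
note documents the model, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Measurement model

A fiber is imaged as ~6 sequential fields of view, each covering roughly
1400 µm of fiber length. Each field yields a co-registered pair:

* a **brightfield** frame — the fiber appears dark on a bright background;
* a **POM** frame (crossed polarizers, fixed exposure) — structurally
  aligned, birefringent material appears bright on a dark background.

Because POM intensity at fixed exposure is a monotone proxy for local
structural alignment, and alignment correlates with strength, the fiber-level
predictor is the **normalized intensity**

    NI = (pooled mean POM intensity inside the fiber) / (pooled mean diameter)   [intensity units / µm]

and the calibrated strength model is simple linear regression

    strength [MPa] = β₀ + β₁ · NI + ε.

## Segmentation

The fiber region is found in the brightfield frame by thresholding:
foreground is strictly `intensity < T`. `T` is either a fixed user value
(default 148, the working value for the primary microscope configuration;
103 is the analogous value for the second configuration) or Yen's
entropic-correlation automatic threshold. Automatic thresholding is the
recommended way to find a working value on a new system; a fixed value is
then preferred for comparability and to avoid local shadows being picked up
as fiber. The Yen implementation scores every split level `T` (dark class
`{i < T}`, bright class `{i ≥ T}`) with integer cumulative statistics so the
criterion is exact and tie-breaks (toward the lower level) are well defined;
it is verified in the tests against an independent exhaustive search of all
255 splits. One practical property worth knowing: on strongly unbalanced
bimodal histograms Yen's criterion places the threshold near the lower tail
of the dominant mode, so the minority (fiber) class is recovered essentially
pure while a small percentage of background tail pixels fall below the
threshold; component selection removes these.

After thresholding, holes are filled, components smaller than `min_area_px`
(default 50) are dropped, and the component with the largest horizontal
extent wins (ties by area) — fibers traverse the frame horizontally, dust
and shadows do not.

Bright (birefringent) areas are the fiber pixels with POM intensity strictly
above a second cut-off. The cut-off is configuration-specific; the default
is 100 on the 8-bit scale, and the value used is always recorded in every
output row so analyses are self-describing. No morphological cleanup is
applied — single-pixel segments are legitimate.

## Diameter via the Euclidean distance transform

The local diameter is measured at every pixel along the fiber, not at a few
manual points: the Euclidean distance transform (EDT) assigns each fiber
pixel its distance to the nearest background pixel, the medial axis
(topological skeleton) is extracted, and the local diameter at each axis
pixel is `2 × EDT × µm/px`. Three guards:

* axis pixels within one local diameter of the left/right frame borders are
  excluded — there the EDT measures the frame cutting the fiber, not the
  fiber;
* skeleton spurs are pruned by iterative endpoint removal, default 10
  iterations (`prune_px`), because threshold noise at the boundary creates
  short branches whose EDT values are artifacts;
* the per-frame summary reports the mean, the sample (n−1) SD, the minimum,
  and the number of axis samples.

Quantization: on a discrete grid `2 × EDT` is exact for even pixel widths
and overestimates odd widths by exactly one pixel; all diameter outputs are
therefore accurate to ±1 px, which at typical calibrations (0.1–1 µm/px) is
well inside the variability of real fibers. Fiber area is the foreground
pixel count times (µm/px)².

## Pooling and calibration

Frame metrics are pooled per fiber with weights, so that every measured
pixel counts once however the fiber was divided into frames: diameters are
weighted by each frame's axis-sample count, intensities by each frame's
fiber area (unweighted frame means are available via `pooling="frames"`).

Calibration is ordinary least squares of measured strength on NI. A nested
quadratic alternative is compared by a likelihood-ratio test with statistic
`n·ln(RSS_linear/RSS_quadratic)` referred to χ²(1); the linear form is kept
unless p < 0.05. The χ² reference is asymptotic: its exact size (computable
through the F(1, n−3) equivalence) is 6.5% at n = 30 and 5.2% at n = 200,
which is why the simulation check of the test's calibration uses cohorts of
200 fibers. Pearson correlations are reported as absolute values — the
magnitude, regardless of sign, is what measures association strength.

A fitted model stores a setup tag. POM intensity scales are exposure- and
camera-specific, so predicting fibers imaged on a different setup is refused
unless explicitly overridden. Prediction reports per-fiber
`|predicted − measured| / measured × 100` and its mean (a MAPE with the
measured value as denominator), plus the absolute Pearson correlation
between predicted and measured strength. A diameter-only baseline model
(same machinery, `mean_diameter` as sole predictor) is provided for
reference; on data where strength tracks alignment rather than size it is
reliably inferior to the NI model.

## Tensile mechanics

Engineering stress is force over the circular cross-section `π d²/4`
computed from the image-derived mean diameter; these fibers have a
longitudinal groove, so the circular assumption overestimates the area and
the reported stress is a mild underestimate — deliberately uncorrected.
Engineering strain is grip displacement over the initial gauge length
(default 10 mm). The ultimate strength is the stress at the last point
before fracture; fracture is the first sample whose force falls below a
configurable fraction (default 0.5) of the running force maximum. If no
drop occurs the final sample is used and flagged. No toe-region correction
is applied (these curves show none).

## Synthetic data: what it emulates, what it does not

The generator renders hard-edged fiber bands column by column: a width
profile (constant, tapered, sinusoidal), an optional curved centerline, dark
fiber (level 60) on bright background (level 220) in brightfield, and a
bright fiber field (base level + rectangular bright patches standing in for
the patchy birefringence of real fibers) on a dark background (level 8) in
POM, with additive Gaussian noise clipped to [0, 255]. Ground truth —
mask, mean/min diameter, noiseless mean POM intensity, patch inventory — is
computed from the analytic specification, never from rendered pixels or the
pipeline's own segmentation, and is independent of the noise seed.

Cohorts sample diameter and NI independently and uniformly and set
`strength = 20 + 3·NI − weak·d + N(0, 26)` MPa by default. Defaults
emulate the thin-fiber study population: diameters 3.1–5.0 µm (the band in
which diameter alone is a poor predictor; the full observed 3.1–24 µm span
is exercised in the morphometry tests), NI 10–50 intensity-units/µm, and
noise sized so the population |r| between NI and strength is ≈ 0.8 — the
regime in which the method is useful in practice. Strength coefficients are
a realistic scale for this fiber class (tens to ~170 MPa), chosen once;
real calibrations are always data-driven, the package hard-codes no
coefficients.

Passing the synthetic suite demonstrates correctness of the machinery
(segmentation, EDT morphometry, bookkeeping, regression inference), not
performance on real micrographs: real fibers have soft edges, uneven
illumination, debris, curvature in depth, and non-Gaussian camera noise,
none of which the generator models (a soft-edge robustness mode exists, but
truth is then only approximate). Problem sizes in the default suite and in
`scripts/acceptance.py` (frames of 64×300–400 px, cohorts of 28–200 fibers,
200–1000 simulation replicates) were chosen to make the distributional
checks statistically meaningful at desk scale.

## Degenerate inputs and tie-breaks

* Single-valued images: no threshold exists → explicit error.
* No component surviving the area filter → "no fiber detected" error
  carrying the threshold used.
* Empty bright mask: bright-only statistics are emitted as nulls, never 0,
  so aggregation is not biased; `bright_fraction = 0`.
* Component-selection ties (equal horizontal extent) go to the larger area;
  Yen criterion ties go to the lower level; axis samples are ordered by
  (column, row) for deterministic output.
* 16-bit inputs are mapped to 8-bit by `round(x/257)` so fixed 8-bit
  thresholds keep their meaning; color inputs are rejected unless Rec. 601
  luminance conversion is requested.

## Known limitations

* The diameter is a projected width; no correction for non-circular
  cross-sections (grooves) or out-of-plane tilt.
* NI units are setup-specific; models do not transfer across microscopes or
  exposure settings (enforced via the setup tag).
* The LR model-comparison test is anti-conservative in small samples (see
  above); with n ≈ 30 calibration fibers its nominal 5% level is ~6.5%.
* Bright-segment statistics depend on the bright cut-off, for which no
  universal value exists; it must be chosen per setup and is recorded in all
  outputs.
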