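# Methods

## The measurement model

The tool estimates how much of the anterior tooth surface is covered by
dental biofilm, from a single natural-smile photograph. The measurement
chain is:

    image + tooth mask → HSB decomposition → saturation threshold
    → plaque fraction f = 100·PA/TA → linear calibration → index estimate

**Tooth region.** Tooth delineation is deliberately *not* automated: the
region arrives as a binary PNG mask (nonzero = tooth), mirroring the
manual "object selection" step of the clinical protocol the tool
reproduces. Automating gingival-margin detection is a different problem —
disclosing dye stains the gingiva too, which is exactly where automatic
segmentation fails — so the mask contract leaves boundary judgment to the
mask author. An all-zero mask is rejected; `TA` is the count of mask
pixels.

**Color space.** HSB (= HSV) with every channel byte-scaled to [0, 255];
hue is mapped from degrees by `deg·255/360` (the 8-bit convention of
classical image-analysis software, which the saturation thresholds below
are calibrated against, rather than the [0, 360) convention). Both
visible biofilm and fuchsin-disclosed biofilm differ from sound enamel
mainly in chroma, so hue and brightness are left unconstrained at
[0, 255] and only saturation is thresholded. The conversion itself is
standard (scikit-image) with rounding to bytes. Byte-quantizing hue
costs up to ~4 RGB levels on an exact round trip at full saturation;
this does not affect the pipeline, which never reconstructs RGB.

**Thresholding.** Two modes, recorded in every report for provenance:

* `fixed_band` — a closed saturation window `[low, high]` (both ends
  inclusive), reproducing an operator who widens the window until all
  plaque is selected.
* `auto_otsu` — Otsu's method on the 256-bin within-mask saturation
  histogram. The implementation maximizes the between-class variance
  `w0·w1·(μ0−μ1)²` of the split `{≤t} / {>t}` over all 256 levels;
  ties break to the smallest maximizing level, and a single-level
  histogram returns that level (the at-or-below class then holds every
  pixel, so the high class is empty — a plaque-free degenerate image
  yields fraction 0). The high-saturation class is treated as plaque by
  default for both visible and disclosed images; `plaque_class="low"` is
  available as an override.

Pixels outside the mask never enter any histogram; the crop step blanks
them to (0, 0, 0) purely for display, and the blanked sentinel cannot
bias a threshold because all statistics are mask-restricted.

## Calibration

The anterior fraction `f` (in **percent**) maps to a full-mouth index
estimate through a straight line. Shipped defaults:

| mode      | intercept | slope | output   |
|-----------|-----------|-------|----------|
| visible   | −7.50     | 1.14  | SVPI (%) |
| disclosed | 40.62     | 0.44  | SDPI (%) |

The percent reading of `f` is the only self-consistent one: with a unit
ratio in [0, 1] the visible-mode line could never leave negative index
values over its observed range. A `fraction_scale="unit"` option keeps
the alternative reading runnable. Calibration output is unclamped by
default (the visible intercept is negative, so zero plaque maps to
−7.5); a clamped-to-[0, 100] accessor exists for presentation only.

`fit_calibration` refits intercept and slope by closed-form
single-predictor OLS; it requires ≥ 3 pairs and a non-constant predictor.
The fit is described elsewhere as "multiple" regression, but only one
predictor is identifiable from the published equations, so one predictor
is what the refit implements.

## Clinical indices

VPI (no dye) and DPI (after disclosing) are both the percentage of
examined surfaces with a positive dichotomous plaque call. Conventions:

* FDI two-digit tooth codes, third molars excluded (28 scoreable teeth).
* Four surfaces per tooth (buccal, lingual, mesial, distal — the
  O'Leary convention), used uniformly for both indices so that they are
  comparable; the source protocol does not state its VPI surface count.
* Missing teeth contribute no records; the denominator is always the
  observed surface count. Duplicate (tooth, surface) observations within
  an arm are rejected.
* Anterior partial indices (VPIant/DPIant) restrict to the twelve
  incisors and canines (FDI 13–23, 33–43).

Integer arithmetic is used up to the final division, so index values are
exact rationals over the surface count.

## Rank correlation

Spearman's rho is the Pearson correlation of average ranks (mean rank
for ties). Two-sided significance comes from the t-approximation
`t = rho·√((n−2)/(1−rho²))` with n−2 degrees of freedom; for n ≤ 8 an
exact permutation p-value over all n! orderings is also reported (the
software used for the original analyses does not document its internals,
so both are exposed). Constant samples have undefined rho and are
rejected rather than returned as NaN. The default significance threshold
throughout is p ≤ 0.05.

## Synthetic data

`generate_smile` renders a row of per-tooth ellipses (canines slightly
shorter) on a dark oral background: enamel at (230, 225, 215)
(saturation ≈ 17/255), plaque at a fuchsin-like (200, 40, 120)
(saturation ≈ 204/255), additive per-channel Gaussian noise (default
sd 3, clipped to bytes) as the simplest model of smartphone JPEG capture.
The default canvas is 640×480 — the capture aspect of the emulated
protocol at desk-testing resolution. The requested plaque fraction is
converted to an exact pixel count and the plaque raster is grown from the
cervical (gingival) margin of each tooth with a jittered wavy depth
profile — the margin is where plaque accumulates clinically and where
detection is hardest; `plaque_placement="uniform"` scatters instead. The
returned `true_fraction_pct` is the realized pixel-count ratio, so
closed-loop tests compare against truth, not against the target. A
target unreachable at the given resolution (tiny tooth areas) is
rejected with the closest achievable value.

`generate_cohort` simulates a paired clinical/selfie cohort (default 47
subjects, the emulated study's size): visible-arm fractions drawn from a
configurable distribution (default uniform on [0, 60] %), disclosed-arm
fractions equal to the visible fraction plus a non-negative increment
(|N(20, 10)|) because disclosing dye reveals plaque that inspection
misses. Clinical indices are the generative calibration of the fraction
plus N(0, `index_noise_sd`) (default sd 2), clamped to [0, 100];
anterior partial indices add N(0, 5). Per-surface dichotomous records
are sampled with positive surfaces allocated within anterior/posterior
strata, so the computed full-mouth and anterior indices reproduce the
table columns to surface-count quantization (100/112 and 100/48
points); jointly infeasible full/anterior combinations are clipped with
a warning, not an error. All randomness flows from one seeded
`numpy` Generator per call: equal seeds give byte-identical output.

**What passing synthetic tests do and do not show.** The generator
produces clean bimodal saturation histograms; real photographs add
specular highlights, uneven illumination, JPEG chroma artifacts, lip and
gingiva pixels near the mask boundary, and camera-to-camera color
differences — none of which are modeled. Closed-loop recovery within
±1 percentage point therefore validates the *algorithmic* chain
(histogramming, Otsu, band semantics, area arithmetic), not field
accuracy on clinical images.

## Numerical choices and edge cases

* Otsu ties → smallest maximizing level; validated in tests against an
  exact-rational exhaustive search over all 256 splits.
* Threshold bands are closed at both ends; widening a band can only grow
  the selection (monotonicity is tested).
* `PA > TA` and `TA = 0` are hard errors, not clamps.
* Hue/saturation/brightness rounding is `rint` (half-to-even on exact
  halves, per numpy).
* Problem sizes in the shipped tests — 480×360 to 640×480 canvases,
  cohorts of 8–47, 50–100 simulation seeds — were chosen as the smallest
  sizes at which the tested properties are stable.

## Known limitations

* No automatic tooth segmentation; results are only as good as the mask.
* One global threshold per image: plaque with a complex margin or very
  high coverage reduces boundary accuracy.
* The shipped calibration coefficients come from a specific cohort,
  camera and operator; new settings should refit via `fit-calibration`.
* The clinical indices measure surface counts, not plaque amount, so
  even a perfect area measurement cannot correlate perfectly with them —
  the cohort simulator reproduces this decoupling qualitatively
  (rank correlation degrades as index noise grows), not quantitatively.
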