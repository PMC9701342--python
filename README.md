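# selfieplaque

Quantitative dental plaque scoring from smartphone smile photographs.

Clinical plaque indices — the Visible Plaque Index (VPI, Ainamo & Bay) and
the O'Leary disclosed index (DPI) — score each tooth surface as a
dichotomous plaque present/absent call and report the percentage of
positive surfaces. They are quick but subjective, and they measure spatial
*distribution* of plaque rather than its amount. `selfieplaque`
implements an image-based alternative for dentists, hygienists and
mHealth researchers: from a natural-smile photograph and a tooth-region
mask it measures the plaque-covered **area fraction** of the six anterior
teeth and maps it to a full-mouth index estimate.

## Method

1. **Tooth region.** The anterior teeth are delineated by a binary PNG
   mask (the stand-in for manual cutting in an image editor); the count
   of mask pixels is the total tooth area `TA`.
2. **Color decomposition.** The cropped image is converted to
   hue–saturation–brightness, each channel byte-scaled to [0, 255].
   Plaque — visible biofilm, or fuchsin-disclosed biofilm — is far more
   saturated than sound enamel, so hue and brightness are left
   unconstrained and only saturation is thresholded.
3. **Thresholding.** Either Otsu's automatic threshold on the within-mask
   saturation histogram (high-saturation class = plaque), or a manually
   chosen fixed saturation band. The plaque pixel count is `PA` and the
   core measurement is the fraction `f = 100 · PA / TA` (percent).
4. **Calibration.** Linear models map the anterior-teeth fraction to a
   full-mouth index estimate:

       SVPI = −7.50 + 1.14 · f        (selfie visible plaque index)
       SDPI = 40.62 + 0.44 · f        (selfie disclosed plaque index)

   These shipped coefficients are clinically fitted defaults;
   `fit_calibration` refits them by ordinary least squares from new
   paired (fraction, clinical index) observations.
5. **Validation.** Spearman rank correlation (average ranks for ties,
   two-sided t-approximation p-values, exact permutation p for n ≤ 8)
   between selfie scores, area fractions and clinical indices.

A synthetic-data module renders smile-like images with exactly known
plaque fractions and simulates paired clinical/selfie cohorts, so the
entire pipeline is testable without patient data.

## Worked example

Generate a synthetic smile with 30 % of the tooth area covered by plaque,
then measure it:

```bash
selfieplaque synth --kind smile --target-fraction 30 --seed 7 --out-dir fx
selfieplaque measure --image fx/smile.png --mask fx/smile_mask.png \
    --mode visible --out-dir out
```

The `synth` step prints the generator's ground truth:

```json
{"true_fraction_pct": 29.99973588294332, "ta": 75724}
```

and `measure` prints the report it also writes to `out/`:

```json
{
  "pa": 22717,
  "ta": 75724,
  "fraction_pct": 29.99973588294332,
  "selfie_index": 26.699698906555383,
  ...
}
```

Of the 75 724 tooth pixels, 22 717 were classified as plaque by the
automatic saturation threshold (the report echoes the effective band,
here [37, 255]) — a plaque fraction of 30.00 %, recovering the generated
truth exactly. The visible-mode calibration turns that fraction into a
full-mouth estimate SVPI = −7.5 + 1.14 · 30.0 ≈ 26.7 %. Other
subcommands: `cohort` (manifest of subjects + correlation tables),
`fit-calibration` (OLS refit from a pairs CSV), `indices` (VPI/DPI from a
per-surface records CSV), `synth --kind cohort`.

The same pipeline is available as a library:

```python
from selfieplaque import (SmileSpec, generate_smile, rgb_to_hsb,
                          detect_plaque, apply_calibration, VISIBLE_MODEL)

sample = generate_smile(SmileSpec(target_fraction_pct=30.0, seed=7))
plaque, meas = detect_plaque(rgb_to_hsb(sample.image), sample.mask)
svpi = apply_calibration(VISIBLE_MODEL, meas.fraction_pct)
```

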