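# ihcquant

Unbiased, quantitative immunohistochemistry for tissue-microarray cores.

Conventional scoring of immunohistochemical (IHC) staining is subjective:
an observer assigns an intensity grade, with large inter-observer variance.
`ihcquant` implements the alternative — a fully automated particle-analysis
protocol that turns each brightfield image of a DAB-stained tissue core into
numbers, plus the downstream statistics used to turn those numbers into
biomarker evidence:

* **Particle quantification** — RGB core image → 16-bit grayscale → dark-side
  threshold → connected components ("particles") with size/circularity
  filters.  Per core: particle count, total stained area *TA* (px), average
  size, area fraction *AF* = 100·*TA*/total px (%).  The amount of tissue is
  measured on the **inverted** grayscale image (tissue bright on dark) with
  the same particle chain, giving the standardized signal *TA*/tissue.
* **Cohort statistics** — Mann–Whitney U (exact enumeration or tie-corrected
  normal approximation), Kolmogorov–Smirnov normality check, fold change
  (mean ratio and mountain-plot AUC ratio on shared bins).
* **Diagnostics** — probit transform Φ⁻¹(AF/100), empirical ROC with
  sensitivity/1−specificity and likelihood ratios at every criterion
  (AUC via the Mann–Whitney identity *U*/(n₀n₁)), binormal ROC
  (a = (m₁−m₀)/s₁, b = s₀/s₁, AUC = Φ(a/√(1+b²))), and two-marker logistic
  regression with in-sample percent correctly identified.
* **Colocalization** — maximum Z-projection, signal masking, pixel-wise
  Pearson coefficient per channel pair, and a paired t-test comparing matched
  relapse vs non-relapse cores.
* **Synthetic data** — generators for DAB cores (known tissue and stain
  masks), fluorescence stacks with prescribed pairwise Pearson correlations,
  and two-group cohorts with prescribed means/SEs — so the whole pipeline is
  testable against exact ground truth without patient data.

## Worked example

```python
from ihcquant import CoreImage, CoreSpec, QuantConfig, generate_core_image, quantify_core

spec = CoreSpec(image_width_px=512, image_height_px=512, tissue_fraction=0.5,
                stained_fraction=0.04, noise_sd=4.0, seed=42)
core = generate_core_image(spec, core_id="demo")
result = quantify_core(CoreImage(core.pixels, bit_depth=8, core_id="demo"), QuantConfig())
```

prints (see `examples/01_quantify_dab_core.py`):

```
particles:          27
total area (px):    10530
area fraction (%):  4.02   (truth 4.02)
tissue area (px):   131072   (truth 131072)
signal / tissue:    0.0803
```

The core was generated with a true stained fraction of 4% of the image on 50%
tissue; the pipeline recovers AF = 4.02% and a tissue-standardized signal of
0.0803 ≈ 0.04/0.5.  The other scripts in `examples/` walk through cohort
statistics (fold ≈ 2.5, Mann–Whitney p ≪ 10⁻⁴ at ~230 cores/group), ROC and
logistic combination, colocalization-based relapse stratification
(r = 0.72 vs 0.60, paired p < 0.05), and the end-to-end pipeline.

A thin CLI wraps the pipelines:

```bash
ihcquant simulate cores -o data --n-benign 10 --n-malignant 10
ihcquant run-all --manifest data/manifest.csv --output results
ihcquant simulate stacks -o fluor && ihcquant coloc --manifest fluor/manifest.csv --output results
```

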