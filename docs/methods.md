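# Methods

## The quantification model

A DAB-stained tissue core photographed in brightfield has three intensity
populations: near-white background (no tissue), mid-gray/pink unstained
tissue (hematoxylin counterstain), and dark-brown DAB deposit marking
antibody binding.  `quantify_core` measures the stain as the total area of
dark "particles" and standardizes it by the amount of tissue:

1. RGB → grayscale.  Default is the unweighted channel mean
   round((R+G+B)/3), the plain RGB→gray conversion of common image-analysis
   tools; a luma mode (0.299R+0.587G+0.114B) is available for sensitivity
   analysis.  The 8-bit result is carried at 16 bits (×257).
2. DAB threshold.  Default `multiotsu_dark`: a three-class multi-Otsu cut,
   keeping the darkest class.  A single Otsu cut is offered (`otsu_dark`)
   but on a three-population image it falls between the two *largest*
   classes — usually tissue vs background — and merges stain with tissue;
   the three-class cut places the first threshold at the stain/tissue
   boundary.  `fixed(lo, hi)` reproduces any manually chosen cut, which is
   how the original protocol was actually run (its thresholds were chosen by
   eye per antibody and never published).
3. Particles.  Connected components of the mask, 8-connectivity by default
   (the convention of the particle-analysis tool this emulates), filtered by
   area ∈ [0.5, ∞) px and circularity ∈ [0, 1] — deliberately pass-all
   defaults, retained for configurability.
4. Tissue standardization.  The grayscale image is inverted (involution
   v → max−v), making tissue bright on dark background; the bright side of
   the lowest three-class cut, plus a 10-gray-level margin against vignette,
   is the tissue mask, run through the same particle chain.  The reported
   `normalized_signal` is stained area / tissue area.

Per-core outputs mirror a particle-analysis spreadsheet row: count, total
area TA (px), average size, area fraction AF = 100·TA/total px, tissue area,
normalized signal.

**Perimeter and circularity.**  Perimeter is the crack length: the count of
exposed pixel edges between particle and complement (single pixel → 4,
3×3 square → 12).  Circularity is min(1, 4π·area/perimeter²).  Crack length
was chosen because it is exactly testable; note that it systematically
overestimates smooth boundaries — a digitized disc has crack perimeter 8r,
so its circularity converges to π²/16 ≈ 0.617, not 1.  Circularity is a
configuration knob here, not a reported quantity, and the default filter
keeps everything.

**Known limitations.**  Automatic thresholds (Otsu and multi-Otsu) assume
the stain class is present: on a core with *no* stain they will latch onto
the tissue/background structure and report spurious signal.  For
possibly-unstained material use a `fixed` threshold, as the original manual
protocol effectively did.  Epithelium-restricted analysis is approximated by
the tissue mask; no epithelial segmentation is attempted.  No stain
unmixing (color deconvolution) is performed — the method quantifies a single
grayscale threshold by design.

## Cohort statistics

Area fractions are right-skewed, so the group comparison is the two-sided
Mann–Whitney U test.  `method="exact"` enumerates all C(n₁+n₂, n₁) labelings
of the pooled midranks (valid under ties; used up to n₁+n₂ = 16);
`method="normal_approx"` uses the tie-corrected normal approximation with
continuity correction.  `ks_normality` tests against a normal with the
sample's own mean/SD (asymptotic p), documenting why ranks are used.

Fold change is reported two ways: the ratio of group means, and the ratio of
"mountain plot" AUCs — each group's values histogrammed on a shared grid
(Freedman–Diaconis width on the pooled sample), bin heights equal to the
total value mass per bin, integrated by the trapezoid rule with zero-padding
bins.  Under shared bins the AUC is linear in the data, so for equal group
sizes the two folds agree; both are emitted side by side.

The cohort is analyzed at the core level, not the patient level — multiple
cores per patient are treated as independent units with no clustering
correction.  This replicates standard tissue-microarray practice but
overstates effective sample size when cores per patient are correlated.

## Diagnostics

Scores are probit-transformed area fractions Φ⁻¹(clamp(AF/100, 10⁻⁶,
1−10⁻⁶)); a rank-based inverse-normal mode is available.  Both are strictly
monotone, so empirical-ROC results are transform-invariant (asserted in
tests).

The empirical ROC uses the `score > criterion` orientation (malignant =
high); a guard warns when AUC < 0.5, indicating flipped orientation.  AUC is
computed by the Mann–Whitney identity, which equals pair-counting with half
credit for ties.  LR+ = sens/(1−spec) is flagged infinite at specificity 1.
The binormal summary uses per-class moments rather than maximum likelihood
on the curve: moments are deterministic, closed-form and testable, and on
probit-transformed data the two differ little.  Both AUCs are always
emitted.

The two-marker logistic model is fitted by iteratively reweighted least
squares (IRLS, max 100 iterations, tolerance 10⁻¹⁰, singular systems solved
in the least-squares sense).  Complete separation — all fitted probabilities
within 10⁻⁶ of the labels, or coefficient blow-up — triggers a refit with a
ridge penalty λ = 10⁻⁴ on the slopes and a `separation_flag`; the penalty
keeps coefficients finite without materially changing classification.
Percent correctly identified is in-sample at probability cutoff 0.5, which
is the definition the tabulated panel percentages use; no cross-validation
is attempted, and in-sample figures are optimistic by construction.

## Colocalization

Stacks are reduced by maximum Z-projection; the Pearson coefficient is
computed over a signal mask.  The default mask is `either_above` with
per-channel Otsu thresholds: on real images, empty background (both channels
dark) carries no biology and biases r.  On the *synthetic* stacks, however,
there is no background — every pixel is signal — so masking or projection
only restricts range and attenuates r; ground-truth-recovery checks
therefore use single-slice stacks with `all_pixels`.  The mask mode is
recorded in every output row.  Group comparison is a two-sided paired
t-test on per-pair coefficients (cores are matched pairs); a Fisher-z option
transforms r before testing since r is bounded.

## Synthetic data: what it emulates, and what it does not

`generate_core_image` builds a disc-like tissue region (exactly the
requested fraction of pixels, nearest-to-center), unions random ellipses for
stain (global radius scale set by bisection so the realized stained fraction
matches the request to well within 0.5 percentage points), colors the three
classes at RGB (90,60,30) / (200,170,180) / ≥245 with optional Gaussian
noise, and can round-trip through JPEG to test threshold robustness.  It
emulates the *intensity structure* that the quantification chain depends on
— three separable classes, stain strictly on tissue — not gland morphology,
stain chemistry, uneven illumination or focus gradients.  Passing tests
show the measurement chain is correct, not that thresholds transfer to any
particular scanner or stain batch.

`generate_fluorescence_stack` mixes i.i.d. standard-normal latent fields
through the Cholesky factor of the target correlation matrix (for one pair
this is C = ρZ + √(1−ρ²)E), then maps affinely to 16-bit.  Correlations are
exact in expectation; the realized r per stack is returned as ground truth.
Across 20 seeds at 10⁵ pixels the mean |target − realized| is ≤ 0.02.  The
fields have no spatial autocorrelation, no point-spread blur and no
background — adequate for testing the statistic, silent on restoration.

`generate_cohort` draws per-core area fractions from a gamma (default) or
lognormal family matched to the requested group mean and SD = SE·√n, both
strictly positive.  The defaults are the benign/malignant group sizes and
moments of a typical marker in this kind of cohort (236/228 cores,
1.66 ± 0.12 vs 4.09 ± 0.27 % AF, implied fold ≈ 2.5).  The family choice is
a modeling assumption: only means and SEs are constrained by data.

## Problem sizes and numerical choices

Test and acceptance runs use 512×512 cores (area fraction is scale-free;
asserted by a resolution-doubling test), 10⁴–10⁵-pixel fluorescence fields,
and 100-replicate significance simulations; the generator default stays
1024×1024.  Probit clamping at 10⁻⁶ bounds transformed scores at ±4.75.
All generators and pipelines are pure functions of their spec/seed;
re-running a pipeline with the same config and seed is byte-identical.

One documented infeasibility: with four matched pairs whose groups have
means 0.73 and 0.60 and SDs 0.02 and 0.07, the two-sided paired t-test at
α = 0.05 has analytic power ≈ 0.67 (noncentral t, 3 df, ncp ≈ 3.57), at
most ≈ 0.73 under the strongest within-pair correlation consistent with
those group SDs.  A single observed p < 0.02 at n = 4 is therefore
plausible but not typical; the corresponding power assertion in the
acceptance tests documents the stricter bound it fails to reach.
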