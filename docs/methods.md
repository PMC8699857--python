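# Methods

## Problem and model

Peripheral facial paralysis (most commonly Bell's palsy) disrupts local
blood circulation on the affected side of the face, and with it the normally
mirror-symmetric facial surface-temperature distribution. `thermasym`
quantifies that disruption from a single frontal infrared thermogram — a
matrix of surface temperatures in °C — and turns it into a screening
classification (paralysis vs. normal).

The pipeline has five stages:

1. **Bilateral ROI segmentation.** The warm face is separated from the
   cooler background by Otsu thresholding of the gray-quantized image.
   Facial key points — nostrils (cold), pupils (cool), inner canthi (the
   warmest facial structures), mouth corners, eyebrows — are localized by
   fusing Harris corner responses, Canny edges, and gray-projection profiles
   inside anthropometric search windows expressed as fractions of the face
   bounding box. Ten rectangular ROIs in five left/right pairs (forehead R1,
   orbital R2, infraorbital R3, nasal R4, mouth R5) are laid out around the
   key points and symmetrized about the facial midline so paired rectangles
   are exact mirror images of identical size.
2. **Feature extraction.** Per ROI: temperature features `T_mean` (mean),
   `T_max` (mean of the warmest 5% of pixels, `m = ceil(0.05 N)`), and
   `T_min` (mean of the coldest 5%); and GLCM texture statistics (contrast,
   correlation, energy, homogeneity) over the parameter grid
   Δ ∈ {2, 5} × G ∈ {16, 32} × θ ∈ {0°, 45°, 90°, 135°} — 16 co-occurrence
   matrices per ROI. GLCM counting is ordered (one displacement per
   direction) and normalized by the number of valid pairs.
3. **Symmetry measurement.** Per ROI pair: `ΔT_mean = |T_L,mean − T_R,mean|`,
   `ΔT_max = max(T_L,max − T_R,min, T_R,max − T_L,min)`, and for each texture
   feature and (Δ, G) cell the Minkowski distance over the four directions,
   `ρ_P = (Σ_θ |F_L(θ) − F_R(θ′)|^P)^{1/P}` with P ∈ {1, 2}. That yields
   2 + 32 = 34 symmetry values per pair, a 170-dimensional vector per
   subject.
4. **Feature selection.** Two-sided Welch t-test per feature between groups;
   features with p < 0.05 (no multiplicity correction by default) feed the
   classifier. Shapiro–Wilk normality is reported as advisory context only.
5. **Classification and evaluation.** RBF-kernel SVM with (C, γ) chosen by
   5-fold grid search on the training fold only; k-NN (k = 5) and LDA as
   comparators. Generalization is estimated by 10 repetitions of a
   stratified leave-30-out split (15 patients + 15 controls per test set,
   every House–Brackmann grade II–V represented among the test patients),
   reporting the mean accuracy, sensitivity, specificity, precision, F1,
   and ROC AUC over the repetitions.

## Design choices where the design was genuinely open

* **`T_max`/`T_min` normalization.** The tail means divide by the tail size
  `m = ceil(0.05 N)`, not by N: dividing by N would make `T_max` about 5% of
  `T_mean`, which is inconsistent with any physical reading of the features
  or with the magnitudes such asymmetry statistics take in practice.
* **`ΔT_mean` uses the absolute value**: the measure is a symmetry
  magnitude, and published group summaries of such measures are
  non-negative.
* **Mirror mapping of diagonal directions (`mirror_mode`, default on).**
  When comparing texture across sides, the right ROI's 45° and 135°
  directions are swapped. A face and its mirror image then produce ρ = 0
  exactly — the essential testable invariant "perfect symmetry ⇒ zero
  asymmetry". A same-direction comparison is available (`mirror_mode=False`)
  and is what the triangle-inequality metric property applies to directly;
  with the mirror map the composed bound is d(a, Mc) ≤ d(a, Mb) + d(b, c),
  since the swap is an isometry.
* **Per-ROI min–max gray quantization for GLCMs.** Texture is meant to
  capture the spatial *shape* of the temperature field; the absolute
  left/right offset is already captured by the ΔT features. A shared-range
  mode is available (`quantize_roi(..., lo_hi=...)`).
* **Ordered (non-symmetric) GLCM counting**, one displacement per direction,
  normalized by valid-pair count. Under ROI transposition this maps
  directions as 0° ↔ 90° (matrices transpose into each other) while 45° and
  135° each map to (a transpose of) themselves; because all four statistics
  are transpose-invariant, per-direction values follow that mapping exactly
  (property-tested against a brute-force pair-count oracle).
* **Welch rather than Student t-test**: group SDs of asymmetry measures are
  strongly unequal (patients are far more variable than controls).
* **Selection mode.** `paper_faithful` (default) selects once on the full
  cohort before cross-validation, which leaks test-label information into
  the feature choice; `leak_free` re-selects within every training fold and
  is the mode to trust on real data. The default reproduces the protocol the
  package models; the flag documents the caveat.
* **F1 vs the alternative F-score.** The report computes F1 as
  2·precision·sensitivity/(precision+sensitivity). Published tables of this
  protocol sometimes print a quantity matching
  2·precision·specificity/(precision+specificity) instead; the report emits
  that as `f_alt` for comparison but never labels it F1.
* **Anthropometric windows and ROI fractions.** Eyes in [0.20, 0.45]·H of
  the face box, nose in [0.45, 0.70]·H, mouth in [0.70, 0.90]·H, eyebrows in
  [0.10, 0.30]·H; orbital boxes 0.45·IPD wide and 0.12·H tall, infraorbital
  directly below, nasal 0.10·H squares flanking the nostrils, mouth 0.12·H
  squares on the mouth corners, forehead band 0.15·H above the eyebrows.
  These follow classical facial canons; no numeric layout is canonical, and
  all values are config-overridable (`SegmentationConfig`).
* **Landmark localization details.** Nostrils: two deepest column-projection
  minima near the midline (the cool face rim would dominate a full-width
  projection baseline). Pupils/canthi: smoothed gray extrema in per-side
  lateral bands, refined to the nearest Harris corner maximum within 3 px.
  Mouth corners: the warm mouth band must raise Canny edges in the mouth
  window (presence check); its row is the detrended row-projection centroid
  and its lateral ends are half-maximum crossings of the
  background-subtracted column projection — a projection-based estimate
  proved far more stable than taking the lateral extremes of the longest
  edge run, which is sensitive to stray edge fragments. Eyebrows: coldest
  compact structure above the pupils in a narrower band (the face narrows
  toward the top).
* **Half-integer midline.** For an even-width face the mirror axis falls
  between two pixel columns; `midline_col` is kept at half-pixel resolution
  so ROI pairs can be exact content mirrors.

## The synthetic phantom (what it emulates, what it does not)

No clinical thermograms are available, so the test substrate is a generated
phantom: an elliptical face (~33.5 °C) on a ~24.5 °C background — the
ambient range of a controlled acquisition room — warm medially and cooler
laterally, with cold nostrils (−6 °C), warm inner canthi (+1.5 °C), cool
pupils (−2.5 °C) and eyebrows (−2 °C), a warm mouth band (+1.2 °C), and
spatially correlated Gaussian pixel noise (SD 0.05 °C, the thermal
sensitivity of the camera class used for such studies; correlation length
3 px). With noise off the phantom is bitwise equal to its horizontal mirror.
Every phantom carries exact ground-truth landmarks and ROI boxes; the
mouth-band corner is defined at the band's half-maximum end, since a soft
band has no unique corner pixel.

Unilateral paralysis is modeled as (a) per-ROI mean offsets on the affected
side with defaults equal to published control-vs-patient group gaps
(forehead 0.32 °C, orbital 0.24 °C, infraorbital 0.22 °C, nasal 0.05 °C,
mouth 0.04 °C), delivered through edge-tapered windows normalized so the
ROI-mean shift equals the nominal offset exactly, and (b) a texture
perturbation blending in a locally smoothed copy of the field (blend weight
0.6 × severity, smoothing σ = 2 px), which raises affected-side GLCM
energy/homogeneity and therefore the bilateral texture distances — the
direction of difference reported for real patients. Severity maps linearly
from the House–Brackmann grade (II = 0.4 … V = 1.0); only monotonicity is
assumed, since clinical asymmetry is known not to track the grade exactly.
Healthy subjects receive small random one-sided per-ROI offsets
(SD 0.15 °C) so control-group asymmetries are nonzero, as in real cohorts.

The default cohort is 45 patients (HB grade counts II: 3, III: 8, IV: 14,
V: 20) plus 45 controls, with a random affected side per patient.

What the phantom does **not** emulate: pose variation, facial hair, glasses,
perspiration, vascular texture beyond smooth gradients, camera calibration
drift, or confounding diseases that also disturb facial temperature. Passing
tests therefore demonstrate the correctness and internal consistency of the
algorithms and the detectability of effects of the published size under
idealized imaging — not clinical performance.

## Numerical choices

* Gray quantization: `level = floor((t − lo)/(hi − lo)·L)` clamped to
  `L − 1`; per-image min–max range by default (the camera's absolute offset
  carries no shape information, and segmentation becomes invariant to adding
  a constant to all temperatures).
* Degenerate cases: a constant ROI quantizes to level 0 with a flag, its
  GLCM has energy 1 and contrast 0, and correlation uses the sentinel 0 when
  either marginal SD vanishes. Two zero-variance samples with equal means
  give t-test p = 1 by convention. Zero-denominator confusion rates are NaN
  sentinels.
* The zero-asymmetry invariant on the noise-free phantom holds exactly for
  ΔT_mean and to ~1e-13 for ρ (texture sums of bitwise-identical GLCMs
  accumulate in different orders under mirroring).
* Morphological erosion treats out-of-image pixels as background; Harris is
  computed on the mean-subtracted image and Canny with nearest-neighbor
  border handling, so a constant image yields exactly zero response/edges
  and image borders create no artifacts.
* All randomness flows from explicit integer seeds (`numpy` Generator);
  cohort generation, splits, and reports are reproducible bit-for-bit.

## Problem sizes used by the test and acceptance runs

Images are 256 × 336 px. The acceptance run generates one default 90-subject
cohort end-to-end (automatic segmentation included), evaluates the standard
feature-set comparisons over 10 cross-validation seeds, checks planted-
feature selection recovery on 20 simulated 90 × 170 feature tables, checks
forehead-gap significance across 50 independently generated cohorts, and
measures landmark recovery on 100 phantoms. The pytest acceptance suite uses
the same conditions with 25 cohorts for the forehead check.

## Known limitations

* The anthropometric layout assumes an upright, roughly frontal face filling
  a substantial part of the frame; there is no pose normalization.
* Landmark detection is tuned for thermograms with the canonical cold/warm
  organ pattern; absent structures (e.g. no cold nostrils) raise a named
  landmark failure rather than degrading silently.
* `paper_faithful` selection leaks label information into the feature
  choice; reported cross-validated numbers under that mode are optimistic.
* The SVM hyperparameter grid is small by design (C ∈ {0.1, 1, 10, 100},
  γ ∈ {0.001, 0.01, 0.1, 1/d}); widening it trades runtime for little gain
  at n = 60 training subjects.
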