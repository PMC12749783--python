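# Methods

`tonescale` evaluates how well subjective skin-tone labeling schemes —
Fitzpatrick Skin Type (FST, 6 photosensitivity classes), the Monk Skin Tone
scale (MST, 10 shades) and the Pantone SkinTone Guide (undertone × pigment
swatches) — capture objectively measured skin color, and whether a melanoma
classifier's scores distribute differently across those classes. This note
records the models, conventions and numerical choices behind each stage,
and what the synthetic study generator does and does not emulate.

## Color space and ITA

All image color work runs through the standard sRGB decoding chain: 8-bit
sRGB → linear light (IEC 61966-2-1 piecewise transfer function) → XYZ (the
canonical sRGB primaries matrix) → CIELAB. The reference white is taken as
the exact row sums of the RGB→XYZ matrix (numerically ≈ D65), so the
neutral axis r = g = b maps to a\* = b\* = 0 identically; this keeps the
256-gray round trip exact to ±1 per channel and makes neutral patches
cleanly degenerate for ITA. Images are assumed untagged sRGB; no ICC
profile handling or chromatic adaptation is performed.

The individual typology angle is computed exactly as written in the
dermatology literature,

    ITA = arctan((L* − 50) / b*) · 180/π   [degrees],

using `arctan`, not `atan2`: a negative b\* flips the angle's sign rather
than wrapping the quadrant. This is documented behavior, not corrected.
When |b\*| < 1e−6 the angle is undefined and a `DegenerateChromaticity`
error is raised instead of returning ±90°. ITA is used as a continuous
variable throughout; no ITA skin-tone binning is applied.

Representative image color is the per-channel (marginal) median of the
8-bit RGB pixels, computed *before* linearization (extract RGB, then
convert). Even pixel counts average the two central values and round half
away from zero. An optional inclusion mask supports excluding artifacts
(dark corners, stickers) but is off by default. On noise-free patches
rendered at a known CIELAB color, extracted ITA agrees with the true ITA
to within 1.5° (8-bit quantization; the observed worst case over a
100-point skin-tone grid is ≈1.2°).

## Agreement statistics

* **Linear-weighted Cohen's kappa** for ordered scales: κ = 1 − Σw·O / Σw·E
  with weights w_ij = |i−j|/(k−1). Weights always span the full scale range
  (k = 10 for MST, 6 for FST, 15 and 10 for the two Pantone components)
  even when levels are unobserved, so values are comparable across strata.
  If both raters used one identical category, chance agreement is total and
  a flagged NaN is returned — never a silent 0. Per-anatomic-site tables
  add a lesional-only and an all-site row; the all-site row is the kappa of
  the pooled pairs, not a mean of per-site values.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measurement — for repeated continuous measurements (colorimeter
  triplicate ITA; image-vs-colorimeter ITA as a 2-column design). The
  absolute-agreement form is the right question for "do repeated device
  measurements agree in value"; sites are pooled as independent subjects.
* **Paired t-test** on rating differences with a t-based 95% CI; identical
  vectors return p = 1 by convention, a constant nonzero difference raises
  an explicit zero-variance error.
* **Pearson chi-squared** independence test; zero expected counts are an
  error, not a warning. All p-values are two-sided; no multiple-testing
  correction is applied (per-site values are descriptive).
* Pantone swatch codes (e.g. `3Y08`) are analyzed as two ordered scales:
  pigment 1–15, and undertone mapped to the 10-level order
  5R,4R,3R,2R,1R,1Y,2Y,3Y,4Y,5Y — the only ordering that makes "5R to 5Y"
  an ordinal range.

## Dispersion in colorimeter space

Each colorimeter-measured, non-lesional site with at least one MST and one
Pantone rating contributes one point: the triplicate-averaged (L\*, b\*)
pair (a\* is excluded; the analysis is deliberately 2-D). Where both raters
rated, one rating is selected uniformly at random under a recorded seed.
Class labels *define* the clusters; nothing is fitted.

* **Davies-Bouldin index**: mean over classes of max (S_i+S_j)/M_ij with
  Euclidean distances and the canonical mean-distance scatter S. Coincident
  centroids raise an error rather than being skipped. A separate per-class
  "radius" — the population SD of member-to-centroid distances — is kept
  for circle-plot geometry only; it is not the DBI scatter term.
* **Mean silhouette (RSI)** with the convention that a point alone in its
  class contributes exactly +1 (relevant for Pantone, where the full swatch
  code defines the class and singletons are common).

Both indices are invariant to rigid motion of the plane, and shrinking
classes toward their centroids strictly improves both — property-tested.

## Crowd aggregation

Quality control is sequential. Each user's *trailing accuracy* is the mean
correctness of their last 50 gold-scored reads (window configurable; the
exact value is immaterial at scale in simulation). A read is *qualified*
iff its user's current accuracy ranks at or above the 20th percentile of
all current user accuracies (i.e. the top 80%) at the moment of the read;
users with no scored history yet cannot be ranked and their reads are
unqualified. Per image, the majority label is the label chosen by ≥70% of
≥3 qualified reads (the 70% boundary is inclusive: 7 of 10 labels); with
more than 12 qualified reads a plurality suffices and ties are unresolved.
Unresolved images are excluded from the downstream confusion table and
kappa. The real crowdsourcing platform's bookkeeping (which items are
scored, per-read vs per-competition ranking) is proprietary; the
sequential per-read rule here is an explicit, documented stand-in.

## Fairness audit

Benign-lesion malignancy scores (0–100%) are compared across classes with
the two-sample Kolmogorov-Smirnov statistic D = sup|F_i − F_j| (supremum
over the pooled sample points). D is invariant under strictly monotone
transforms, so the log display transform (base e, scores floored at 1e−4%)
never changes it — asserted in tests. Summaries: per-class mean percentile
rank in the pooled sample (midrank ties, 100·(rank−0.5)/n), the full
pairwise KS matrix, and the mean D at each ordinal class distance Δ
(per-pair values are retained alongside the mean; pairs with an empty
class are omitted). Asymptotic p-values are available, but D itself is the
primary quantity.

## Synthetic study generator

The generator produces the full study the pipeline consumes, with known
ground truth so every estimator can be checked by parameter recovery. What
it emulates, and the default conditions:

* **Cohort**: 64 participants, FST-balanced (10/12/11/10/11/10 for I..VI);
  11 standardized non-lesional sites plus 5–13 lesions each; 73.4% of
  participants colorimeter-measured (47 of 64).
* **Color model**: each MST shade has a mean CIELAB color with L\*
  decreasing monotonically 75 → 30 across shades 1..10 and b\* rising then
  falling; anatomic-site offsets (e.g. the callused sole is modeled ~6 L\*
  lighter, sun-exposed forearm/forehead darker) plus Gaussian within-class
  spread (σ_L = 2.5). These are configuration values, not claims about
  real skin.
* **FST ↔ tone**: a participant's true MST tone is drawn around an
  FST-implied center (1 + 1.8(f−1)) with σ = 2.5 shades. The wide spread is
  deliberate: it encodes, as generator ground truth, that a
  photosensitivity class spans a broad range of true color — the structure
  the dispersion analysis exists to detect (DBI: MST < FST).
* **Rater noise**: MST ratings apply a symmetric kernel (70% exact, 15%
  each ±1, clipped at scale ends); Pantone components use a wider kernel
  (50/17.5/7.5). The kappa these kernels imply is computable in closed form
  from the kernel and the realized class distribution (`implied_kappa`) and
  the pipeline estimate recovers it within ±0.05.
* **Colorimeter**: triplicates add per-channel Gaussian noise
  (σ_L = 0.4, σ_a = 0.25, σ_b = 0.35). The implied triplicate-ITA ICC is
  the variance ratio between-site/(between-site + delta-method noise
  variance) (`implied_icc`); recovered within ±0.05.
* **Lighting**: white-light TBP ratings are biased −0.70 MST (lighter) and
  cross-polarized +0.15 on the latent tone before rounding, so the paired
  tests recover the configured signs (clipping attenuates magnitudes at
  the scale ends).
* **Dermoscopy imaging**: patches are rendered at the true site color
  passed through a device-processing model — auto exposure compresses
  captured L\* toward a mid tone (slope 0.25 about L\* = 60) and b\* mildly
  (0.60) — then shifted by per-mode (dL\*, db\*) offsets (polarized modes
  yellower/darker, non-polarized lighter), with per-pixel Gaussian RGB
  noise. The compression is what decouples image-extracted ITA from
  colorimeter ITA, reproducing the qualitative in-person ≫ image agreement
  gap.
* **Crowd**: 60 users with Beta(6,3) skill. Critically, all readers of an
  image share a *perceived* tone — true FST shifted by dermoscopy mode,
  anatomic site, and an image-level N(0, 0.7) bias — and individual errors
  scatter around that shared perception. Correlated errors survive
  majority voting, which is what produces realistic (not near-perfect)
  crowd concordance, with the highest per-class concordance at the clipped
  scale ends (FST I and VI) and the lowest mid-scale. One image per
  lesional site enters the task (mode assigned per site), so the per-image
  majority rule is applied exactly as stated.
* **Scores**: per-MST-shade Beta distributions scaled to percent, means
  ≈2–3.5% for shades 1–7 with shades 8–9 shifted upward (8% and 10%), and a
  common concentration of 8. FST inherits the structure only through its
  noisy link to MST, so KS-by-Δ rises more cleanly under MST than FST.

All randomness flows from one master seed through named substreams
(participants, colors, ratings, colorimeter, TBP, images, crowd, scores,
rater selection); the same seed reproduces every table byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photorealistic skin texture, lesion morphology,
vascularity or lentigines beyond site offsets; real annotator demographics
or engagement dynamics; the real classifier (scores are a parametric
stand-in, with a CSV drop-in point for real outputs); JPEG compression
artifacts (an optional JPEG mode exists but PNG is the default); and any
claim about the true color distribution of human skin.

## Problem sizes and numerical choices

The default study (64 participants, ~1300 sites, ~2800 rendered patches,
~4600 crowd reads, ~570 scores) generates in a few seconds and the full
pipeline runs in under ten; parameter-recovery checks run on this size.
Monte-Carlo convergence checks use n = 2000–5000 where ±0.05 tolerances
require it, and KS-by-Δ monotonicity is checked at 400 scores per class
under a monotone-shift score configuration. Ties in qualification ranks
are resolved inclusively (accuracy ≥ threshold qualifies); the 70%
majority boundary is inclusive; midranks handle score ties; degenerate
inputs (empty masks, neutral chromaticity, zero-variance designs,
coincident centroids, empty classes) raise typed errors or are reported as
missing, never silently imputed.

## Known limitations

The printed headline statistics of the motivating clinical study are not
reproducible at desk scale without its deposited dataset; this package
validates the *methods* by oracle equivalence and parameter recovery on
synthetic data whose generating values are known. The dispersion indices
additionally depend on an unrecorded rater-selection seed and on the DBI
scatter convention (mean distance here, per the canonical definition; an
SD-based variant would differ), so even on the real data exact numeric
agreement of DBI/RSI would not be expected.
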