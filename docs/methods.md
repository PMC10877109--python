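# Methods

## Overview

`histoclust` implements a weakly supervised pipeline for characterising
primary liver cancers (PLC) on routine-stained biopsy slides. The three
tumour types of interest span a spectrum: hepatocellular carcinoma (HCC,
eosinophilic tumour hepatocytes in trabeculae with scant stroma),
intrahepatic cholangiocarcinoma (iCCA, glandular structures embedded in
abundant fibrous stroma, stained orange by saffron), and combined
hCC-CCA tumours containing both contingents. The pipeline never sees
tumour-type labels at the tile level; it only uses coarse tumour /
non-tumour outlines — the weak supervision — and discovers the
HCC-like / iCCA-like structure by unsupervised clustering:

1. **Tiling.** Slides are cut into a non-overlapping grid of windows of
   fixed physical size (default 125 µm), background is masked away, and
   each retained tile gets a weak tumour / non-tumour label from the
   annotation mask by majority vote.
2. **Weak feature learning.** A convolutional classifier is trained to
   predict the weak label. Its head is then discarded and the last
   convolutional layer becomes a feature extractor for tumour tiles.
3. **Clustering.** Pooled tile features are reduced to half their
   dimension by PCA and clustered with a K-component Gaussian mixture
   fitted by expectation-maximization (K = 2 by default, K = 3
   supported).
4. **Slide analysis.** Per-slide cluster proportions quantify the two
   tumour contingents; the majority cluster (via a cluster→type map
   learned from pure-diagnosis slides) predicts the slide diagnosis, and
   proportions are compared against pathology and against contingents
   quantified from immunohistochemistry (IHC) cell counts.

Everything is exercised end to end on synthetic biopsy phantoms with
exact per-pixel ground truth, so the whole method is testable without
any real whole-slide image.

## Tiling

* **Coordinates.** Pixels are 0-based, origin top-left; grid windows are
  half-open `[r, r+s) × [c, c+s)` with stride equal to the window edge
  (no overlap). A pixel belongs to a polygon iff its centre lies inside
  it (even-odd rule; self-intersecting polygons are rejected by index).
  These conventions are fixed so patch manifests are byte-reproducible.
* **Tissue mask.** Stained tissue is far more saturated than the
  near-white background, so the mask thresholds HSV saturation at 0.07
  by default, with an Otsu fallback (`saturation_threshold=None`) for
  atypical stain intensity.
* **Thresholds.** A tile is retained when its tissue fraction exceeds
  0.5 ("mainly tissue"), and labelled tumour when more than half of its
  window pixels fall inside the tumour mask — the same majority rule
  applied to border tiles.
* **Resampling.** When the physical window is not exactly the output
  size, the window is resampled bilinearly; in the desk-scale phantom
  setup 125 µm maps to exactly 64 px, so no resampling occurs.

## Augmentation

Transforms are restricted to pathologically plausible ranges: hue
±2 % of the hue circle, multiplicative saturation in [0.2, 1.6]
(−80 %…+60 %), brightness ±0.2, rotations in [−90°, +90°] with reflect
padding, independent horizontal/vertical flips, a 3×3 Gaussian blur
applied with probability 0.25, and a scale jitter in [1.0, 1.2].
Saturation is implemented multiplicatively (an additive reading of
"−80 % to +60 %" would be the alternative; the multiplicative one keeps
white background white). Policies outside these bounds are rejected
unless explicitly overridden. Transforms compose in a fixed order
(scale → rotation → flips → colour → blur) so a seed fully determines
the output; every augmented tile's sampled parameters are logged in the
manifest. The number of augmented copies per training tile is exposed
(`n_augments_per_patch`, default 1). Validation tiles are never
augmented, and the split is patient-level: a slide id appearing in both
partitions is an error, not a warning.

## Weak feature learning

* **Backbone.** The default backbone is a compact four-stage CNN
  (3×3 conv + ReLU + 2×2 max-pool, channels 8/16/32/32, global average
  pooling, single-logit head) implemented directly on NumPy with an
  im2col convolution and hand-derived backprop (verified against finite
  differences in the test suite). On 64×64 tiles it trains in minutes on
  one CPU and yields a 32-dimensional pooled feature per tile. The
  `resnet18` configuration value describes the transfer-learning recipe
  (17 conv layers, first 9 frozen, last 8 fine-tuned) but requires a
  deep-learning runtime and pretrained weights that this package does
  not bundle; selecting it raises a clear error.
* **Optimisation.** Adam with an exponentially decaying learning rate,
  `lr_e = lr_0 · γ^e` stepped per epoch with γ = 0.5. The configuration
  default `lr_0 = 0.03` is the fine-tuning recipe for a pretrained deep
  backbone; for the compact random-initialised backbone trained from
  scratch the pipeline uses `lr_0 = 0.003`, which is stable across
  seeds. Loss is binary cross-entropy; epochs default to 10 (the
  end-to-end phantom runs use 5, which suffices on the phantom
  textures); batch size 64. Frozen layers receive no updates and are
  audited bitwise in the tests.
* **Features.** The "last convolutional layer" representation is the
  post-activation map of the final conv stage. The clusterable unit is
  its global spatial mean (one vector per tile); the full spatial map is
  available on request (`keep_maps=True`) for the per-pixel pathway.
  Patch-level pooling is the default because all downstream quantities
  (cluster tile counts, per-slide proportions) are defined per tile.
  Inputs are normalised by training-set channel statistics (there is no
  canonical normalisation for a randomly initialised backbone).
* **Degenerate inputs.** Single-class training sets are rejected; a
  non-finite loss aborts with a diagnostic rather than continuing.

## Clustering

* **PCA.** Features are mean-centred and projected onto their top D/2
  principal components (a deterministic full-SVD solve). Rank-deficient
  inputs keep only the rank components, with a warning. The transform
  is persisted so an external cohort can be projected without refitting.
  Following the pipeline's design, PCA and the mixture are fitted on
  validation-cohort tumour tiles and then applied to all slides.
* **EM.** The Gaussian mixture is fitted by a hand-implemented EM with
  full covariances: k-means initialisation, `n_init = 5` seeded
  restarts, `max_iter = 200`, `tol = 1e-4` on the change in mean
  per-sample log-likelihood, and a `1e-6` ridge on covariance diagonals
  to keep them positive definite (singular initialisations are
  regularised with a warning, not an error). The per-iteration
  log-likelihood trace is recorded and must be non-decreasing within
  1e-7 — a property test — and small instances are checked against an
  independent brute-force EM and against `sklearn.mixture.GaussianMixture`
  from identical initialisations to 1e-6/1e-5.
* **Component identity.** Raw EM component order is arbitrary, so
  components are re-indexed by descending mixture weight before any
  reporting; "cluster 0 / cluster 1" is therefore stable across runs.
* **Cluster→type map.** Each cluster is mapped to the majority tumour
  type among its tiles from pure-diagnosis (HCC or iCCA) reference
  slides, with the composition table reported. Exact ties are refused
  unless a tie-break type is given; two clusters mapping to the same
  type is legal (the K = 3 regime has two HCC-like clusters) and
  triggers a warning plus pooled proportions downstream.

## Slide analysis

Per-slide proportions are simple tile counts per cluster divided by the
slide's tumour-tile total. The predicted major contingent is the type
with the largest pooled proportion; an exact tie is flagged
`indeterminate` rather than silently broken. IHC contingents follow the
marker rule: the HCC contingent percentage is the larger of the
glypican-3 and anti-hepatocyte positive-cell ratios, the iCCA contingent
is the CK7 ratio. Agreement tables report per-diagnosis concordance
rounded half-up to integer percent (half-up reproduces the printed
ratios such as 7/9 → 78 and 13/15 → 87; half-even cannot be
distinguished from the printed values and half-up is adopted and
documented). Model-vs-IHC association uses the standard Pearson
product-moment correlation on paired percentages; zero-variance inputs
yield NaN with a warning.

## Synthetic phantoms

The generator emulates the aspects of biopsy slides the pipeline is
sensitive to, and nothing more:

* an elongated, gently curved tissue strip (buffered sine centreline)
  on a near-white background — biopsy geometry with scarce tissue;
* a contiguous tumour segment whose outline is emitted as GeoJSON-style
  polygons, exactly consistent with the truth masks because both are
  rasterised from the same geometry with the same pixel-centre rule;
* two procedural tumour textures: texture A (HCC-like) — packed pink
  cell blobs with dark nuclei and no stroma; texture B (iCCA-like) —
  dark ring/gland motifs on striped saffron-orange stroma; plus a pale
  non-tumour parenchyma texture;
* mixed slides place the two contingents contiguously (as in real
  combined tumours); an interleaved checkerboard mode exists for stress
  tests;
* synthetic IHC counts: marker-positive cells are binomial draws whose
  probabilities track the true contingent fraction with ±5 % systematic
  jitter, exercising the max-of-two-antibodies rule and the correlation
  pipeline with a known expected association.

Contingent fractions are realised by cutting the tumour region along
cumulative pixel columns, which lands within 2 % of the requested
fraction (typically well under 1 %). Default cohorts are balanced —
one third HCC-like, one third iCCA-like, one third mixed with fractions
drawn from [0.2, 0.8] — with a stratified, patient-level 70/30 split.

**What the phantoms do not emulate:** nuclear pleomorphism, stain
variability between laboratories, scanner artefacts (folds, tears,
fragmentation), tumour grade heterogeneity, or any texture subtler than
the blob/ring contrast. Passing the phantom suite therefore shows the
pipeline's machinery is correct and that it recovers structure whose
separability is at least that of the phantom textures (certified by a
nearest-mean-colour baseline at ≥ 0.95 tile accuracy before any network
is trained); it does not show that real HCC/iCCA morphology is
separable at the same accuracy — the real-tissue accuracies are
substantially lower than the phantom ones, as expected.

## Problem sizes and numerical choices

The end-to-end runs use 30 phantom slides (10 + 10 + 10) of 448×640 px
at 125 µm ≈ 64 px, giving roughly 650 tiles of which ~400 are tumour;
the compact backbone trains for 5 epochs. These sizes were chosen so a
complete pipeline run finishes in about a minute on a single CPU while
leaving enough validation tiles (~100) to fit a 16-dimensional
full-covariance two-component mixture comfortably.

Tie-breaks and degenerate cases are all explicit: label majority uses a
strict `> 0.5` rule; an all-background slide yields an empty mask with a
warning; slides smaller than one window yield zero patches with a
warning; sub-pixel window requests are errors.

## Known limitations

* No deep pretrained backbone is bundled; transfer learning from
  ImageNet-scale weights is out of scope for this package.
* The pipeline consumes IHC *cell counts*; single-cell segmentation of
  IHC slides (done interactively in external tools) is not implemented.
* K is a parameter, not a model-selection output: no information
  criterion is applied across K.
* Phantom realism is deliberately minimal (see above).
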