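# Methods

This note documents the models, parameter choices and numerical
conventions behind `octma`, and what the synthetic experiments do and
do not demonstrate.

## Coordinate and labeling conventions

Images are indexed 0-based as (row, column) with the origin top-left;
crops are half-open.  Points exchanged with the registration module are
(x, y) = (column, row).  The 30-px strip window around center `c` is
`[c-15, c+15)`.  The positive class is MA everywhere: sensitivity is
the recall of MA strips, specificity the recall of normal strips.

## Synthetic B-scan model

The generator is the *minimal* model exhibiting the appearance facts
the pipeline exploits, not a physical OCT simulator.

* **Layers.**  Seven horizontal Gaussian-profile bands with alternating
  reflectivities (0.55, 0.25, 0.50, 0.22, 0.45, 0.30, 0.85); the
  brightest, deepest band plays the RPE.  The stack anchors at row 175
  and spans 120 px of depth in a 496×768 scan — roughly the proportions
  of a macular spectral-domain B-scan.  Band sigma is 0.3 × spacing, so
  neighbouring bands stay distinct.
* **Fovea.**  A cosine dip (30 px deep, half-width 20% of the image
  width, centered) shifts band centers downward, attenuating linearly
  with depth — inner layers dip, the RPE stays flat, producing foveal
  thinning.
* **Speckle.**  Multiplicative Rayleigh noise rescaled to unit mean and
  blended with weight `speckle_sigma` (default 0.12).  This reproduces
  the granular multiplicative character of OCT speckle, not its
  spatial correlation (see Limitations).
* **Microaneurysm.**  A soft-edged hyperreflective disc (radius 6 px,
  additive contrast 0.30, sigmoid edge of width 0.7 px) centered in
  band 3 — the dark mid-retinal band standing in for the inner nuclear
  layer — plus an upward bulge of the overlying bands (Gaussian in
  column, sigma 2 × radius).  The bulge amplitude defaults to
  20 × contrast: clinically, larger MAs thicken the retina more, and
  tying the deformation to the contrast means "contrast → 0" removes
  the lesion entirely, which the degradation experiments rely on.
* **Per-strip eye variation.**  The study conditions pool strips over
  many patients, so the strip generator draws per-strip band
  reflectivities (cv 0.15) and retinal thickness (cv 0.10) around the
  nominal values.  Without this heterogeneity the flattened-descriptor
  (PCA) features are unrealistically clean and the bag-of-features
  representation shows no advantage.
* **Lesion placement jitter.**  Training-strip lesions sit up to ±5 px
  off the strip center, modeling registration residual plus crop
  quantization.  Perfectly centered lesions make the classifier
  position-brittle at detection time.

Strips for datasets are rendered directly as 30-column windows (full
height, then ROI-trimmed); this is pixel-equivalent to cropping a full
render at the same columns and ~25× cheaper, which is what keeps the
test-suite experiment sizes (202-strip datasets, multi-seed sweeps)
tractable.

## Synthetic en-face model

FA and SLO share one vessel tree grown by branching random walks
(3 trunks entering from the edges, heading jitter 0.08 rad/step,
branching probability 0.03/step, up to 32 walkers), splatted with a
Gaussian profile of sigma 2.8 px — a ~6–10 px full width, the caliber
of major retinal vessels at typical en-face sampling.  FA shows bright
vessels on a dark background plus Gaussian "hyperfluorescent" dots at
MA sites; the SLO twin has inverted vessel contrast, no dots, and its
geometry pushed through the true warp.  The warp is a similarity
transform about the image center (rotation, scale, translation)
optionally composed with a smooth sinusoidal displacement field
(amplitude ≤ a few px, wavelength 250 px) standing in for residual
non-rigid eye-surface distortion.  The 31 B-scan acquisition lines are
spaced uniformly over the central 80% of the SLO height, and MA dots
are kept ≥ 12% of the image size away from the borders so annotations
fall inside the scanned region.

## Registration

Vessel maps come from the multiscale Frangi filter (sigmas 1–2.5 px),
with polarity set by the modality flag.  Phase I maximizes zero-mean,
globally normalized cross-correlation over a three-pass grid:

| pass | rotation step | scale step | resolution |
|------|---------------|------------|------------|
| coarse | 1° over ±10° | 0.02 over 0.90–1.10 | maps downsampled 4× |
| mid | 0.2°, one coarse step wide | 0.01 | downsampled 2× |
| fine | 0.1° | 0.005 | full |

The translation at each (rotation, scale) candidate is read off the
FFT cross-correlation peak, so it is never gridded.  Each pass's grid
contains the previous best; with downsampling disabled the result is
provably the maximum over every scanned cell (tested against a
brute-force scan).  The three-pass layout evaluates a few hundred
candidates instead of tens of thousands at full resolution.

Phase II shifts a 64×64 patch of the affinely aligned FA against the
(intensity-inverted) SLO around each MA point, scanning integer
displacements at steps {4, 2, 1} px within a radius of 8 px; each finer
pass searches the reach of the previous one, so a single-step schedule
degenerates to an exhaustive scan.  The displacement starts at zero and
only improves, so refinement can never worsen the local score.  Mapped
points pick the nearest B-scan row (ties to the lower index) and the
nearest pixel column.

## Dense SURF

One keypoint per cell of an 8×8 grid (rounded cumulative splits, cells
differing by ≤ 1 px), fixed scale s = 1.6 px, no interest-point
detection.  The standard SURF constants are used: orientation from
Haar responses (filter side 4s) in a radius-6s disc, Gaussian-weighted
(sigma 2s), maximized over 40 sliding π/3 windows; descriptor from a
20s-sided oriented square, 4×4 subregions × 5×5 samples, Haar side 2s,
Gaussian sigma 3.3s, per-subregion (Σdx, Σ|dx|, Σdy, Σ|dy|),
L2-normalized to 64-d.  An upright variant (orientation pinned to 0)
is available behind a flag.

Boundary handling: the integral image is built over edge-replicated
padding wide enough that every Haar window stays inside it.  This is
the "nearest valid pixel" extension, and it keeps the descriptor's
invariance to adding a constant *exact* even for edge cells (box
differences cancel), which the test suite asserts bitwise on
dyadic-valued images (multiples of 1/256, whose float64 sums are exact
in any order).  Descriptors whose raw response norm falls below 1e-8 —
the summation-noise level of a constant patch — are flagged degenerate
and left as zero vectors rather than normalized noise.

## Vocabulary and encoding

k-means++ (D² seeding) followed by Lloyd iterations under the Euclidean
metric, K = 100, fit on training-split descriptors only.  Written
in-package rather than delegated so that per-iteration inertia is
recorded (its monotone decrease is an asserted invariant) and the
empty-cluster rule is explicit: an emptied center re-seeds at the
point farthest from its assigned center.  Convergence: assignment
stability, relative inertia change < 1e-6, or 300 iterations.
Nearest-word ties break to the lowest index.  Term vectors are
L1-normalized by default (raw counts available); the per-class summed
histograms ("word profiles") are exportable for plotting.

## Classifiers

* **MLP** — one hidden layer, 10 tanh units, full-batch Adam
  (lr 0.01), trained in chunks of 20 steps; after each chunk the
  log-loss on the *provided* validation split is measured, training
  stops after 20 chunks without improvement and the best-validation
  weights are restored.  The explicit validation split in the 70/15/15
  protocol strongly implies validation-driven early stopping, which
  sklearn's built-in mechanism (internal re-split) cannot honor —
  hence the manual loop.  Three random restarts are trained and the
  lowest-validation-loss network kept: a 10-neuron net is sensitive to
  its initialization, and restart selection uses no test information.
* **Baselines** — Gaussian SVM (variance-adaptive gamma = 
  1/(dim·Var X), C = 1), linear SVM (C = 1), KNN (k = 5), Gaussian
  naive Bayes.  MLP, SVMs and KNN see standardized inputs (scaler fit
  on the training split); naive Bayes models per-feature variance and
  takes raw vectors.  These hyperparameters are package defaults, not
  reported study values.
* **PCA ablation** — the 64 grid descriptors concatenated in fixed
  grid order (4096-d), PCA (50 components, full SVD, deterministic)
  fit on training strips only.

Splits are stratified 70/15/15 with largest-remainder rounding at both
the global and per-label level, so 202 strips give 142/30/30 with every
per-label count within one strip of exact proportionality.

## Detection

A B-scan is tiled by strips at stride 30 (25 tiles plus one
right-aligned strip for a 768-px scan; overlapping strides are
configurable), each trimmed, encoded and scored; the MA threshold
defaults to 0.5.  Strips exactly cover `[0, width)`.

## What the synthetic experiments show — and don't

Passing tests demonstrate that each stage recovers the ground truth
its generator implanted: registration recovers known warps to the fine
grid step and maps annotations within 2 px; the feature/vocabulary/MLP
chain separates lesioned from clean strips at ≥ 90% test accuracy at
the default lesion contrast and degrades to chance as the contrast
vanishes; the bag-of-features path beats the PCA + KNN ablation under
inter-eye heterogeneity.  They do *not* establish clinical
performance: the generator omits spatially correlated speckle, vessel
shadowing in B-scans, pathologies other than MA, motion artifacts, and
real inter-device variation.  Numbers on real data will differ.

Known limitations: lesions inside the foveal dip are the hard case for
the detector (layer geometry is compressed there; the default-stride
tiling also splits off-center lesions between strips); hyporeflective
MAs are not simulated; the PCA-path flattening assumes the fixed dense
grid, so it does not generalize to variable keypoint counts.

Experiment sizes in the test suite (202-strip datasets, 5-seed sweeps,
20 registration pairs) were chosen as the smallest sets that make the
pass/fail contrasts statistically unambiguous.
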