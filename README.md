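# octma — microaneurysm detection in retinal OCT B-scans

Microaneurysms (MAs) are the earliest clinical sign of diabetic
retinopathy.  They are conventionally found on fluorescein angiography
(FA), an invasive dye-injection exam; OCT is non-invasive, but an MA in
a single B-scan is a subtle, small hyperreflective blob in the inner
nuclear layer that is easy to miss.  `octma` implements a screening
pipeline that learns to recognize MA cross-sections in OCT, using FA
only once — to label the training data:

1. **Registration.**  The en-face FA image is aligned to the device SLO
   image (pixel-aligned with the B-scan stack) in two phases: a rigid
   similarity search maximizing the normalized cross-correlation of
   Frangi vessel maps over a coarse-to-fine rotation/scale grid, then a
   translation-only patch refinement around each annotated MA point.
   Each FA annotation thereby maps to a (B-scan index, column) pair.
2. **Strip extraction.**  Around every mapped column a 30-px-wide
   vertical bar is cut and trimmed top/bottom to the 170 rows containing
   the retinal layers, giving fixed 170×30 strips labeled MA or normal.
3. **Bag of features.**  Each strip is described by dense SURF: one
   64-d descriptor per cell of an 8×8 grid (integral-image Haar
   responses, orientation assignment, 4×4 subregions of
   (Σdx, Σ|dx|, Σdy, Σ|dy|)).  Descriptors pooled over the *training*
   strips are clustered by k-means++ into K = 100 visual words; every
   strip becomes the length-100 histogram ("term vector") of its 64
   descriptors' nearest words.
4. **Classification.**  A one-hidden-layer MLP (10 neurons) with
   validation-driven early stopping labels term vectors MA / normal.
   Gaussian SVM, linear SVM, KNN and Gaussian naive Bayes are the
   baselines, and a PCA path (flattened grid descriptors reduced to 50
   components instead of the visual-word histogram) is the ablation.
   Metrics use MA as the positive class:
   accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN),
   specificity = TN/(TN+FP), precision = TP/(TP+FP).

At test time a B-scan is tiled into consecutive 30-px vertical strips,
each encoded against the trained vocabulary and classified, flagging
the columns that contain MA cross-sections.

Patient data is not required anywhere: `octma.synthetic` renders
layered, speckled B-scans with implanted hyperreflective lesions and
paired FA/SLO vessel images under a known warp, so every stage is
testable against ground truth.  See `docs/methods.md` for the image
model and all numerical choices.

## Worked example

Train on a synthetic dataset with the study's class sizes and inspect a
B-scan:

```sh
$ octma train --n-ma 92 --n-normal 110 --vocab-size 100 --seed 0 --out bundle/
{
  "accuracy": 96.66666666666667,
  "sensitivity": 100.0,
  "specificity": 93.75,
  "precision": 93.33333333333333,
  "confusion": {
    "tp": 14,
    "fp": 1,
    "tn": 15,
    "fn": 0
  }
}
```

202 strips were split 70/15/15 (142/30/30, stratified); the numbers are
computed on the 30 held-out test strips: all 14 MA strips and 15 of the
16 normal strips were classified correctly.

```sh
$ octma simulate --seed 2 --n-ma-points 3 --out eye/
manifest: eye/manifest.json
$ octma detect --bscan eye/bscan_15.png --bundle bundle/ --out det/
```

`det/detections.csv` lists the 26 strips tiling the 768-px B-scan with
their labels and MA scores, and an overlay PNG marks flagged strips in
red (the visualization clinicians would review).

Other verbs: `octma register` (two-phase FA→SLO alignment report),
`octma extract` (labeled strips from a manifest), `octma sweep`
(hidden-neuron sweep), `octma compare` (the 10-row
{BOF, PCA} × classifier table).

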