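# Methods

## The model

`sparsebagnet` implements an inherently interpretable screening classifier
for diabetic retinopathy (DR): a bag-of-local-features convolutional
network (BagNet).  The network's effective receptive field is restricted
to q×q = 33×33 input pixels on a lattice of stride s = 8, so each cell of
its spatial output is a function of exactly one small image patch.  The
spatial output A_c — the *class evidence map* — is therefore a faithful
per-patch account of where the model sees evidence for class c, and the
class logit is defined as the spatial mean of A_c:

    logit_c = mean_{i,j} A_c[i, j],      p = softmax(logit).

Class probabilities and the explanation (the map, and bounding boxes
around its peaks) are thus two views of the same numbers; nothing is
post-hoc.

Training minimizes a sparsified objective

    L = CE(softmax(mean A), y) + λ · Σ_{i,j,c} |A_c[i, j]|,

cross-entropy plus an ℓ1 penalty over every cell of both class maps.  The
penalty concentrates evidence on few patches, which is what makes the
derived bounding boxes precise.  Both terms are averaged over the batch so
λ does not depend on batch size.

### Architecture as data

The backbone is described by an `ArchitectureSpec` (layer kinds, kernels,
strides, channels); `(q, s)` is *computed* from the spec by the standard
receptive-field recursion (rf ← rf + (k−1)·jump, jump ← jump·stride) and
cross-checked empirically by single-pixel perturbation probing.  Any spec
whose recursion yields (33, 8) is a conformant backbone.  The reference
spec uses five unpadded 3×3 convolutions with strides (1, 2, 2, 2, 1) —
giving exactly rf 33, cumulative stride 8 — followed by a residual block
of 1×1 convolutions and a 1×1 class head, which add depth without touching
patch geometry.  All convolutions are valid (unpadded); patch positions
are the placements fully inside the image, so an H×W input yields a
⌊(H−33)/8⌋+1 square lattice (60×60 for 512×512).

Convolutions carry batch normalization and ReLU; the class head is a
bias-free 1×1 convolution, so the evidence scale is anchored by patch
features rather than a free global offset (a bias on the head undergoes a
large-step random walk under the ℓ1 subgradient and destabilizes the sign
of background evidence).

The network, its backward pass and the SGD-with-momentum optimizer are
implemented directly on numpy (im2col convolutions).  The definitional
correctness oracle — evaluating every 33×33 patch independently and
comparing with the convolutional forward pass — is part of the test suite
and of the acceptance script (agreement to 1e-4 relative).

### Training procedure

SGD with momentum 0.9 under a *clipped cosine* schedule: the learning rate
follows cosine annealing from `initial_lr` toward zero over `epochs`,
floored at `min_lr`.  Defaults follow the full-scale recipe (initial
1e-3, floor 1e-4, 100 epochs); the reduced benchmark (below) uses its own
documented values because it trains from scratch rather than from
pretrained weights.  Initialization is seeded He-normal; a checkpoint hook
accepts external weights.  Augmentation — horizontal/vertical flip, ±5%
translation, optional rotation (±15°), color jitter (0.1), random crop
(scale 0.9–1.0), and fresh gaussian pixel noise per presentation — applies
to training batches only.  The best-validation-accuracy weights are kept.

λ is chosen on the validation fold: among candidates, take the largest λ
whose validation accuracy is within δ = 0.01 of the maximum — the
sparsest model at essentially no accuracy cost.

### Data splitting

Train/validation/test folds target 75/10/15 of *images* while keeping all
images of a subject in one fold.  Subjects are sorted, shuffled with the
seed, and filled into folds until each fold's image-count target is met;
the assignment depends only on the subject set and seed, not record order.

## Explanations

- **Overlay**: each map cell's value is placed at its patch-center pixel
  (i·s + (q−1)/2) and interpolated bilinearly between centers, with edge
  clamping beyond the outermost centers.  No smoothing is added.
- **Bounding boxes**: greedy peak picking on the DR evidence map.
  Repeatedly take the cell with the highest strictly positive evidence
  (ties broken row-major), emit its patch rectangle (rows [i·s, i·s+q)),
  then suppress all cells whose patch centers lie within q/2 pixels
  (Chebyshev) of the selected center.  Stop at k_max = 12 boxes or when no
  positive cell remains; an all-nonpositive map yields an empty (valid)
  explanation.  Box scores are the raw map values — never resampled.  The
  suppression radius and tie-break are this package's contract; they
  prevent near-duplicate boxes while allowing adjacent distinct lesions.
- **Ranked patches**: the pixel crops behind the boxes, highest evidence
  first.

## Evaluation

- **Classification**: accuracy, AUC (rank statistic), sensitivity,
  specificity, precision at threshold 0.5, each with a percentile
  bootstrap CI (2.5/97.5 percentiles) from 1000 unstratified, seeded
  resamples.  With single-class labels the AUC is undefined and reported
  as such; the other metrics are still computed.
- **Localization precision**: a box is a hit iff ≥1 annotated lesion pixel
  lies inside its rectangle (no overlap threshold — annotations may be
  sparse point marks dilated to 5-px discs).  Precision pools hits over
  all boxes of all images; a per-image breakdown is reported alongside,
  since either pooling convention is defensible.  Lesion *recall* is
  deliberately not evaluated: the model is not a lesion detector, and
  decision support does not require exhaustive detection.
- **Random-box baseline**: 20 random receptive-field-sized boxes per
  annotated image, rejecting boxes with more than 10% black pixels (all
  channels < 10/255) so chance is measured over the retinal field; the
  attempt cap is 10,000 draws.
- **Consensus masks**: pixelwise union and intersection across graders.
- **Patch dice**: both annotations are rasterized onto the model's patch
  lattice (33×33 patches, strides 8/32 overlapping or 33 non-overlapping;
  a patch is positive iff it contains any annotated pixel) and dice is
  computed over positive-patch sets, defined as 1.0 when both are empty.

## Preprocessing

Fundus photographs are cropped to a centered square around the retinal
field: threshold any channel at 10/255, keep the largest connected
component, fit a circle to its boundary pixels by linear least squares
(Kåsa), and resample the circle's bounding square (black-padded if it
exceeds the frame) to 512×512 with bilinear interpolation.  Boundary pixel
centers sit about half a pixel inside the continuous circle, so the fitted
radius is compensated by +0.5 px.  Per-channel mean/std are pooled over
all pixels of the training fold only and reused verbatim for validation,
test and external data.

## Synthetic scenes

The generator emulates the *structure* of a screening dataset, not retinal
photorealism: a bright circular field (radius 0.42–0.48 of the image side)
with radial falloff, low-frequency shading, dark vessel-like arcs and
pixel noise; two eyes per subject with subject-level disease status
(default prevalence 0.27); and small planted lesions whose exact rendered
footprints form the localization ground truth.  Lesion types follow the
clinical vocabulary: microaneurysm-like dark-red discs (radius 2–4 px),
hemorrhage-like irregular dark blobs (unions of jittered discs, radius
5–12 px), and bright exudate-like deposits (radius 4–10 px).  Grade 1
plants 1–3 lesions, grade 2 plants 4–10; grades 3–4 are out of scope
(their hallmark lesions are not local).  A blob's shape is a pure function
of the lesion's own fields, so any lesion can be re-rendered independently
— the basis of the mask-consistency oracle.

Three features keep the task honest.  25% of DR scenes are *subtle
presentations* whose lesions all draw from a low-contrast range
(0.04–0.10 instead of 0.10–0.35) — a patient's lesions share phenotype
and acquisition conditions, so faintness is a scene property, not a
per-lesion coin flip.  Half of the healthy scenes carry 1–3 faint
MA-coloured distractor specks (pigment spots, dust) that are *not* in the
lesion mask.  And 6% of healthy scenes are *confounders* bearing 2–4
full-contrast MA-like spots under a healthy reference label — screening
reference labels are imperfect, and such images are what drives a real
model's rare false positives.  Without these the classes are trivially
separable and a screening model makes no errors, which would say nothing
about localization and could not support the error-stratified reader
study.

What passing tests on these scenes do not show: robustness to real
acquisition variation (illumination, camera optics, ungradable images),
anatomy (optic disc, macula, real vasculature), or the hard ambiguity of
real grade-1 screening.  The synthetic recovery study is a correctness
check of the pipeline under conditions where ground truth is exact, not a
clinical performance claim.

## The reduced benchmark study

Full-scale training (tens of thousands of 512×512 images, 100 epochs) is
out of reach on one CPU, so the package defines one canonical reduced
study (`sparsebagnet.experiments`), used identically by the tests, the
examples and the acceptance script:

- 200 subjects (400 scenes of 128×128 px), prevalence 0.30, split 75/10/15
  by subject;
- reduced backbone of the same (33, 8) geometry, double-width channels
  (16/32/48/64/64);
- λ = 1e-3, 35 epochs, SGD momentum 0.9, cosine from 0.05 floored at
  0.002, batch 16; flips, translation and fresh pixel noise as
  augmentation.  The learning rate is larger than the full-scale recipe
  because training starts from random weights, not a pretrained backbone;
- sparsity-response grid at λ ∈ {0, 1e-4, 1e-3} on a 200-image cohort,
  12 epochs each, reporting held-out mean |A|;
- localization scored on a separate annotated pool of 45 DR scenes whose
  grade mix (13 mild : 32 moderate) matches the ~20:45 composition of the
  annotated evaluation subset used at full scale;
- the reader-study set built from the trained model's scores on a fresh
  pool (120 scenes per grade, enlarged to 360 if needed), thresholded at
  0.5.  The study is *defined* around model errors (five per grade); at
  full scale the test pool is large enough that the default operating
  point supplies every stratum, but at reduced scale the model can be
  error-free on a grade (mean pooling over 144 patch cells makes a few
  spots hard to mistake for disease, so specificity saturates).  When a
  stratum is short, the operating point is recalibrated to the feasible
  threshold closest to 0.5 — the predictions remain a monotone function
  of the model's real scores.

## Numerical choices and degenerate inputs

- float32 network arithmetic; float64 for evidence-map analysis, softmax
  and metrics.  Softmax subtracts the row maximum; CE clamps probabilities
  at 1e-300.
- The ℓ1 subgradient uses sign(0) = 0.
- Bit-identical reruns: all randomness flows from explicit
  `numpy.random.Generator` seeds (generation, splitting, batching,
  augmentation, bootstrap, box sampling); two runs with the same seeds
  produce byte-identical weights and artifacts.
- Degenerate inputs raise typed errors: all-black images (circle fit),
  constant channels (normalization), inputs smaller than one patch,
  single-class labels (AUC), empty training folds, negative λ, stride ≤ 0,
  and reader-study strata with too few candidates (the error names the
  stratum).
- Evidence maps with no positive cell yield an empty explanation, not an
  error; patch dice of two empty annotations is 1.0.

## Known limitations

- The numpy engine targets clarity and determinism over speed; it is
  single-threaded BLAS-bound and far slower than a GPU framework.
  Training beyond a few hundred 128-px images is impractical.
- Pretrained initialization, the five-grade head, pooling layers beyond
  the spec kinds, and black-box baselines with post-hoc attribution are
  not implemented; external heatmaps can still be scored by feeding them
  to `extract_boxes` as an adapter.
- The by-design reader-study set fixes the model accuracy at 75% for
  human-factors experiments; it is a sampling construction, not an
  estimate of model quality.
- At reduced scale the localization precision of the sparse model is
  variance-prone across training seeds (small cohorts, few annotated
  scenes); the benchmark's seed is part of the study definition.
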