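# sparsebagnet

Inherently interpretable screening for diabetic retinopathy (DR) with a
sparse bag-of-local-features network, plus the machinery to explain and
evaluate it — exercisable end to end on synthetic fundus-like scenes with
planted, pixel-annotated lesions.

## The idea

Standard screening CNNs are black boxes: a clinician gets a label and a
confidence, and any explanation is a post-hoc approximation.  A BagNet
restricts the network's effective receptive field so that each cell of its
spatial output depends on exactly one small image patch — here q×q = 33×33
pixels on a stride-8 lattice.  The spatial output **A_c** is then a *class
evidence map*: A_c[i, j] is the evidence for class c contributed by patch
(i, j) alone, and the class logit is literally its spatial mean,

    logit_c = mean_ij A_c[i, j],        p = softmax(logit),

so the heatmap *is* the decision, not a rationalization of it.  Training
adds an ℓ1 penalty on the maps,

    L = CE(softmax(mean A), y) + λ Σ_{i,j,c} |A_c[i,j]|,

which concentrates evidence on few patches.  Explanations for a clinician
are the upsampled evidence overlay and up to 12 receptive-field-sized
bounding boxes around the strictly positive evidence peaks, ranked by
evidence.  Early DR is a good match for this inductive bias: its lesions
(microaneurysms, small hemorrhages, exudates) are tiny and local.

The whole model — convolutions, batch norm, backprop, SGD with a clipped
cosine schedule — is implemented directly on numpy, and its defining
property is *verified*, not assumed: the convolutional forward pass is
tested cell-by-cell against independently encoding every 33×33 patch, and
the (33, 8) geometry is checked both by the receptive-field recursion and
by single-pixel perturbation probing.

The package also provides: circle-fit preprocessing of fundus photographs
to 512×512, subject-grouped 75/10/15 splitting, validation-based λ
selection, classification metrics with 1000-resample bootstrap CIs,
bounding-box lesion-localization precision against annotation masks, a
random-box chance baseline, grader-consensus masks, patch-level dice for
inter-grader agreement, a synthetic-fundus generator with exact lesion
masks, and the stratified 60-image reader-study constructor (20 images per
grade 0/1/2, 15 correctly + 5 incorrectly classified each ⇒ 75% model
accuracy by design).

## Worked example

```python
>>> import numpy as np
>>> from sparsebagnet import build_reference_backbone, effective_receptive_field
>>> from sparsebagnet.model import reference_spec, map_grid_shape
>>> effective_receptive_field(reference_spec())
(33, 8)
>>> map_grid_shape((512, 512), 33, 8)
(60, 60)
```

A quick end-to-end run on synthetic scenes (see `examples/` for the full
narrative scripts):

```python
>>> from sparsebagnet.experiments import ReducedStudyConfig, make_cohort, train_candidate
>>> from sparsebagnet.training import predict_scores
>>> config = ReducedStudyConfig(n_subjects=60, width=1, epochs=10)
>>> cohort = make_cohort(config, seed=0)
>>> model, history = train_candidate(cohort, config, lambda_sparsity=1e-3, seed=0)
>>> te = cohort.folds == "test"
>>> scores = predict_scores(model, cohort.images[te])
>>> from sklearn.metrics import roc_auc_score
>>> print(f"held-out AUC: {roc_auc_score(cohort.labels[te], scores):.3f}")
held-out AUC: 0.958
```

Explaining one held-out diseased scene (`examples/04_explain_image.py`):

```
prediction: DR (confidence 0.970); true grade 2
overlay range: [-1.42, 13.10] (positive = evidence for DR)
  box  1: rows 80-112, cols 48-80, evidence 13.099 -> lesion
  box  2: rows 24-56, cols 24-56, evidence 7.145 -> lesion
  box  3: rows 56-88, cols 48-80, evidence 4.533 -> lesion
  ...
  box 12: rows 72-104, cols 0-32, evidence 0.208 -> no lesion
localization precision on this image: 0.83
12 ranked 33x33 patch crops extracted
```

Each box is a 33×33 patch whose evidence value is taken straight from the
map cell that produced it; "lesion" means at least one annotated lesion
pixel falls inside the box.

The command-line pipeline mirrors the library:

```bash
sparsebagnet generate --out data --n-subjects 50 --seed 1
sparsebagnet split --metadata data/metadata.csv --out data/split.csv --seed 1
sparsebagnet train --data data --split data/split.csv --out run --lambda 1e-3 --epochs 10 --seed 1
sparsebagnet predict --model run/model.npz --data data --out run/scores.csv
sparsebagnet explain --model run/model.npz --image data/images/subj00000_left.png --out run/expl
sparsebagnet evaluate --scores run/scores.csv --out run/metrics.json
```

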