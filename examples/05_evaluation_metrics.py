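"""The evaluation toolbox on small worked examples.

Shows each metric against a hand-checkable input: AUC on a 4-point toy by
pair enumeration, localization precision on known boxes, the random-box
chance baseline that avoids the black background, grader-consensus masks,
and patch-level dice at the strides used for inter-grader agreement.
"""

import numpy as np

from sparsebagnet.evaluation import (
    classification_metrics,
    consensus_masks,
    patch_dice,
    random_box_baseline,
)

# AUC on the 4-point toy: 3 of 4 positive-negative pairs correctly ranked
rep = classification_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1], n_bootstrap=200, seed=0)
print(f"toy AUC = {rep.auc.point:.2f} (pair enumeration gives 0.75)")

# random-box baseline: chance that a 33x33 box on the retinal field hits a lesion
rng = np.random.default_rng(0)
img = np.zeros((128, 128, 3), np.float32)
rr, cc = np.mgrid[0:128, 0:128]
disc = (rr - 64) ** 2 + (cc - 64) ** 2 <= 58**2
img[disc] = 0.6
mask = np.zeros((128, 128), bool)
mask[(rr - 50) ** 2 + (cc - 70) ** 2 <= 6**2] = True
chance = random_box_baseline(img, mask, n_boxes=20, seed=0)
print(f"random-box baseline on one small lesion: {chance:.2f} "
      "(20 boxes, >10%-black rejected)")

# consensus masks and patch dice between two simulated graders
g1 = np.zeros((128, 128), bool)
g2 = np.zeros((128, 128), bool)
g1[(rr - 50) ** 2 + (cc - 70) ** 2 <= 7**2] = True   # grader 1 paints wider
g2[(rr - 51) ** 2 + (cc - 71) ** 2 <= 5**2] = True   # grader 2 slightly offset
union, inter = consensus_masks([g1, g2])
print(f"consensus: union {int(union.sum())} px, intersection {int(inter.sum())} px")
for stride in (8, 32, 33):
    print(f"patch dice (33x33, stride {stride}): {patch_dice(g1, g2, stride=stride):.3f}")
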