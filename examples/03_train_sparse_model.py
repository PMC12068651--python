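"""Train a small sparse bag-of-local-features screener on synthetic scenes.

A deliberately quick run (60 subjects, 10 epochs, narrow backbone) that
still shows the training mechanics: subject-grouped splitting, the
clipped-cosine schedule, the l1-sparsified objective, and held-out
screening metrics with bootstrap confidence intervals.  Expect a few
minutes on one CPU; the full reduced benchmark lives in
sparsebagnet.experiments.run_recovery_study.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from sparsebagnet.evaluation import classification_metrics
from sparsebagnet.experiments import ReducedStudyConfig, make_cohort, train_candidate
from sparsebagnet.training import predict_scores

config = ReducedStudyConfig(n_subjects=60, width=1, epochs=10)
cohort = make_cohort(config, seed=0)
print("fold sizes:", {f: int((cohort.folds == f).sum()) for f in ("train", "val", "test")})

model, history = train_candidate(cohort, config, lambda_sparsity=1e-3, seed=0)
frame = history.frame()
print(frame[["epoch", "lr", "loss", "ce", "l1", "val_accuracy"]].tail(3).to_string(index=False))

te = cohort.folds == "test"
scores = predict_scores(model, cohort.images[te])
print(f"held-out AUC: {roc_auc_score(cohort.labels[te], scores):.3f}")
report = classification_metrics(cohort.labels[te], scores, n_bootstrap=200, seed=0)
acc = report.accuracy
print(f"accuracy {acc.point:.3f} (95% CI {acc.ci_low:.3f}-{acc.ci_high:.3f}) "
      f"from 200 bootstrap resamples")
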