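"""Construct the by-design reader-study set.

The study set used for clinician experiments is stratified: 20 images per
grade 0/1/2, of which exactly 15 were classified correctly by the model
and 5 incorrectly — fixing model accuracy on the set at 45/60 = 75% and
the DR fraction at 40/60, independent of how good the model actually is.
Here the pool's predictions are simulated; any per-scene binary outputs
work, provided each stratum has enough correct and incorrect candidates.
"""

import numpy as np

from sparsebagnet import GeneratorConfig, generate_scene, sample_reader_study

config = GeneratorConfig()
scenes, preds = [], []
seed = 0
for grade in (0, 1, 2):
    for k in range(30):
        scene = generate_scene(config, seed=seed, grade=grade)
        seed += 1
        correct = k < 22  # a pool with 22 correct / 8 incorrect per grade
        preds.append(scene.label if correct else 1 - scene.label)
        scenes.append(scene)

study = sample_reader_study(scenes, np.array(preds), seed=7)
rec = study.records
print(rec.groupby(["grade", "model_correct"]).size().to_string())
print(f"study size: {len(rec)} images")
print(f"model accuracy on the study set: {study.model_accuracy:.4f} (75% by design)")
print(f"DR fraction: {study.dr_fraction:.4f} (= 40/60)")
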