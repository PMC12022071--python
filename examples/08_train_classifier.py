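"""Train the three-fold CNN ensemble on synthetic plaque patches.

Generates 60 patches per morphotype (coarse-grained / cored / diffuse),
trains the ensemble under three-fold cross-validation and reports held-out
metrics.  With the default architecture this takes a few minutes on one
CPU; the run in scripts/acceptance.py uses 100 patches per class.
"""

import numpy as np

from plaquemap.classifier import (
    TrainConfig, classification_metrics, split_train_test, train_crossval)
from plaquemap.synthio import make_patch_set

patches, labels = make_patch_set(60, seed=1)
xtr, ytr, xte, yte = split_train_test(patches, labels, seed=0)
print(f"training on {len(xtr)} patches, testing on {len(xte)}")

cfg = TrainConfig(epochs=12, patience=5, seed=0)
ensemble = train_crossval(xtr, ytr, cfg)
for f, hist in enumerate(ensemble.fold_history):
    print(f"fold {f}: {len(hist)} epochs, "
          f"final val accuracy {hist[-1]['val_acc']:.2f}")

pred = ensemble.predict(xte)
order = ensemble.class_order
M = np.zeros((3, 3), dtype=int)
for yt, yp in zip(yte, pred):
    M[order.index(yt), order.index(yp)] += 1
report = classification_metrics(M, order)
print(f"\nheld-out accuracy: {report.accuracy:.3f}")
print("confusion matrix (rows true, cols predicted, order CGP/CP/DP):")
print(report.confusion)
print("per-class F1:", {k: round(v, 2) for k, v in report.f1.items()})
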