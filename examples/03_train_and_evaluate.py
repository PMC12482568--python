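"""Train the reduced dual-branch classifier on synthetic tiles.

Runs a shortened version of the fixture experiment (smaller tile set, 18
epochs) so it finishes in about a minute on one CPU, then reports metrics
and demonstrates patch-to-image majority voting.  The full 30-epoch run used
for the headline numbers lives in scripts/acceptance.py.
"""

import numpy as np

from histofusion import (HistoFusionNet, compute_metrics, predict_probs,
                         reduced_config, train, vote_by_image)
from histofusion.experiments import make_fixture_datasets, reduced_recipe

train_set, val_set, test_set = make_fixture_datasets(
    n_classes=4, tiles_per_class=60, tile_size=96, seed=0)
print(f"fixture task: {len(train_set)} train / {len(val_set)} val / "
      f"{len(test_set)} test tiles, 4 classes")

model = HistoFusionNet(reduced_config(4), image_size=96)
result = train(model, train_set, val_set, reduced_recipe(epochs=18), seed=0)
print(f"best validation accuracy {result.best_val_accuracy:.3f} "
      f"at epoch {result.best_epoch} "
      f"({'early-stopped' if result.stopped_early else 'ran to schedule'})")

probs = predict_probs(model, test_set.X)
metrics = compute_metrics(probs, test_set.y)
print(f"test accuracy {metrics.accuracy:.3f}, macro F1 "
      f"{metrics.macro_f1:.3f}, micro-average AUC {metrics.auc_micro:.3f}")

# majority voting: pretend each pair of test tiles are patches of one image
image_ids = np.repeat(np.arange(len(test_set) // 2), 2)
patch_preds = probs.argmax(axis=1)[:len(image_ids)]
votes = vote_by_image(image_ids, patch_preds, probs[:len(image_ids)])
image_labels = test_set.y[:len(image_ids):2]
vote_acc = np.mean([votes[i] == image_labels[k]
                    for k, i in enumerate(sorted(votes))])
print(f"image-level accuracy after majority voting over 2-patch groups: "
      f"{vote_acc:.3f}")
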