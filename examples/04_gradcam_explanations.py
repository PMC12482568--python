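"""Fused multi-layer Grad-CAM on a trained tile classifier.

Trains the reduced model on the 4-class fixture task (about two minutes on
one CPU), computes per-layer class activation maps on a
few tiles, fuses them (bilinear resize + equal-weight average + min-max
normalization), overlays the jet-colorized heatmap on the tile, and scores
localization against the generator's lesion masks.  The IoU is compared with
the closed-form chance level for independent random regions.
"""

import numpy as np

from histofusion import (FixtureSpec, HistoFusionNet, generate_tile,
                         reduced_config, train)
from histofusion.experiments import make_fixture_datasets, reduced_recipe
from histofusion.gradcam import (explain, localization_score, overlay,
                                 random_baseline_iou)

datasets = make_fixture_datasets(n_classes=4, tiles_per_class=100,
                                 tile_size=96, seed=0)
model = HistoFusionNet(reduced_config(4), image_size=96)
train(model, datasets[0], datasets[1], reduced_recipe(epochs=30), seed=0)

print("registered CAM layers:", model.cam_layer_names())
print("default fusion layers:", model.default_cam_layers())

spec = FixtureSpec(n_classes=4, tiles_per_class=100, tile_size=96, seed=0)
ious, baselines = [], []
for c in range(4):
    per_class = []
    for i in (80, 85, 90, 95):  # tiles with generator-provided masks
        tile = generate_tile(spec, c, i)
        cam = explain(model, tile.pixels.transpose(2, 0, 1))
        per_class.append(localization_score(cam, tile.lesion_mask, q=0.2))
        baselines.append(random_baseline_iou(0.2, tile.lesion_mask.mean()))
    ious.extend(per_class)
    tile = generate_tile(spec, c, 95)
    cam = explain(model, tile.pixels.transpose(2, 0, 1))
    ov = overlay(tile.pixels, cam, alpha=0.5)
    print(f"class {c}: explained class {cam.class_id}, "
          f"mean top-20% IoU vs lesion mask {np.mean(per_class):.3f}, "
          f"overlay range [{ov.min():.2f}, {ov.max():.2f}]")

print(f"\nmean IoU over 16 tiles: {np.mean(ious):.3f}; chance level for "
      f"independent random regions of these areas: {np.mean(baselines):.3f}."
      f"\nAn IoU above chance means the fused CAM concentrates on lesional "
      f"tissue rather than background.")
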