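"""Patch extraction and leakage-safe dataset splitting.

Shows the two patching modes (fixed grid for 2048x1536 fields, overlapping
sliding window for 700x460 images), the stratified 70/10/20 image-level
split, and the patient-grouped 5-fold plan with its leakage audit.
"""

import numpy as np

from histofusion import (FixtureSpec, TileRecord, audit_fold_plan,
                         audit_split, generate_dataset, grid_patch,
                         image_level_split, patient_grouped_kfold,
                         sliding_window_patch)

rng = np.random.default_rng(0)

# grid patching: a 2048x1536 field cut by a fixed 4x3 grid of 512-px tiles
field = rng.random((1536, 2048, 3)).astype(np.float32)
tiles = grid_patch(field, 512, (4, 3), source_image_id="field0")
print(f"grid 4x3 of 512px on 2048x1536 -> {len(tiles)} non-overlapping "
      f"tiles; first origins {[t.patch_origin for t in tiles[:3]]}")

# sliding window: 700x460 image, 224-px patches at stride 112
img = rng.random((460, 700, 3)).astype(np.float32)
win = sliding_window_patch(img, 224, 112, source_image_id="img0")
print(f"sliding window 224/112 on 700x460 -> {len(win)} overlapping tiles "
      f"(5 along x, 3 along y)")

# stratified image-level split: 200 images per class, 70/10/20
records = [TileRecord(source_image_id=f"c{c}i{i}", label=c)
           for c in range(4) for i in range(200)]
split = image_level_split(records, (0.7, 0.1, 0.2), seed=0)
print("split counts:", audit_split(split)["counts"],
      "(each class contributes 140/20/40)")

# patient-grouped stratified 5-fold with audit
spec = FixtureSpec(n_classes=4, tiles_per_class=82, tile_size=32, seed=0)
recs, _ = generate_dataset(spec)  # tiles grouped into synthetic patients
plan = patient_grouped_kfold(recs, k=5, seed=0)
audit = audit_fold_plan(plan, recs)
print(f"5-fold over {len({r.patient_id for r in recs})} patients: "
      f"max patients shared between folds = "
      f"{audit['max_shared_patients']} (0 = no leakage)")
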