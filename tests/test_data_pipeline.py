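"""Patching arithmetic, split bookkeeping, grouped k-fold, augmentation."""

import numpy as np
import pytest

from histofusion.data import (TileRecord, apply_augment, audit_fold_plan,
                              audit_split, augment, grid_patch,
                              image_level_split, manifest_to_records,
                              patient_grouped_kfold, reassemble_grid,
                              records_to_manifest, sample_augment_params,
                              sliding_window_patch)


def _image(h, w, seed=0):
    return np.random.default_rng(seed).random((h, w, 3)).astype(np.float32)


# -------------------------------------------------------------- grid patch

def test_grid_4x3_of_512_on_2048x1536_yields_12_tiles():
    records = grid_patch(_image(1536, 2048), 512, (4, 3))
    assert len(records) == 12
    # row-major order, origins at multiples of 512
    assert records[0].patch_origin == (0, 0)
    assert records[1].patch_origin == (0, 512)
    assert records[4].patch_origin == (512, 0)
    assert all(r.pixels.shape == (512, 512, 3) for r in records)


def test_grid_single_tile():
    records = grid_patch(_image(512, 512), 512, (1, 1))
    assert len(records) == 1 and records[0].patch_origin == (0, 0)


def test_grid_origins_follow_row_col_convention():
    records = grid_patch(_image(512, 1024), 512, (2, 1))
    assert [r.patch_origin for r in records] == [(0, 0), (0, 512)]


def test_grid_exceeding_image_reports_max_feasible():
    with pytest.raises(ValueError, match="maximum feasible grid is 4x3"):
        grid_patch(_image(1536, 2048), 512, (5, 3))


def test_grid_patches_reassemble_source_exactly():
    img = _image(1024, 1024, seed=3)
    records = grid_patch(img, 256, (4, 4))
    np.testing.assert_array_equal(reassemble_grid(records), img)


# ---------------------------------------------------------- sliding window

@pytest.mark.parametrize("h,w,expected", [
    (460, 700, 15),   # floor((700-224)/112)+1=5 by floor((460-224)/112)+1=3
    (224, 224, 1),
    (224, 336, 2),
])
def test_sliding_window_count_follows_axis_formula(h, w, expected):
    records = sliding_window_patch(_image(h, w), 224, 112)
    assert len(records) == expected
    for r in records:
        y, x = r.patch_origin
        assert y % 112 == 0 and x % 112 == 0
        assert y + 224 <= h and x + 224 <= w
        assert r.pixels.shape == (224, 224, 3)


def test_sliding_window_image_smaller_than_patch_raises():
    with pytest.raises(ValueError):
        sliding_window_patch(_image(100, 300), 224, 112)


# ------------------------------------------------------------------- split

def _records(n_per_class, n_classes=4, patches_per_image=1):
    records = []
    for c in range(n_classes):
        for i in range(n_per_class):
            for p in range(patches_per_image):
                records.append(TileRecord(source_image_id=f"c{c}i{i}",
                                          label=c, patch_origin=(0, p)))
    return records


def test_split_matches_reference_800_item_layout():
    records = image_level_split(_records(200), (0.7, 0.1, 0.2), seed=0)
    counts = audit_split(records)["counts"]
    assert counts == {"train": 560, "val": 80, "test": 160}
    for c in range(4):
        per = {s: sum(1 for r in records if r.label == c and r.split == s)
               for s in ("train", "val", "test")}
        assert per == {"train": 140, "val": 20, "test": 40}


def test_split_ten_items_gives_7_1_2():
    records = image_level_split(_records(10, n_classes=1), (0.7, 0.1, 0.2),
                                seed=1)
    counts = audit_split(records)["counts"]
    assert counts == {"train": 7, "val": 1, "test": 2}


def test_split_deterministic_given_seed_and_varies_across_seeds():
    a = image_level_split(_records(50), (0.7, 0.1, 0.2), seed=5)
    b = image_level_split(_records(50), (0.7, 0.1, 0.2), seed=5)
    c = image_level_split(_records(50), (0.7, 0.1, 0.2), seed=6)
    assert [r.split for r in a] == [r.split for r in b]
    assert [r.split for r in a] != [r.split for r in c]
    assert audit_split(a)["counts"] == audit_split(c)["counts"]


def test_split_counts_match_brute_force_rounding_rule():
    # 13 items at (0.7, 0.1, 0.2): val = round_half_down(1.3) = 1,
    # test = round_half_down(2.6) = 3, train takes the remainder = 9
    records = image_level_split(_records(13, n_classes=1), (0.7, 0.1, 0.2),
                                seed=0)
    assert audit_split(records)["counts"] == {"train": 9, "val": 1, "test": 3}


def test_split_keeps_patches_of_one_image_together():
    records = image_level_split(_records(10, patches_per_image=12),
                                (0.7, 0.1, 0.2), seed=0)
    assert audit_split(records)["images_straddling_splits"] == []


def test_synthetic_records_confined_to_training_split():
    records = _records(20, n_classes=2)
    synth = [TileRecord(source_image_id=f"gan{c}i{i}", label=c,
                        is_synthetic=True)
             for c in range(2) for i in range(10)]
    split = image_level_split(records + synth, (0.7, 0.1, 0.2), seed=0)
    assert all(r.split == "train" for r in split if r.is_synthetic)
    # real images still split by the rounding rule: 20/class -> 14/2/4
    real_counts = {s: sum(1 for r in split
                          if not r.is_synthetic and r.split == s)
                   for s in ("train", "val", "test")}
    assert real_counts == {"train": 28, "val": 4, "test": 8}
    # literal layout: synthetic images distributed like any other
    mixed = image_level_split(records + synth, (0.7, 0.1, 0.2), seed=0,
                              synthetic_train_only=False)
    assert any(r.split != "train" for r in mixed if r.is_synthetic)


def test_split_keeps_whole_patients_together_when_ids_present():
    records = _patient_records(40, images_per_patient=5, n_classes=2)
    split = image_level_split(records, (0.7, 0.1, 0.2), seed=0)
    by_patient = {}
    for r in split:
        by_patient.setdefault(r.patient_id, set()).add(r.split)
    assert all(len(s) == 1 for s in by_patient.values())
    counts = audit_split(split)["counts"]
    # patient blocks of 5: targets 20 val / 40 test met exactly here
    assert counts["val"] == 20 and counts["test"] == 40


def test_split_errors_on_class_smaller_than_bucket_count():
    with pytest.raises(ValueError, match="nonzero buckets"):
        image_level_split(_records(2, n_classes=1), (0.7, 0.1, 0.2), seed=0)


def test_split_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        image_level_split(_records(10), (0.7, 0.1, 0.1), seed=0)


# ------------------------------------------------------------------ k-fold

def _patient_records(n_patients, images_per_patient=4, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for p in range(n_patients):
        label = p % n_classes
        for i in range(images_per_patient):
            records.append(TileRecord(source_image_id=f"p{p}i{i}",
                                      label=label, patient_id=f"P{p:03d}"))
    return records


def test_five_patients_five_folds_one_patient_each():
    records = _patient_records(5, n_classes=1)
    plan = patient_grouped_kfold(records, k=5, seed=0, val_splits=2)
    for parts in plan.folds:
        test_patients = {records[i].patient_id for i in parts["test"]}
        assert len(test_patients) == 1


def test_82_patient_manifest_has_zero_patient_leakage():
    records = _patient_records(82, images_per_patient=3, n_classes=8)
    plan = patient_grouped_kfold(records, k=5, seed=0)
    audit = audit_fold_plan(plan, records)
    assert audit["max_shared_patients"] == 0
    assert all(v == 0 for v in audit["within_fold_shared_patients"])
    assigned = plan.assignments()
    assert len(assigned) == len(records)  # every record lands in one fold


def test_fold_class_proportions_near_global():
    records = _patient_records(20, n_classes=2)
    plan = patient_grouped_kfold(records, k=5, seed=0)
    audit = audit_fold_plan(plan, records)
    for props in audit["fold_class_proportions"]:
        for c, g in audit["global_class_proportions"].items():
            assert abs(props.get(c, 0.0) - g) <= 0.15


def test_kfold_missing_patient_id_directs_to_image_level_split():
    records = _records(10)
    with pytest.raises(ValueError, match="image_level_split"):
        patient_grouped_kfold(records, k=5, seed=0)


def test_kfold_k_exceeding_patients_raises():
    with pytest.raises(ValueError):
        patient_grouped_kfold(_patient_records(3), k=5, seed=0)


# ------------------------------------------------------------- augmentation

def test_double_horizontal_flip_is_identity():
    tile = _image(32, 32)
    params = {"policy": "geometric", "hflip": True, "vflip": False,
              "rot90": 0}
    once = apply_augment(tile, params)
    twice = apply_augment(once, params)
    np.testing.assert_array_equal(twice, tile)


def test_breakhis_rotation_always_within_ten_degrees(rng):
    angles = [sample_augment_params("breakhis", rng)["angle"]
              for _ in range(200)]
    assert all(-10.0 <= a <= 10.0 for a in angles)
    assert any(a != 0 for a in angles)


def test_augment_deterministic_given_rng_state():
    tile = _image(32, 32)
    a = augment(tile, "bach", np.random.default_rng(42))
    b = augment(tile, "bach", np.random.default_rng(42))
    np.testing.assert_array_equal(a, b)
    assert a.shape == tile.shape
    assert a.min() >= 0.0 and a.max() <= 1.0


def test_unknown_policy_raises(rng):
    with pytest.raises(ValueError, match="policy"):
        augment(_image(16, 16), "cifar", rng)


# --------------------------------------------------------------- manifests

def test_manifest_round_trip():
    records = image_level_split(_records(10), (0.7, 0.1, 0.2), seed=0)
    df = records_to_manifest(records)
    back = manifest_to_records(df)
    assert [r.source_image_id for r in back] == \
        [r.source_image_id for r in records]
    assert [r.split for r in back] == [r.split for r in records]
    assert [r.label for r in back] == [r.label for r in records]
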