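"""Tile extraction, dataset splitting, grouped cross-validation, augmentation.

Conventions: pixel coordinates are 0-based ``(row, col)`` = ``(y, x)`` with
half-open patch intervals; images are ``(H, W, 3)`` float arrays in [0, 1]
(or uint8, converted on read).  Splits operate at the source-image level so
patches of one image can never straddle subsets, and k-fold plans operate at
the patient level via scikit-learn's ``StratifiedGroupKFold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedGroupKFold

MANIFEST_COLUMNS = ["image_path", "label", "patient_id", "magnification",
                    "source_image_id", "patch_row", "patch_col", "split",
                    "is_synthetic"]


@dataclass
class TileRecord:
    source_image_id: str
    label: int
    patch_origin: tuple = (0, 0)          # (row, col)
    patch_size: int | None = None
    image_path: str | None = None
    patient_id: str | None = None
    magnification: str | None = None
    split: str | None = None              # "train" | "val" | "test" | fold id
    pixels: np.ndarray | None = None      # optional in-memory tile
    is_synthetic: bool = False            # e.g. externally generated images


@dataclass
class FoldPlan:
    k: int
    # per fold: {"train": [...], "val": [...], "test": [...]} record indices
    folds: list = field(default_factory=list)

    def assignments(self) -> dict:
        """Map record index -> index of the fold holding it as *test*."""
        out = {}
        for f, parts in enumerate(self.folds):
            for i in parts["test"]:
                out[i] = f
        return out


# ------------------------------------------------------------------ patching

def grid_patch(image: np.ndarray, patch_size: int, grid: tuple,
               source_image_id: str = "img", label: int = 0,
               **meta) -> list[TileRecord]:
    """Cut a fixed ``cols x rows`` grid of non-overlapping patches anchored
    at (0, 0); row-major order.  A 2048x1536 image with a 4x3 grid of 512
    yields 12 tiles."""
    cols, rows = grid
    H, W = image.shape[:2]
    if cols * patch_size > W or rows * patch_size > H:
        max_cols, max_rows = W // patch_size, H // patch_size
        raise ValueError(
            f"grid {cols}x{rows} of {patch_size}px patches exceeds the "
            f"{W}x{H} image; maximum feasible grid is {max_cols}x{max_rows}")
    records = []
    for r in range(rows):
        for c in range(cols):
            y, x = r * patch_size, c * patch_size
            records.append(TileRecord(
                source_image_id=source_image_id, label=label,
                patch_origin=(y, x), patch_size=patch_size,
                pixels=image[y:y + patch_size, x:x + patch_size].copy(),
                **meta))
    return records


def sliding_window_patch(image: np.ndarray, patch_size: int, stride: int,
                         source_image_id: str = "img", label: int = 0,
                         **meta) -> list[TileRecord]:
    """Overlapping patches at origins (i*stride, j*stride), fully contained;
    per-axis count floor((dim - patch)/stride) + 1.  A 700x460 image with
    224/112 yields 5 x 3 = 15 tiles."""
    H, W = image.shape[:2]
    if patch_size > H or patch_size > W:
        raise ValueError(f"patch {patch_size} larger than image {W}x{H}")
    ny = (H - patch_size) // stride + 1
    nx = (W - patch_size) // stride + 1
    records = []
    for i in range(ny):
        for j in range(nx):
            y, x = i * stride, j * stride
            records.append(TileRecord(
                source_image_id=source_image_id, label=label,
                patch_origin=(y, x), patch_size=patch_size,
                pixels=image[y:y + patch_size, x:x + patch_size].copy(),
                **meta))
    return records


def reassemble_grid(records: list[TileRecord]) -> np.ndarray:
    """Stitch grid patches back together (bookkeeping check)."""
    ps = records[0].patch_size
    rows = max(r.patch_origin[0] for r in records) // ps + 1
    cols = max(r.patch_origin[1] for r in records) // ps + 1
    out = np.zeros((rows * ps, cols * ps) + records[0].pixels.shape[2:],
                   records[0].pixels.dtype)
    for r in records:
        y, x = r.patch_origin
        out[y:y + ps, x:x + ps] = r.pixels
    return out


# ----------------------------------------------------------------- splitting

def _round_half_down(x: float) -> int:
    return math.ceil(x - 0.5)


def image_level_split(records: list[TileRecord], fractions: tuple,
                      seed: int, stratify: bool = True,
                      group_on_patient: bool = True,
                      synthetic_train_only: bool = True) -> list[TileRecord]:
    """Assign train/val/test at the source-image level.

    Within each class, the val and test bucket sizes are
    round-half-down(fraction * class size) and the remainder goes to train,
    so a 200-image class under (0.7, 0.1, 0.2) lands exactly at 140/20/40.
    Returns new records with ``split`` set; all patches of a source image
    share its assignment.  When every record carries a patient id (and
    ``group_on_patient`` is true), whole patients move together — the
    bucket targets are then met as closely as patient block sizes allow.

    Records flagged ``is_synthetic`` (e.g. generatively augmented images)
    are confined to the training split by default, so evaluation happens on
    real data only; pass ``synthetic_train_only=False`` to distribute them
    like any other image.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} must sum to 1")
    if synthetic_train_only and any(r.is_synthetic for r in records):
        real = [r for r in records if not r.is_synthetic]
        split_real = image_level_split(real, fractions, seed, stratify,
                                       group_on_patient,
                                       synthetic_train_only=False)
        by_image = {r.source_image_id: r.split for r in split_real}
        return [replace(r, split="train") if r.is_synthetic
                else replace(r, split=by_image[r.source_image_id])
                for r in records]
    f_train, f_val, f_test = fractions
    by_image: dict[str, int] = {}
    img_patient: dict[str, str | None] = {}
    for r in records:
        prev = by_image.setdefault(r.source_image_id, r.label)
        if prev != r.label:
            raise ValueError(
                f"source image {r.source_image_id} has inconsistent labels")
        img_patient.setdefault(r.source_image_id, r.patient_id)
    use_patients = group_on_patient and all(
        p is not None for p in img_patient.values())
    classes: dict[int, list[str]] = {}
    for img, lab in by_image.items():
        classes.setdefault(lab if stratify else 0, []).append(img)
    n_buckets = sum(1 for f in fractions if f > 0)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for lab in sorted(classes):
        imgs = sorted(classes[lab])
        if len(imgs) < n_buckets:
            raise ValueError(
                f"class {lab} has {len(imgs)} images but the split has "
                f"{n_buckets} nonzero buckets")
        n = len(imgs)
        n_val = _round_half_down(f_val * n)
        n_test = _round_half_down(f_test * n)
        if not use_patients:
            rng.shuffle(imgs)
            units = [[img] for img in imgs]
        else:
            groups: dict[str, list[str]] = {}
            for img in imgs:
                groups.setdefault(str(img_patient[img]), []).append(img)
            keys = sorted(groups)
            rng.shuffle(keys)
            units = [groups[k] for k in keys]
        filled = {"val": 0, "test": 0}
        targets = {"val": n_val, "test": n_test}
        for unit in units:
            # fill val, then test, up to their targets; remainder to train
            for bucket in ("val", "test"):
                if filled[bucket] < targets[bucket]:
                    dest = bucket
                    break
            else:
                dest = "train"
            for img in unit:
                assignment[img] = dest
            if dest in filled:
                filled[dest] += len(unit)
    return [replace(r, split=assignment[r.source_image_id]) for r in records]


def patient_grouped_kfold(records: list[TileRecord], k: int,
                          seed: int, val_splits: int = 5) -> FoldPlan:
    """Two-stage patient-grouped stratified k-fold.

    Stage one partitions patients into ``k`` folds (each fold's items serve
    as that fold's test set); stage two sub-splits each remaining
    train+val pool with another patient-grouped stratified split, holding
    out 1/``val_splits`` of it for validation.  No patient ever appears in
    more than one of a fold's three parts.
    """
    if any(r.patient_id is None for r in records):
        raise ValueError(
            "patient_grouped_kfold requires a patient_id on every record; "
            "use image_level_split for datasets without patient metadata")
    groups = np.array([r.patient_id for r in records])
    labels = np.array([r.label for r in records])
    idx = np.arange(len(records))
    if k > len(set(groups)):
        raise ValueError(f"k={k} exceeds the {len(set(groups))} patients")
    outer = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    plan = FoldPlan(k=k)
    for trainval_idx, test_idx in outer.split(idx, labels, groups):
        inner = StratifiedGroupKFold(n_splits=val_splits, shuffle=True,
                                     random_state=seed)
        tr_rel, val_rel = next(iter(inner.split(
            trainval_idx, labels[trainval_idx], groups[trainval_idx])))
        plan.folds.append({
            "train": trainval_idx[tr_rel].tolist(),
            "val": trainval_idx[val_rel].tolist(),
            "test": test_idx.tolist(),
        })
    return plan


def audit_fold_plan(plan: FoldPlan, records: list[TileRecord]) -> dict:
    """Count patients shared between every fold pair (must all be 0) and
    report per-fold class proportions."""
    patients = [set(records[i].patient_id for i in parts["test"])
                for parts in plan.folds]
    overlaps = {}
    for a in range(plan.k):
        for b in range(a + 1, plan.k):
            overlaps[(a, b)] = len(patients[a] & patients[b])
    within = []
    for parts in plan.folds:
        tr = set(records[i].patient_id for i in parts["train"])
        va = set(records[i].patient_id for i in parts["val"])
        te = set(records[i].patient_id for i in parts["test"])
        within.append(len(tr & va) + len(tr & te) + len(va & te))
    all_labels = np.array([r.label for r in records])
    global_prop = {int(c): n / len(records)
                   for c, n in zip(*np.unique(all_labels,
                                              return_counts=True))}
    fold_props = []
    for parts in plan.folds:
        labs = all_labels[parts["test"]]
        fold_props.append({int(c): n / len(labs)
                           for c, n in zip(*np.unique(labs,
                                                      return_counts=True))})
    return {"pairwise_shared_patients": overlaps,
            "max_shared_patients": max(overlaps.values()) if overlaps else 0,
            "within_fold_shared_patients": within,
            "global_class_proportions": global_prop,
            "fold_class_proportions": fold_props}


def audit_split(records: list[TileRecord]) -> dict:
    """Verify no source image straddles splits and report subset counts."""
    by_image: dict[str, set] = {}
    counts: dict[str, int] = {}
    for r in records:
        by_image.setdefault(r.source_image_id, set()).add(r.split)
        counts[r.split] = counts.get(r.split, 0) + 1
    broken = [img for img, splits in by_image.items() if len(splits) > 1]
    return {"images_straddling_splits": broken, "counts": counts}


# -------------------------------------------------------------- augmentation

def sample_augment_params(policy: str, rng: np.random.Generator,
                          p_apply: float = 0.5,
                          jitter: float = 0.2,
                          blur_sigma_range: tuple = (0.1, 1.0)) -> dict:
    """Draw one augmentation configuration.

    ``bach``: flips, 90-degree rotations, brightness/contrast jitter
    (+-20%), Gaussian blur.  ``breakhis``: flips and continuous small-angle
    rotations within +-10 degrees.  ``geometric``: flips and 90-degree
    rotations only (photometry untouched; the default for synthetic
    fixtures).  Each transform fires with probability ``p_apply``.
    """
    if policy not in ("bach", "breakhis", "geometric"):
        raise ValueError(f"unknown augmentation policy: {policy!r}")
    params = {
        "policy": policy,
        "hflip": bool(rng.random() < p_apply),
        "vflip": bool(rng.random() < p_apply),
    }
    if policy in ("bach", "geometric"):
        params["rot90"] = int(rng.integers(0, 4)) \
            if rng.random() < p_apply else 0
    if policy == "bach":
        params["brightness"] = float(rng.uniform(-jitter, jitter)) \
            if rng.random() < p_apply else 0.0
        params["contrast"] = float(rng.uniform(-jitter, jitter)) \
            if rng.random() < p_apply else 0.0
        params["blur_sigma"] = float(rng.uniform(*blur_sigma_range)) \
            if rng.random() < p_apply else 0.0
    elif policy == "breakhis":
        params["angle"] = float(rng.uniform(-10.0, 10.0)) \
            if rng.random() < p_apply else 0.0
    return params


def apply_augment(tile: np.ndarray, params: dict) -> np.ndarray:
    """Apply a sampled augmentation; shape-preserving, label-free."""
    out = tile.astype(np.float32, copy=True)
    if params["hflip"]:
        out = out[:, ::-1]
    if params["vflip"]:
        out = out[::-1]
    if params.get("rot90"):
        out = np.rot90(out, k=params["rot90"], axes=(0, 1))
    if params["policy"] == "bach":
        if params["brightness"]:
            out = out + params["brightness"]
        if params["contrast"]:
            mean = out.mean(axis=(0, 1), keepdims=True)
            out = (out - mean) * (1.0 + params["contrast"]) + mean
        if params["blur_sigma"]:
            out = ndimage.gaussian_filter(
                out, sigma=(params["blur_sigma"], params["blur_sigma"], 0))
    elif params["policy"] == "breakhis":
        if params["angle"]:
            out = ndimage.rotate(out, params["angle"], axes=(1, 0),
                                 reshape=False, order=1, mode="reflect")
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def augment(tile: np.ndarray, policy: str,
            rng: np.random.Generator, **kwargs) -> np.ndarray:
    return apply_augment(tile, sample_augment_params(policy, rng, **kwargs))


# ------------------------------------------------------------------ manifest

def records_to_manifest(records: list[TileRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "image_path": r.image_path, "label": r.label,
            "patient_id": r.patient_id, "magnification": r.magnification,
            "source_image_id": r.source_image_id,
            "patch_row": r.patch_origin[0], "patch_col": r.patch_origin[1],
            "split": r.split, "is_synthetic": r.is_synthetic,
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def _truthy(value) -> bool:
    if pd.isna(value):
        return False
    return bool(value) and str(value).lower() not in ("false", "0")


def manifest_to_records(df: pd.DataFrame) -> list[TileRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(TileRecord(
            source_image_id=str(row.source_image_id), label=int(row.label),
            patch_origin=(int(row.patch_row), int(row.patch_col)),
            image_path=None if pd.isna(row.image_path) else str(row.image_path),
            patient_id=None if pd.isna(row.patient_id) else str(row.patient_id),
            magnification=None if pd.isna(row.magnification)
            else str(row.magnification),
            split=None if pd.isna(row.split) else str(row.split),
            is_synthetic=_truthy(getattr(row, "is_synthetic", False))))
    return records
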