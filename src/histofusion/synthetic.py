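"""Deterministic generator of histology-like labeled tiles.

Tiles emulate H&E-stained tissue statistically, not photographically: a
low-frequency eosin-pink background with nuclear-like hematoxylin blobs
(anti-aliased ellipses with hue jitter) concentrated in a per-tile "lesion"
region whose geometry follows the class layout.  Classes are built
factorially from a *local* cue (blob radius/density inside the lesion) and a
*global* cue (lesion layout: scattered foci, one compact cluster, a ring, or
a diagonal band), so that classes sharing a layout are separable only by
texture and classes sharing a texture only by arrangement — neither a purely
local nor a purely global feature extractor suffices for all classes.

Every tile is a pure function of ``(spec, seed, class_id, index)``.  Each
tile carries a binary lesion mask (area fraction drawn from
``lesion_fraction_range`` and enforced by construction via a quantile
threshold on the layout's distance field) for explainability scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .data import TileRecord

LAYOUTS = ("scattered", "clustered", "ring", "banded")

_EOSIN = np.array([0.91, 0.74, 0.83], np.float32)      # background stroma
_HEMATOXYLIN = np.array([0.36, 0.25, 0.55], np.float32)  # nuclei


@dataclass
class ClassRecipe:
    blob_radius: float            # mean nuclear radius, px
    blob_density: float           # blobs per 1000 px^2 of lesion area
    layout: str                   # one of LAYOUTS
    background_shift: float = 0.0  # additive hue shift of the stroma


@dataclass
class FixtureSpec:
    n_classes: int = 4
    tiles_per_class: int = 100
    tile_size: int = 96
    seed: int = 0
    class_recipes: list = field(default_factory=list)
    lesion_fraction_range: tuple = (0.15, 0.30)
    tiles_per_patient: int = 4

    def __post_init__(self):
        if not self.class_recipes:
            self.class_recipes = default_recipes(self.n_classes)
        if len(self.class_recipes) != self.n_classes:
            raise ValueError("one recipe per class required")
        validate_recipes(self.class_recipes)


def default_recipes(n_classes: int) -> list[ClassRecipe]:
    """Factorial local x global recipes: 2 textures x (2 or 4) layouts."""
    if n_classes not in (4, 8):
        raise ValueError("default recipes cover 4 or 8 classes")
    radii = (2.0, 3.0)
    # clustered vs ring differ in whether the tile's central region is
    # lesional — a positional cue a ViT resolves through its position
    # embeddings, while remaining invisible to a GAP-pooled CNN
    layouts = ("clustered", "ring") if n_classes == 4 else LAYOUTS
    recipes = []
    for r in radii:
        for lay in layouts:
            # density scaled to equal ~40% blob coverage of the lesion, so
            # texture classes differ in nuclear size/granularity rather
            # than in how legible the lesion region is
            recipes.append(ClassRecipe(blob_radius=r,
                                       blob_density=400.0 / (np.pi * r * r),
                                       layout=lay))
    return recipes


def validate_recipes(recipes: list[ClassRecipe]) -> None:
    """The recipe set must vary in both cue families: at least two distinct
    local settings and at least two distinct layouts."""
    locals_ = {(r.blob_radius, r.blob_density) for r in recipes}
    layouts = {r.layout for r in recipes}
    for r in recipes:
        if r.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {r.layout!r}")
    if len(recipes) > 1 and (len(locals_) < 2 or len(layouts) < 2):
        raise ValueError(
            "recipes must differ in at least one local (radius/density) and "
            "one global (layout) parameter across the class set")


@dataclass
class FixtureTile:
    pixels: np.ndarray            # (S, S, 3) float32 in [0, 1]
    label: int
    lesion_mask: np.ndarray       # (S, S) bool
    patient_id: str | None = None
    magnification: str | None = None
    n_blobs: int = 0              # lesion blob count (density audits)


def _layout_field(layout: str, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Scalar field whose low values trace the lesion geometry."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    if layout == "scattered":
        m = rng.integers(4, 7)
        cx = rng.uniform(0.1 * size, 0.9 * size, m)
        cy = rng.uniform(0.1 * size, 0.9 * size, m)
        d = np.min(np.sqrt((yy[..., None] - cy) ** 2
                           + (xx[..., None] - cx) ** 2), axis=-1)
        return d
    if layout == "clustered":
        cy = rng.uniform(0.35 * size, 0.65 * size)
        cx = rng.uniform(0.35 * size, 0.65 * size)
        return np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    if layout == "ring":
        cy = rng.uniform(0.4 * size, 0.6 * size)
        cx = rng.uniform(0.4 * size, 0.6 * size)
        r0 = rng.uniform(0.26, 0.30) * size
        return np.abs(np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) - r0)
    if layout == "banded":
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(-0.15, 0.15) * size
        n = (np.cos(theta), np.sin(theta))
        return np.abs((yy - size / 2) * n[0] + (xx - size / 2) * n[1]
                      - offset)
    raise ValueError(f"unknown layout {layout!r}")


def _paint_blobs(pixels: np.ndarray, mask: np.ndarray, radius: float,
                 density: float, rng: np.random.Generator) -> int:
    size = pixels.shape[0]
    area = float(mask.sum())
    n = int(rng.poisson(density * area / 1000.0))
    ys, xs = np.nonzero(mask)
    if len(ys) == 0 or n == 0:
        return 0
    picks = rng.integers(0, len(ys), n)
    for p in picks:
        cy = ys[p] + rng.uniform(-1, 1)
        cx = xs[p] + rng.uniform(-1, 1)
        ry = max(radius * rng.normal(1.0, 0.25), 0.8)
        rx = max(radius * rng.normal(1.0, 0.25), 0.8)
        color = np.clip(_HEMATOXYLIN + rng.normal(0, 0.04, 3), 0, 1) \
            .astype(np.float32)
        y0, y1 = int(max(cy - ry - 2, 0)), int(min(cy + ry + 3, size))
        x0, x1 = int(max(cx - rx - 2, 0)), int(min(cx + rx + 3, size))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
        d = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        alpha = np.clip(1.0 - (d - 1.0) / 0.6, 0.0, 1.0)[..., None]
        pixels[y0:y1, x0:x1] = (1 - alpha) * pixels[y0:y1, x0:x1] \
            + alpha * color
    return n


def generate_tile(spec: FixtureSpec, class_id: int,
                  index: int) -> FixtureTile:
    """Render one tile; fully determined by ``(spec.seed, class_id, index)``."""
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} outside 0..{spec.n_classes-1}")
    recipe: ClassRecipe = spec.class_recipes[class_id]
    rng = np.random.default_rng([spec.seed, class_id, index])
    S = spec.tile_size

    # stroma background: low-frequency eosin field + fine grain
    coarse = rng.normal(0, 1, (6, 6, 3)).astype(np.float32)
    lowfreq = ndimage.zoom(coarse, (S / 6, S / 6, 1), order=1) * 0.04
    pixels = np.clip(_EOSIN + recipe.background_shift + lowfreq
                     + rng.normal(0, 0.012, (S, S, 3)).astype(np.float32),
                     0, 1).astype(np.float32)

    # lesion region: quantile-threshold the layout field so the mask area
    # fraction equals the drawn target exactly (up to pixel ties)
    target = rng.uniform(*spec.lesion_fraction_range)
    field_vals = _layout_field(recipe.layout, S, rng)
    mask = field_vals <= np.quantile(field_vals, target)

    # desmoplastic-like stroma darkening inside the lesion: makes the region
    # geometry legible to patch tokens while carrying no class signal for a
    # globally pooled extractor (lesion area is class-independent)
    pixels[mask] *= 0.82

    n_blobs = _paint_blobs(pixels, mask, recipe.blob_radius,
                           recipe.blob_density, rng)
    # sparse benign nuclei outside the lesion
    _paint_blobs(pixels, ~mask, recipe.blob_radius * 0.8,
                 recipe.blob_density * 0.08, rng)
    return FixtureTile(pixels=pixels, label=class_id,
                       lesion_mask=mask, n_blobs=n_blobs)


def generate_dataset(spec: FixtureSpec, out_dir=None,
                     magnification_tags: bool = False,
                     assign_patients: bool = True):
    """Generate the full fixture set.

    Tiles are grouped into synthetic patients (``spec.tiles_per_patient``
    consecutive tiles per patient, patients never crossing classes) so the
    grouped k-fold machinery can be exercised.  With ``out_dir`` set, writes
    PNG tiles, mask PNGs, and a CSV manifest; always returns
    ``(records, tiles)`` where ``records`` align with the manifest rows.
    """
    records: list[TileRecord] = []
    tiles: list[FixtureTile] = []
    mags = ("40x", "100x", "200x", "400x")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    patient = 0
    for c in range(spec.n_classes):
        for i in range(spec.tiles_per_class):
            tile = generate_tile(spec, c, i)
            if assign_patients:
                tile.patient_id = f"P{patient:04d}"
            if magnification_tags:
                tile.magnification = mags[i % len(mags)]
            if (i + 1) % spec.tiles_per_patient == 0:
                patient += 1
            name = f"c{c}_t{i:04d}"
            rec = TileRecord(source_image_id=name, label=c,
                             patch_origin=(0, 0), patch_size=spec.tile_size,
                             patient_id=tile.patient_id,
                             magnification=tile.magnification,
                             pixels=tile.pixels)
            if out_dir is not None:
                img_path = out_dir / f"{name}.png"
                iio.imwrite(img_path,
                            (tile.pixels * 255).round().astype(np.uint8))
                iio.imwrite(out_dir / f"{name}_mask.png",
                            tile.lesion_mask.astype(np.uint8) * 255)
                rec.image_path = str(img_path)
            records.append(rec)
            tiles.append(tile)
        patient += 1  # patients never straddle classes
    if out_dir is not None:
        from .data import records_to_manifest
        records_to_manifest(records).to_csv(out_dir / "manifest.csv",
                                            index=False)
    return records, tiles


def as_arrays(tiles: list[FixtureTile]):
    """Stack tiles into (N, 3, S, S) images in [0,1] and (N,) labels."""
    X = np.stack([t.pixels.transpose(2, 0, 1) for t in tiles])
    y = np.array([t.label for t in tiles], np.int64)
    return X.astype(np.float32), y
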