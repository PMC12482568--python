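"""Multi-layer Grad-CAM explanations for the CNN branch.

For a registered backbone layer k with activations A^(k), the channel
weights are the spatially averaged gradients of the pre-softmax class score
y^c, and the per-layer map is the rectified weighted sum

    alpha_i = mean_hw  d y^c / d A_i[h, w],      L^(k) = ReLU(sum_i alpha_i A_i).

Maps from several layers are bilinearly resized to a common size, averaged
with equal weights, and min-max normalized to [0, 1]; the normalized map is
colorized through a jet-like lookup table and alpha-blended onto the tile:

    Overlay = Image * (1 - alpha) + Heatmap * alpha.

Localization quality against a binary lesion mask is scored as the IoU
between the mask and the top-q quantile region of the fused map; for two
independent random sets with area fractions p and m the expected IoU is
p*m / (p + m - p*m), which serves as the chance baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass
class ClassActivationMap:
    map: np.ndarray            # (h, w) nonnegative; fused maps lie in [0, 1]
    layer_id: str
    class_id: int


def layer_cam(model, image: np.ndarray, layer_id: str,
              class_id: int | None = None) -> ClassActivationMap:
    """Grad-CAM for one tile at one registered backbone layer.

    ``image`` is (3, S, S) in [0, 1].  ``class_id=None`` explains the
    predicted class; gradients are taken w.r.t. the pre-softmax score.
    """
    known = model.cam_layer_names()
    if layer_id not in known:
        raise KeyError(f"unknown CAM layer {layer_id!r}; registered layers: "
                       f"{known}")
    model.eval()
    model.zero_grad()
    logits = model.logits(image[None], record_cams=True)
    if class_id is None:
        class_id = int(logits.data[0].argmax())
    score = logits[0, class_id]
    score.backward()
    act = model.cnn.backbone.activations[layer_id]
    A = act.data[0]                       # (C, h, w)
    G = act.grad[0]
    alpha = G.mean(axis=(1, 2))           # spatial GAP of gradients
    cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    return ClassActivationMap(map=cam.astype(np.float32),
                              layer_id=layer_id, class_id=class_id)


def fuse_cams(cams: list[ClassActivationMap],
              target_size: tuple) -> ClassActivationMap:
    """Resize each map bilinearly to ``target_size``, average with equal
    weights, then min-max normalize to [0, 1].  A constant fused map has no
    range to normalize; it is returned as all-zeros with a warning."""
    if not cams:
        raise ValueError("fuse_cams needs at least one map")
    resized = [_sk_resize(c.map.astype(np.float64), target_size, order=1,
                          preserve_range=True, anti_aliasing=False,
                          mode="edge")
               for c in cams]
    fused = np.mean(resized, axis=0)
    lo, hi = float(fused.min()), float(fused.max())
    if hi - lo < 1e-12:
        warnings.warn("fused CAM has degenerate (zero) range; returning "
                      "an all-zero map")
        fused = np.zeros_like(fused)
    else:
        fused = (fused - lo) / (hi - lo)
    return ClassActivationMap(map=fused.astype(np.float32),
                              layer_id="+".join(c.layer_id for c in cams),
                              class_id=cams[0].class_id)


def explain(model, image: np.ndarray, class_id: int | None = None,
            layers: list[str] | None = None) -> ClassActivationMap:
    """Fused multi-layer Grad-CAM at image resolution."""
    layers = layers or model.default_cam_layers()
    cams = [layer_cam(model, image, lid, class_id) for lid in layers]
    return fuse_cams(cams, image.shape[1:])


def jet_colormap(values: np.ndarray) -> np.ndarray:
    """Piecewise-linear jet-like lookup table (documented for
    bit-reproducibility): for x in [0,1],
    R = clip(1.5 - |4x - 3|), G = clip(1.5 - |4x - 2|),
    B = clip(1.5 - |4x - 1|)."""
    x = np.asarray(values, np.float32)
    r = np.clip(1.5 - np.abs(4 * x - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * x - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * x - 1), 0, 1)
    return np.stack([r, g, b], axis=-1)


def overlay(image: np.ndarray, cam: ClassActivationMap, alpha: float = 0.5,
            colormap=jet_colormap) -> np.ndarray:
    """Convex combination of the tile and the colorized heatmap in [0, 1]
    pixel space; ``alpha=0`` returns the image, ``alpha=1`` the heatmap."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    img = np.asarray(image, np.float32)
    if img.ndim == 3 and img.shape[0] == 3 and img.shape[-1] != 3:
        img = img.transpose(1, 2, 0)      # accept CHW tiles
    if img.shape[:2] != cam.map.shape:
        raise ValueError(f"image {img.shape[:2]} and CAM {cam.map.shape} "
                         "sizes differ")
    heat = colormap(cam.map)
    return img * (1.0 - alpha) + heat * alpha


def localization_score(cam: ClassActivationMap, lesion_mask: np.ndarray,
                       q: float = 0.2) -> float:
    """IoU between the top-``q`` quantile region of the CAM and the mask."""
    mask = np.asarray(lesion_mask).astype(bool)
    if mask.shape != cam.map.shape:
        raise ValueError("mask and CAM sizes differ")
    if not mask.any():
        raise ValueError("lesion mask is empty; localization undefined")
    thresh = np.quantile(cam.map, 1.0 - q)
    region = cam.map >= thresh
    inter = np.logical_and(region, mask).sum()
    union = np.logical_or(region, mask).sum()
    return float(inter / union)


def random_baseline_iou(p: float, m: float) -> float:
    """Expected IoU of two independent random regions with area fractions
    ``p`` and ``m`` (closed form)."""
    return p * m / (p + m - p * m)
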