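"""Grad-CAM heat maps for the age-range classifier.

For a class ``c`` with pre-softmax score ``y^c``, each channel ``k`` of the
last convolutional stage output ``A`` receives the weight

    alpha_k^c = (1/Z) * sum_ij  d y^c / d A_ij^k

(the spatial mean of the backpropagated score gradient over the Z = H x W
feature positions), and the map is the ReLU-rectified weighted channel sum
``L^c = ReLU(sum_k alpha_k^c A^k)``. The map is bilinearly upsampled to the
50x200 fused-image frame and min-max normalized for overlay; regions the
model relies on for class ``c`` glow red in the blended image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._interp import resize_bilinear
from .age_cnn import AgeRangeCNN
from .roi import ROI_COLS, ROI_ROWS

__all__ = ["HeatMap", "gradcam_map", "overlay"]


@dataclass
class HeatMap:
    """Channel weights, raw feature-resolution map, and the 50x200 overlay map."""

    weights: np.ndarray          # alpha_k^c, one per feature channel
    map: np.ndarray              # L^c at feature-layer resolution, >= 0
    upsampled: np.ndarray        # bilinear upsample of L^c to 50x200, in [0, 1]
    class_c: int
    score: float                 # pre-softmax y^c


def gradcam_map(model: AgeRangeCNN, img: np.ndarray, class_c: int) -> HeatMap:
    """Grad-CAM map of one 50x200 8-bit image for target class ``class_c``."""
    if not (0 <= class_c < model.spec.n_classes):
        raise ValueError(f"class {class_c} out of range 0..{model.spec.n_classes - 1}")
    img = np.asarray(img)
    if img.shape != tuple(model.spec.input_shape):
        raise ValueError(f"expected {model.spec.input_shape} image, got {img.shape}")

    model.set_train(False)
    x = AgeRangeCNN.prepare(img)
    logits = model.forward(x)  # caches the feature layer
    score = float(logits[0, class_c])
    dlogits = np.zeros_like(logits)
    dlogits[0, class_c] = 1.0  # d y^c / d logits: the raw score, no softmax
    model.zero_grad()
    dfeat = model.backward(dlogits, to_feature_only=True)  # (1, K, h, w)
    feat = model._feature[0]       # A^k
    grads = dfeat[0]               # d y^c / d A^k

    alpha = grads.mean(axis=(1, 2))                     # 1/Z sum_ij
    raw = np.tensordot(alpha, feat, axes=(0, 0))        # sum_k alpha_k A^k
    raw = np.maximum(raw, 0.0)                          # ReLU
    up = resize_bilinear(raw, (ROI_ROWS, ROI_COLS))
    up = np.maximum(up, 0.0)
    if up.max() > 0:
        up = (up - up.min()) / (up.max() - up.min())
    return HeatMap(weights=alpha, map=raw, upsampled=up, class_c=class_c, score=score)


def overlay(heat: HeatMap, img: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a red-intensity rendering of the heat map onto the gray image.

    A zero map returns the pure grayscale image as RGB; hotter pixels shift
    toward saturated red proportionally to ``alpha * heat``.
    """
    img = np.asarray(img, dtype=np.float64)
    h = heat.upsampled
    if h.shape != img.shape:
        raise ValueError(f"heat map {h.shape} does not align with image {img.shape}")
    w = alpha * h
    rgb = np.empty(img.shape + (3,), dtype=np.float64)
    rgb[..., 0] = img * (1 - w) + 255.0 * w   # red channel pulled up
    rgb[..., 1] = img * (1 - w)
    rgb[..., 2] = img * (1 - w)
    return np.rint(np.clip(rgb, 0, 255)).astype(np.uint8)


def heat_mass_fraction(heat: HeatMap, row_lo: int, row_hi: int) -> float:
    """Fraction of total heat mass inside rows [row_lo, row_hi) of the overlay map."""
    total = float(heat.upsampled.sum())
    if total == 0:
        return 0.0
    return float(heat.upsampled[row_lo:row_hi].sum()) / total
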