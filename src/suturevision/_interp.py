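"""Bilinear resampling with a pixel-centre grid convention.

Output sample ``j`` of an axis resized from ``n_src`` to ``n_out`` is taken
at source coordinate ``(j + 0.5) * n_src / n_out - 0.5``, clamped to the
frame; values are bilinearly interpolated. Bilinear weights are convex, so
resampling can never overshoot the source value range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _axis_coords(n_src: int, n_out: int) -> np.ndarray:
    scale = n_src / n_out
    c = (np.arange(n_out) + 0.5) * scale - 0.5
    return np.clip(c, 0.0, n_src - 1.0)


def resize_bilinear(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resize a 2-D array to ``out_shape`` (rows, cols), returning float64."""
    img = np.asarray(img, dtype=np.float64)
    rr = _axis_coords(img.shape[0], out_shape[0])
    cc = _axis_coords(img.shape[1], out_shape[1])
    grid = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(img, grid, order=1, mode="nearest")
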