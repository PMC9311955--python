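"""Extraction of the normalized 50x200 midpalatal-suture ROI.

For every labeled axial slice, a window centred transversely on the
midsagittal line is cropped (50 px across the suture) over the labeled
anterior-posterior extent, and the anterior-posterior axis is resampled to a
fixed 200 px so every scan yields same-sized ROI images regardless of palate
length. The output is oriented with the transverse direction along rows and
anterior at column 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._interp import resize_bilinear
from .volume_io import RoiBoundaries, VolumeGrid, write_png

ROI_ROWS = 50   # transverse width across the suture (cropped exactly)
ROI_COLS = 200  # anterior-posterior length (resampled)

__all__ = ["SliceStack", "extract_roi", "export_roi_pngs", "ROI_ROWS", "ROI_COLS"]


@dataclass
class SliceStack:
    """Ordered per-slice ROI images for one scan, each exactly 50x200 8-bit."""

    images: list[np.ndarray]
    subject_id: str

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("SliceStack needs at least one image")
        for k, im in enumerate(self.images):
            if im.shape != (ROI_ROWS, ROI_COLS):
                raise ValueError(
                    f"slice {k}: ROI must be {ROI_ROWS}x{ROI_COLS}, got {im.shape}"
                )
        self.images = [np.asarray(im, dtype=np.uint8) for im in self.images]

    @property
    def n_slices(self) -> int:
        return len(self.images)


def extract_roi(volume: VolumeGrid, bounds: RoiBoundaries) -> SliceStack:
    """Crop and length-normalize the suture ROI from each labeled slice.

    The transverse window spans 50 columns centred on ``midline_px``; the
    anterior-posterior span ``[anterior_px, posterior_px)`` is resampled to
    200 samples with bilinear interpolation. Output rows are transverse,
    columns anterior->posterior with anterior at column 0.
    """
    if bounds.lower_slice > volume.n_axial:
        raise ValueError(
            f"{bounds.subject_id}: lower_slice {bounds.lower_slice} exceeds "
            f"volume depth {volume.n_axial}"
        )
    half = ROI_ROWS // 2
    c0 = bounds.midline_px - half
    c1 = c0 + ROI_ROWS
    if c0 < 0 or c1 > volume.voxels.shape[2]:
        raise ValueError(
            f"{bounds.subject_id}: transverse crop [{c0}, {c1}) exceeds the "
            f"512x512 frame (midline_px={bounds.midline_px})"
        )
    images = []
    for z in range(bounds.upper_slice, bounds.lower_slice):
        sl = volume.voxels[z]
        # rows = anterior-posterior extent, cols = transverse window
        patch = sl[bounds.anterior_px : bounds.posterior_px, c0:c1]
        # reorient: transverse along rows, anterior at column 0
        patch = patch.T.astype(np.float64)
        out = resize_bilinear(patch, (ROI_ROWS, ROI_COLS))
        images.append(np.rint(np.clip(out, 0, 255)).astype(np.uint8))
    return SliceStack(images=images, subject_id=bounds.subject_id)


def export_roi_pngs(stack: SliceStack, out_dir: str | Path) -> list[Path]:
    """Write one PNG per slice for expert review (subject_sliceNNN.png)."""
    out = []
    for k, im in enumerate(stack.images):
        out.append(write_png(im, Path(out_dir) / f"{stack.subject_id}_slice{k:03d}.png"))
    return out
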