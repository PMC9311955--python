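"""Age-range labels, image augmentation, and train/validation/test splits.

Chronological age in months maps to five range labels:
4-10 y -> 0, 11-12 y -> 1, 13-14 y -> 2, 15-16 y -> 3, 17-23 y -> 4.

Training images are expanded by small random translation, tilt, contrast
and brightness adjustment, cropping and horizontal mirroring, then
renormalized to 50x200. Splits take a fixed per-class quota into the
validation and test sets (10 and 20 by default, i.e. 50 and 100 images for
five classes) and leave the remainder for training; selection is seeded,
stratified, and grouped so repeat scans of one participant never straddle
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._interp import resize_bilinear
from .roi import ROI_COLS, ROI_ROWS
from .volume_io import AGE_MONTHS_MAX, AGE_MONTHS_MIN, RoiBoundaries

__all__ = [
    "AGE_RANGE_BOUNDS_YEARS",
    "AugmentationPolicy",
    "label_of",
    "label_name",
    "augment",
    "make_splits",
    "N_CLASSES",
]

N_CLASSES = 5

# label -> inclusive [lo, hi] bounds in whole years
AGE_RANGE_BOUNDS_YEARS = {0: (4, 10), 1: (11, 12), 2: (13, 14), 3: (15, 16), 4: (17, 23)}


def label_of(age_months: int) -> int:
    """Five-class age-range label for an age in months (floor to whole years)."""
    if not (AGE_MONTHS_MIN <= age_months < AGE_MONTHS_MAX):
        raise ValueError(
            f"age_months {age_months} outside the study range "
            f"[{AGE_MONTHS_MIN}, {AGE_MONTHS_MAX})"
        )
    years = age_months // 12
    for lab, (lo, hi) in AGE_RANGE_BOUNDS_YEARS.items():
        if lo <= years <= hi:
            return lab
    raise AssertionError("unreachable: bounds cover the study range")


def label_name(label: int) -> str:
    lo, hi = AGE_RANGE_BOUNDS_YEARS[label]
    return f"{lo}-{hi} years old"


@dataclass
class AugmentationPolicy:
    """Magnitudes of the six small-amplitude training-set transforms.

    Fractions are of image extent (translate, crop) or intensity
    (contrast/brightness); tilt is in degrees. All default to the "small
    amplitude" regime (<= 10%).
    """

    translate_frac: float = 0.05
    tilt_deg: float = 5.0
    contrast_frac: float = 0.10
    brightness_frac: float = 0.10
    crop_frac: float = 0.05
    hflip_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("translate_frac", "tilt_deg", "contrast_frac", "brightness_frac", "crop_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.hflip_prob <= 1.0):
            raise ValueError("hflip_prob must lie in [0, 1]")

    @property
    def identity(self) -> bool:
        return (
            self.translate_frac == 0
            and self.tilt_deg == 0
            and self.contrast_frac == 0
            and self.brightness_frac == 0
            and self.crop_frac == 0
            and self.hflip_prob == 0
        )


def augment(img: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to a 50x200 image.

    Deterministic given the generator state. The all-zero policy is the
    identity; hflip alone is an involution (exact column reversal).
    """
    img = np.asarray(img)
    if img.shape != (ROI_ROWS, ROI_COLS):
        raise ValueError(f"expected {ROI_ROWS}x{ROI_COLS} image, got {img.shape}")
    out = img.astype(np.float64)

    if policy.translate_frac > 0:
        # whole-pixel shifts keep the transform exactly invertible at the edges
        mr = int(round(policy.translate_frac * ROI_ROWS))
        mc = int(round(policy.translate_frac * ROI_COLS))
        dr = int(rng.integers(-mr, mr + 1))
        dc = int(rng.integers(-mc, mc + 1))
        if dr or dc:
            out = ndimage.shift(out, (dr, dc), order=0, mode="nearest")
    if policy.tilt_deg > 0:
        ang = rng.uniform(-policy.tilt_deg, policy.tilt_deg)
        out = ndimage.rotate(out, ang, reshape=False, order=1, mode="nearest")
    if policy.contrast_frac > 0:
        gain = 1.0 + rng.uniform(-policy.contrast_frac, policy.contrast_frac)
        out = (out - out.mean()) * gain + out.mean()
    if policy.brightness_frac > 0:
        out = out + rng.uniform(-policy.brightness_frac, policy.brightness_frac) * 255.0
    if policy.crop_frac > 0:
        cr = int(round(rng.uniform(0, policy.crop_frac) * ROI_ROWS))
        cc = int(round(rng.uniform(0, policy.crop_frac) * ROI_COLS))
        if cr or cc:
            out = out[cr : ROI_ROWS - cr or None, cc : ROI_COLS - cc or None]
            out = resize_bilinear(out, (ROI_ROWS, ROI_COLS))
    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        out = out[:, ::-1]
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def _quota_pick(
    class_parts: dict[str, int],
    quota: int,
    rng: np.random.Generator,
) -> list[str] | None:
    """Pick participants whose scan counts sum exactly to ``quota``.

    ``class_parts`` maps participant id -> number of scans, all in one
    class. A subset-sum table over the (shuffled) participants finds an
    exact combination whenever one exists; returns None otherwise.
    """
    pids = list(class_parts)
    rng.shuffle(pids)
    # reachable[s] = index of the participant whose inclusion first reached
    # sum s (walking pids in order), for backtracking
    reached: dict[int, tuple[int, int]] = {0: (-1, 0)}  # sum -> (pid index, prev sum)
    for i, pid in enumerate(pids):
        c = class_parts[pid]
        updates = {}
        for s in reached:
            t = s + c
            if t <= quota and t not in reached:
                updates[t] = (i, s)
        reached.update(updates)
        if quota in reached:
            break
    if quota not in reached:
        return None
    chosen = []
    s = quota
    while s:
        i, prev = reached[s]
        chosen.append(pids[i])
        s = prev
    return chosen


def make_splits(
    records: list[RoiBoundaries],
    val_per_class: int = 10,
    test_per_class: int = 20,
    seed: int = 0,
) -> dict[str, list[int]]:
    """Grouped, stratified train/validation/test split of label records.

    Returns index lists into ``records`` for keys "train", "val", "test".
    Validation and test receive exactly ``val_per_class`` and
    ``test_per_class`` scans per age-range label, drawn from participants
    whose scans all carry that label; everything else trains. No participant
    appears in more than one split.
    """
    rng = np.random.default_rng(seed)
    labels = [label_of(r.age_months) for r in records]

    # participant -> per-class scan counts
    from collections import Counter, defaultdict

    by_pid: dict[str, Counter] = defaultdict(Counter)
    for r, lab in zip(records, labels):
        by_pid[r.participant_id][lab] += 1

    taken: set[str] = set()
    split_pids: dict[str, set[str]] = {"val": set(), "test": set()}
    for split, quota in (("val", val_per_class), ("test", test_per_class)):
        for lab in range(N_CLASSES):
            pure = {
                pid: cnt[lab]
                for pid, cnt in by_pid.items()
                if pid not in taken and set(cnt) == {lab}
            }
            if sum(pure.values()) < quota:
                raise ValueError(
                    f"class {lab} too small: {sum(pure.values())} eligible scans "
                    f"for a {split} quota of {quota}"
                )
            chosen = _quota_pick(pure, quota, rng)
            if chosen is None:
                raise ValueError(
                    f"class {lab}: cannot meet the {split} quota of {quota} "
                    "without splitting a participant"
                )
            split_pids[split].update(chosen)
            taken.update(chosen)

    out: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for i, r in enumerate(records):
        if r.participant_id in split_pids["val"]:
            out["val"].append(i)
        elif r.participant_id in split_pids["test"]:
            out["test"].append(i)
        else:
            out["train"].append(i)
    return out
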