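"""Reading and writing CBCT volumes, boundary labels and derived images.

A CBCT scan is handled as a 3-D stack of axial slices, windowed to 8-bit
gray. Two on-disk forms are supported: a DICOM series directory (clinical
source data, read-only) and a portable ``.npz`` container (read/write, used
for fixtures and phantom output). Expert boundary labels travel in a flat
CSV with one row per scan.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "RoiBoundaries",
    "IngestionError",
    "LabelValidationError",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "write_png",
    "read_png",
    "AGE_MONTHS_MIN",
    "AGE_MONTHS_MAX",
]

# Study age range: 4 to 23 years old inclusive.
AGE_MONTHS_MIN = 48
AGE_MONTHS_MAX = 288  # exclusive

IN_PLANE = 512  # axial in-plane resolution after resampling


class IngestionError(RuntimeError):
    """A volume could not be read (missing/corrupt slices, bad container)."""


class LabelValidationError(ValueError):
    """A label row violates the schema or a domain invariant."""


@dataclass
class VolumeGrid:
    """A CBCT volume as an 8-bit gray voxel grid.

    Axes are ``(axial, row, col)``: index 0 walks the axial stack, rows run
    anterior->posterior in-plane, columns run transversely. Values are the
    windowed gray levels in [0, 255].
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        n_axial, h, w = self.voxels.shape
        if n_axial < 1:
            raise ValueError("volume must contain at least one axial slice")
        if (h, w) != (IN_PLANE, IN_PLANE):
            raise ValueError(
                f"in-plane resolution must be {IN_PLANE}x{IN_PLANE}, got {h}x{w}"
            )
        if self.voxels.dtype != np.uint8:
            if self.voxels.min() < 0 or self.voxels.max() > 255:
                raise ValueError("non-uint8 voxels must already lie in [0, 255]")
            self.voxels = self.voxels.astype(np.uint8)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm entries must be positive")

    @property
    def n_axial(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class RoiBoundaries:
    """Expert label record delimiting the midpalatal-suture ROI in a volume.

    ``upper_slice``/``lower_slice`` bound the axial extent (half-open,
    0-based), ``anterior_px``/``posterior_px`` the anterior-posterior extent
    in-plane (row indices, half-open), and ``midline_px`` marks the
    midsagittal column. ``age_months``/``sex`` are the subject covariates
    used downstream.
    """

    subject_id: str
    upper_slice: int
    lower_slice: int
    anterior_px: int
    posterior_px: int
    midline_px: int
    age_months: int
    sex: str
    participant_id: str = ""

    def __post_init__(self) -> None:
        if not self.participant_id:
            self.participant_id = self.subject_id
        if not (0 <= self.upper_slice < self.lower_slice):
            raise LabelValidationError(
                f"{self.subject_id}: need 0 <= upper_slice < lower_slice, "
                f"got [{self.upper_slice}, {self.lower_slice})"
            )
        if not (0 <= self.anterior_px < self.posterior_px <= IN_PLANE):
            raise LabelValidationError(
                f"{self.subject_id}: need 0 <= anterior_px < posterior_px <= "
                f"{IN_PLANE}, got [{self.anterior_px}, {self.posterior_px})"
            )
        if not (0 <= self.midline_px < IN_PLANE):
            raise LabelValidationError(
                f"{self.subject_id}: midline_px {self.midline_px} outside frame"
            )
        if not (AGE_MONTHS_MIN <= self.age_months < AGE_MONTHS_MAX):
            raise LabelValidationError(
                f"{self.subject_id}: age_months {self.age_months} outside the "
                f"study range [{AGE_MONTHS_MIN}, {AGE_MONTHS_MAX})"
            )
        if self.sex not in ("F", "M"):
            raise LabelValidationError(
                f"{self.subject_id}: unknown sex code {self.sex!r} (expected F or M)"
            )

    @property
    def n_slices(self) -> int:
        return self.lower_slice - self.upper_slice


def _window_to_uint8(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale raw intensities to [0, 255].

    A constant volume has a degenerate window and maps to all zeros.
    Rescaling is monotone, so voxel order statistics are preserved.
    """
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.uint8)
    scaled = (raw - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def _read_dicom_series(path: Path, subject_id: str) -> VolumeGrid:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise IngestionError(f"no DICOM slices found under {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
            arr = ds.pixel_array
        except Exception as exc:  # corrupt slice: name it
            raise IngestionError(f"corrupt or unreadable DICOM slice {f.name}: {exc}") from exc
        ipp = getattr(ds, "ImagePositionPatient", None)
        z = float(ipp[2]) if ipp is not None else None
        inst = int(getattr(ds, "InstanceNumber", 0))
        slices.append((z, inst, arr, ds, f.name))
    # Sort by axial position; fall back to InstanceNumber when positions absent.
    if all(s[0] is not None for s in slices):
        slices.sort(key=lambda s: s[0])
        zs = np.array([s[0] for s in slices])
        if len(zs) > 2:
            steps = np.diff(zs)
            if np.ptp(steps) > 1e-3:
                warnings.warn(
                    f"{subject_id}: non-uniform axial slice spacing "
                    f"(range {steps.min():.4f}..{steps.max():.4f} mm); proceeding",
                    stacklevel=3,
                )
    else:
        slices.sort(key=lambda s: s[1])
    shapes = {s[2].shape for s in slices}
    if len(shapes) != 1:
        raise IngestionError(f"{subject_id}: inconsistent slice shapes {shapes}")
    raw = np.stack([s[2] for s in slices]).astype(np.float64)
    ds0 = slices[0][3]
    px = getattr(ds0, "PixelSpacing", [0.3, 0.3])
    dz = float(getattr(ds0, "SliceThickness", 0.3))
    return VolumeGrid(
        voxels=_window_to_uint8(raw),
        spacing_mm=(dz, float(px[0]), float(px[1])),
        subject_id=subject_id,
    )


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a CBCT volume from a DICOM series directory or ``.npz`` container.

    Raw intensities are min-max rescaled per volume to 8-bit gray. Already
    8-bit containers round-trip bit-identically (the window [0, 255] maps to
    itself).
    """
    path = Path(path)
    subject_id = path.stem if path.suffix else path.name
    if path.is_dir():
        return _read_dicom_series(path, subject_id)
    if path.suffix == ".npz":
        try:
            with np.load(path, allow_pickle=False) as z:
                raw = z["voxels"]
                spacing = tuple(float(s) for s in z["spacing_mm"]) if "spacing_mm" in z else (0.3, 0.3, 0.3)
                sid = str(z["subject_id"]) if "subject_id" in z else subject_id
        except Exception as exc:
            raise IngestionError(f"cannot read container {path}: {exc}") from exc
        # already-windowed 8-bit data round-trips bit-identically
        voxels = raw if raw.dtype == np.uint8 else _window_to_uint8(raw)
        return VolumeGrid(voxels=voxels, spacing_mm=spacing, subject_id=sid)
    raise IngestionError(f"unsupported volume source: {path}")


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> Path:
    """Write a volume to the portable ``.npz`` container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        voxels=vol.voxels,
        spacing_mm=np.asarray(vol.spacing_mm, dtype=np.float64),
        subject_id=np.str_(vol.subject_id),
    )
    return path


LABEL_COLUMNS = [
    "subject_id",
    "upper_slice",
    "lower_slice",
    "anterior_px",
    "posterior_px",
    "midline_px",
    "age_months",
    "sex",
]


def read_labels(path: str | os.PathLike) -> list[RoiBoundaries]:
    """Read boundary-label records from CSV, one per scan.

    Rows violating a domain invariant are rejected with their (1-based data)
    row number in the error message. An optional ``participant_id`` column
    groups repeat scans of one person.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "participant_id": str})
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise LabelValidationError(f"labels file {path} missing columns: {missing}")
    records: list[RoiBoundaries] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                RoiBoundaries(
                    subject_id=str(row.subject_id),
                    upper_slice=int(row.upper_slice),
                    lower_slice=int(row.lower_slice),
                    anterior_px=int(row.anterior_px),
                    posterior_px=int(row.posterior_px),
                    midline_px=int(row.midline_px),
                    age_months=int(row.age_months),
                    sex=str(row.sex),
                    participant_id=str(getattr(row, "participant_id", "") or ""),
                )
            )
        except (LabelValidationError, ValueError) as exc:
            raise LabelValidationError(f"row {i}: {exc}") from exc
    return records


def write_labels(records: list[RoiBoundaries], path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                **{c: getattr(r, c) for c in LABEL_COLUMNS},
                "participant_id": r.participant_id,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return path


def write_png(img: np.ndarray, path: str | os.PathLike) -> Path:
    """Write an 8-bit grayscale (or RGB) image as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))
    return path


def read_png(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(iio.imread(path))
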