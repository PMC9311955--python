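"""GLCM texture features of fused suture images and their relation to age.

Six features are computed from the gray-level co-occurrence matrix (GLCM):
correlation, contrast, homogeneity, dissimilarity, angular second moment
(ASM) and energy (= sqrt(ASM)). Co-occurrences are counted at a fixed pixel
offset for four angles, symmetrized and normalized; features are averaged
over the angles for rotation robustness. As the midpalatal suture ossifies
its gray level approaches the surrounding bone, the fused image becomes
more uniform, and homogeneity and correlation rise — the trend quantified
per sex against chronological age by ``age_feature_report``.

The matrices and feature sums themselves are delegated to scikit-image
(``graycomatrix``/``graycoprops``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix, graycoprops

__all__ = [
    "GlcmParams",
    "TextureVector",
    "glcm",
    "texture_features",
    "age_feature_report",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ["correlation", "contrast", "homogeneity", "dissimilarity", "asm", "energy"]

# Angle names follow the usual texture convention (45 deg = up-right
# neighbour). scikit-image measures angles with the row axis pointing down,
# so the diagonal angles are passed with a flipped sign.
_DEG = {0: 0.0, 45: -np.pi / 4, 90: np.pi / 2, 135: -3 * np.pi / 4}


@dataclass
class GlcmParams:
    """Co-occurrence parameters: quantization levels, pixel offset, angles."""

    levels: int = 256
    distance: int = 1
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normed: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        unknown = [a for a in self.angles_deg if a not in _DEG]
        if unknown:
            raise ValueError(f"unsupported angles {unknown}; use 0/45/90/135")

    @property
    def angles_rad(self) -> list[float]:
        return [_DEG[a] for a in self.angles_deg]


@dataclass
class TextureVector:
    """The six GLCM features of one fused image plus subject covariates.

    ``correlation_defined`` is False for a constant image, where the GLCM
    marginals have zero variance and correlation is undefined (stored NaN).
    """

    correlation: float
    contrast: float
    homogeneity: float
    dissimilarity: float
    asm: float
    energy: float
    subject_id: str = ""
    age_months: int = 0
    sex: str = ""
    correlation_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age_months": self.age_months,
            "sex": self.sex,
            **{k: getattr(self, k) for k in FEATURE_NAMES},
        }


def glcm(img: np.ndarray, params: GlcmParams | None = None) -> np.ndarray:
    """Gray-level co-occurrence matrices, one ``levels x levels`` plane per angle.

    Returns an array of shape ``(levels, levels, 1, n_angles)`` (the
    scikit-image layout, with a single distance). Gray values are requantized
    to ``levels`` bins when levels < 256.
    """
    params = params or GlcmParams()
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("image must be 8-bit gray")
        img = img.astype(np.uint8)
    if min(img.shape) <= params.distance:
        raise ValueError(
            f"image {img.shape} smaller than co-occurrence offset {params.distance}"
        )
    if params.levels < 256 and int(img.max()) >= params.levels:
        img = (img.astype(np.int64) * params.levels // 256).astype(np.uint8)
    return graycomatrix(
        img,
        distances=[params.distance],
        angles=params.angles_rad,
        levels=params.levels,
        symmetric=params.symmetric,
        normed=params.normed,
    )


def texture_features(
    img: np.ndarray,
    params: GlcmParams | None = None,
    subject_id: str = "",
    age_months: int = 0,
    sex: str = "",
) -> TextureVector:
    """Six GLCM features averaged over the configured angles.

    contrast = sum p(i,j) (i-j)^2; dissimilarity = sum p(i,j) |i-j|;
    homogeneity = sum p(i,j) / (1 + (i-j)^2); ASM = sum p(i,j)^2;
    energy = sqrt(ASM); correlation = sum p(i,j)(i-mu_i)(j-mu_j)/(s_i s_j).
    """
    params = params or GlcmParams()
    p = glcm(img, params)
    corr_defined = bool(np.ptp(np.asarray(img)) > 0)
    vals = {}
    for prop, key in [
        ("contrast", "contrast"),
        ("dissimilarity", "dissimilarity"),
        ("homogeneity", "homogeneity"),
        ("ASM", "asm"),
        ("correlation", "correlation"),
    ]:
        vals[key] = float(np.mean(graycoprops(p, prop)))
    # energy from the angle-averaged ASM, keeping energy = sqrt(ASM) exactly
    vals["energy"] = float(np.sqrt(vals["asm"]))
    if not corr_defined:
        vals["correlation"] = float("nan")
    return TextureVector(
        correlation=vals["correlation"],
        contrast=vals["contrast"],
        homogeneity=vals["homogeneity"],
        dissimilarity=vals["dissimilarity"],
        asm=vals["asm"],
        energy=vals["energy"],
        subject_id=subject_id,
        age_months=age_months,
        sex=sex,
        correlation_defined=corr_defined,
    )


def vectors_to_frame(vectors: list[TextureVector]) -> pd.DataFrame:
    """Features table: subject_id, age_months, sex, then the six features."""
    return pd.DataFrame([v.as_dict() for v in vectors])


def age_feature_report(vectors: list[TextureVector], min_group: int = 3) -> pd.DataFrame:
    """Per-sex, per-feature Pearson and Spearman coefficients of feature vs age.

    Groups smaller than ``min_group`` are skipped with a warning. A feature
    constant across ages has an undefined coefficient; it is reported as 0.0
    with ``defined = False``.
    """
    df = vectors_to_frame(vectors)
    rows = []
    for sex, grp in df.groupby("sex"):
        if len(grp) < min_group:
            warnings.warn(f"sex group {sex!r} has only {len(grp)} samples; skipped")
            continue
        age = grp["age_months"].to_numpy(dtype=float)
        for feat in FEATURE_NAMES:
            y = grp[feat].to_numpy(dtype=float)
            ok = np.isfinite(y)
            defined = ok.sum() >= min_group and np.ptp(y[ok]) > 0 and np.ptp(age[ok]) > 0
            if defined:
                pear = float(stats.pearsonr(age[ok], y[ok]).statistic)
                spear = float(stats.spearmanr(age[ok], y[ok]).statistic)
            else:
                pear = spear = 0.0
            rows.append(
                {
                    "sex": sex,
                    "feature": feat,
                    "n": int(ok.sum()),
                    "pearson": pear,
                    "spearman": spear,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def scatter_data(vectors: list[TextureVector], feature: str) -> pd.DataFrame:
    """(age, feature) pairs per sex, ready for scatter plotting."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    df = vectors_to_frame(vectors)
    return df[["sex", "age_months", feature]].rename(columns={feature: "value"})
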