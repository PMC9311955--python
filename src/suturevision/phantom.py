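"""Seeded synthetic CBCT phantoms of the midpalatal suture.

A phantom volume is a stack of 512x512 axial slices of textured "bone"
(smoothed Gaussian noise around a constant gray) crossed by a sinuous dark
band along the anterior-posterior axis at the midline — the unossified
suture. A latent ossification parameter ``omega`` in [0, 1] controls how
far the band has faded: at ``omega = 0`` the suture is wide, dark and
high-contrast; at ``omega = 1`` its intensity deficit is zero and the ROI
is statistically indistinguishable from plain bone. Because texture
uniformity rises monotonically with ``omega`` by construction, the
downstream fusion + GLCM pipeline should recover a strong positive
association between ``omega`` (or the age it is tied to) and the
homogeneity/correlation features — which is exactly what the package's
trend tests measure.

``generate_cohort`` reproduces the demographic shape of a growth-population
CBCT database: 1006 scans from 690 participants (414/245/23/7/1 with
1/2/3/4/5 scans), 610 female and 396 male files, ages concentrated between
10 and 19 years. Ossification is a noisy monotone function of age.

This is an emulation of the data-generating situation, not of palate
anatomy or radiation physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import RoiBoundaries, VolumeGrid

__all__ = [
    "PhantomParams",
    "CohortMember",
    "generate_volume",
    "generate_cohort",
    "write_cohort",
    "TABLE_AGE_SEX_COUNTS",
]

# Demographic table of the emulated database: per-year age bin -> (F, M) scan counts.
TABLE_AGE_SEX_COUNTS: dict[int, tuple[int, int]] = {
    4: (0, 1), 5: (5, 1), 6: (2, 1), 7: (7, 2), 8: (11, 10),
    9: (22, 32), 10: (50, 51), 11: (61, 48), 12: (61, 51), 13: (65, 48),
    14: (56, 38), 15: (52, 29), 16: (57, 28), 17: (68, 26), 18: (65, 21),
    19: (17, 6), 20: (9, 0), 21: (1, 2), 22: (1, 0), 23: (0, 1),
}
# participants with 1..5 repeat scans
PARTICIPANT_MULTIPLICITY = {1: 414, 2: 245, 3: 23, 4: 7, 5: 1}

BONE_GRAY = 170.0
SUTURE_AMPLITUDE_MAX_PX = 7.0  # interdigitation sinusoid amplitude, open suture
SUTURE_AMPLITUDE_MIN_PX = 1.0  # residual wander of the nearly closed suture
SUTURE_WIDTH_MAX_PX = 8.0      # Gaussian half-width of the fully open suture
SUTURE_WIDTH_MIN_PX = 1.2      # residual width of the nearly closed suture
SUTURE_CONTRAST_MAX = 40.0     # gray deficit scale of the fully open suture
SUTURE_ROUGHNESS_MAX = 10.0    # extra high-frequency gray jitter of the open suture
MATURATION_SD_MAX = 20.0       # low-frequency density variation of mature bone
MATURATION_SIGMA_PX = 12.0     # correlation length of that variation
BONE_NOISE_SD_MATURE = 10.0    # pre-smoothing trabecular noise, mature bone
BONE_NOISE_IMMATURITY = 1.5    # extra noise fraction of fully immature bone


@dataclass
class PhantomParams:
    """Construction parameters of one phantom volume."""

    ossification: float              # omega in [0, 1]
    age_months: int = 120
    suture_width_px: float = SUTURE_WIDTH_MAX_PX
    suture_contrast: float = SUTURE_CONTRAST_MAX
    interdigitation_amplitude: float = SUTURE_AMPLITUDE_MAX_PX
    suture_roughness: float = SUTURE_ROUGHNESS_MAX
    maturation_sd: float = 0.0
    bone_noise_sd: float = BONE_NOISE_SD_MATURE
    n_slices: int = 7
    seed: int = 0
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ossification <= 1.0):
            raise ValueError("ossification must lie in [0, 1]")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @classmethod
    def from_ossification(
        cls, omega: float, age_months: int = 120, seed: int = 0, subject_id: str = "phantom"
    ) -> "PhantomParams":
        """Map omega to suture geometry: width and contrast fade as it closes."""
        return cls(
            ossification=omega,
            age_months=age_months,
            suture_width_px=SUTURE_WIDTH_MIN_PX
            + (SUTURE_WIDTH_MAX_PX - SUTURE_WIDTH_MIN_PX) * (1 - omega),
            suture_contrast=SUTURE_CONTRAST_MAX * (1 - omega),
            interdigitation_amplitude=SUTURE_AMPLITUDE_MIN_PX
            + (SUTURE_AMPLITUDE_MAX_PX - SUTURE_AMPLITUDE_MIN_PX) * (1 - omega),
            suture_roughness=SUTURE_ROUGHNESS_MAX * (1 - omega),
            maturation_sd=MATURATION_SD_MAX * omega,
            bone_noise_sd=BONE_NOISE_SD_MATURE * (1 + BONE_NOISE_IMMATURITY * (1 - omega)),
            seed=seed,
            subject_id=subject_id,
        )


def generate_volume(params: PhantomParams) -> tuple[VolumeGrid, RoiBoundaries]:
    """One phantom volume plus the boundary labels of its constructed geometry.

    The suture occupies axial slices [2, 2 + n_slices) between in-plane rows
    150..350 (anterior->posterior) around column 256, with per-slice jitter
    of the sinusoid phase emulating out-of-plane wandering.
    """
    rng = np.random.default_rng(params.seed)
    n_axial = params.n_slices + 4
    upper, lower = 2, 2 + params.n_slices
    anterior, posterior = 150, 350
    midline = 256

    vol = np.empty((n_axial, 512, 512), dtype=np.float64)
    rows = np.arange(anterior, posterior, dtype=np.float64)
    cols = np.arange(512, dtype=np.float64)
    phase0 = rng.uniform(0, 2 * np.pi)
    n_waves = rng.uniform(2.0, 3.5)
    # the gap/island speckle pattern is a 3-D structure shared by adjacent
    # slices, so it survives the pairwise fusion instead of averaging out
    speckle = rng.uniform(0.0, 1.0, size=(posterior - anterior, 512))
    rough = rng.normal(0.0, 1.0, size=(posterior - anterior, 512))
    # mature bone carries smooth large-scale density variation (sclerotic
    # banding); its amplitude grows with ossification and, being shared
    # across slices, it survives fusion — the source of the rising lag-1
    # texture correlation of older phantoms
    if params.maturation_sd > 0:
        mat = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(512, 512)), sigma=MATURATION_SIGMA_PX
        )
        mat *= params.maturation_sd / mat.std()
    else:
        mat = 0.0

    for z in range(n_axial):
        bone = (
            BONE_GRAY
            + ndimage.gaussian_filter(
                rng.normal(0.0, params.bone_noise_sd, size=(512, 512)), sigma=1.5
            )
            + mat
        )
        if upper <= z < lower and (params.suture_contrast > 0 or params.suture_roughness > 0):
            # sinuous band: centre wanders sinusoidally along the AP axis,
            # with per-row jaggedness emulating interdigitated edges
            phase = phase0 + rng.normal(0.0, 0.25)
            jitter = rng.normal(0.0, 0.8)
            centre = (
                midline
                + jitter
                + params.interdigitation_amplitude
                * np.sin(2 * np.pi * n_waves * (rows - anterior) / (posterior - anterior) + phase)
                + rng.normal(0.0, 0.5, size=rows.shape)
            )
            band = np.exp(
                -((cols[None, :] - centre[:, None]) ** 2) / (2 * params.suture_width_px**2)
            )
            # speckled deficit: the open suture reads as a jumble of gaps and
            # bone islands, so its gray variance is high-frequency and the
            # lag-1 texture correlation stays low until the band fades
            deficit = params.suture_contrast * band * speckle
            if params.suture_roughness > 0:
                deficit += params.suture_roughness * band * rough
            bone[anterior:posterior, :] -= deficit
        vol[z] = bone

    voxels = np.rint(np.clip(vol, 0, 255)).astype(np.uint8)
    grid = VolumeGrid(voxels=voxels, subject_id=params.subject_id)
    bounds = RoiBoundaries(
        subject_id=params.subject_id,
        upper_slice=upper,
        lower_slice=lower,
        anterior_px=anterior,
        posterior_px=posterior,
        midline_px=midline,
        age_months=params.age_months,
        sex="F",
    )
    return grid, bounds


@dataclass
class CohortMember:
    """One scan of the synthetic cohort: labels plus generation truth."""

    subject_id: str
    participant_id: str
    age_months: int
    sex: str
    omega: float
    params: PhantomParams
    bounds: RoiBoundaries = field(init=False)

    def __post_init__(self) -> None:
        # bounds are fixed by the construction geometry of generate_volume
        self.bounds = RoiBoundaries(
            subject_id=self.subject_id,
            upper_slice=2,
            lower_slice=2 + self.params.n_slices,
            anterior_px=150,
            posterior_px=350,
            midline_px=256,
            age_months=self.age_months,
            sex=self.sex,
            participant_id=self.participant_id,
        )


def _base_roster() -> pd.DataFrame:
    """The full 1006-scan roster: one row per scan with age year and sex."""
    rows = []
    for year, (n_f, n_m) in TABLE_AGE_SEX_COUNTS.items():
        rows += [{"age_years": year, "sex": "F"}] * n_f
        rows += [{"age_years": year, "sex": "M"}] * n_m
    return pd.DataFrame(rows)


def _assign_participants(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Group scans into participants with the table multiplicities.

    Scans are sorted by (sex, age) so repeat scans of one participant share
    the sex and have close ages; multiplicities are assigned in a seeded
    shuffle. When the roster is a subsample, multiplicities are scaled to
    cover it.
    """
    df = df.sort_values(["sex", "age_years"], kind="stable").reset_index(drop=True)
    n = len(df)
    mult = []
    for m, cnt in PARTICIPANT_MULTIPLICITY.items():
        mult += [m] * cnt
    rng.shuffle(mult)
    pids = np.empty(n, dtype=object)
    pid, i, mi = 0, 0, 0
    while i < n:
        m = mult[mi % len(mult)]
        take = min(m, n - i)
        pids[i : i + take] = f"P{pid:04d}"
        i += take
        pid += 1
        mi += 1
    df["participant_id"] = pids
    return df


def generate_cohort(
    n: int = 1006,
    age_range_years: tuple[int, int] | None = None,
    seed: int = 0,
    n_slices: int = 7,
) -> list[CohortMember]:
    """A labeled synthetic cohort shaped like the emulated database.

    Ages follow the demographic table (optionally restricted to
    ``age_range_years``, inclusive), sexes keep the ~610:396 proportion, and
    ossification is a noisy increasing function of age. ``n = 1006`` uses
    the exact table counts; smaller cohorts subsample them, larger ones
    resample with replacement.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    roster = _base_roster()
    if age_range_years is not None:
        lo, hi = age_range_years
        roster = roster[(roster.age_years >= lo) & (roster.age_years <= hi)]
        if roster.empty:
            raise ValueError(f"no roster scans in age range {age_range_years}")
    if n == len(roster):
        df = roster.reset_index(drop=True)
    else:
        idx = rng.choice(len(roster), size=n, replace=n > len(roster))
        df = roster.iloc[np.sort(idx)].reset_index(drop=True)
    df = _assign_participants(df, rng)

    members: list[CohortMember] = []
    for i, row in enumerate(df.itertuples(index=False)):
        age_months = int(row.age_years) * 12 + int(rng.integers(0, 12))
        # ossification: monotone in age with individual variation
        base = (age_months / 12.0 - 4.0) / 19.0
        omega = float(np.clip(base + rng.normal(0.0, 0.06), 0.02, 0.98))
        sid = f"S{i:04d}"
        params = PhantomParams.from_ossification(
            omega,
            age_months=age_months,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=sid,
        )
        params.n_slices = n_slices
        members.append(
            CohortMember(
                subject_id=sid,
                participant_id=str(row.participant_id),
                age_months=age_months,
                sex=str(row.sex),
                omega=omega,
                params=params,
            )
        )
    return members


def write_cohort(members: list[CohortMember], out_dir: str | Path) -> dict[str, Path]:
    """Write volumes (.npz), a labels CSV and an omega-truth CSV."""
    from .volume_io import write_labels, write_volume

    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    for m in members:
        grid, _ = generate_volume(m.params)
        grid.subject_id = m.subject_id
        write_volume(grid, vol_dir / f"{m.subject_id}.npz")
    labels_path = write_labels([m.bounds for m in members], out_dir / "labels.csv")
    truth = pd.DataFrame(
        [
            {"subject_id": m.subject_id, "participant_id": m.participant_id, "omega": m.omega}
            for m in members
        ]
    )
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return {"volumes": vol_dir, "labels": labels_path, "truth": truth_path}


def fused_image_of(member: CohortMember, fusion_params=None) -> np.ndarray:
    """Convenience: generate, extract and fuse one member's suture image."""
    from .fusion import fuse_stack
    from .roi import extract_roi

    grid, bounds = generate_volume(member.params)
    stack = extract_roi(grid, member.bounds)
    return fuse_stack(stack, fusion_params).pixels
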