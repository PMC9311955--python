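"""GLCM counting against a brute-force oracle; feature formulas; age report."""

import numpy as np
import pytest

from suturevision.texture import (
    FEATURE_NAMES,
    GlcmParams,
    TextureVector,
    age_feature_report,
    glcm,
    texture_features,
)

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(img, levels, angle_deg, distance=1, symmetric=True, normed=True):
    """Double-loop pair counting, independent of any library."""
    dr, dc = OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    m = np.zeros((levels, levels))
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[img[r, c], img[r2, c2]] += 1
    if symmetric:
        m = m + m.T
    if normed and m.sum() > 0:
        m = m / m.sum()
    return m


class TestGlcmCounting:
    def test_two_row_image_gives_diagonal_halves(self):
        img = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        p = glcm(img, GlcmParams(levels=2, angles_deg=(0,)))
        np.testing.assert_allclose(p[:, :, 0, 0], [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_mass_on_one_diagonal_cell(self):
        img = np.full((6, 6), 3, dtype=np.uint8)
        p = glcm(img, GlcmParams(levels=4, angles_deg=(0, 90)))
        for a in range(2):
            assert p[3, 3, 0, a] == pytest.approx(1.0)

    def test_checkerboard_mass_off_diagonal(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        p = glcm(img.astype(np.uint8), GlcmParams(levels=2, angles_deg=(0,)))
        assert p[0, 0, 0, 0] == 0 and p[1, 1, 0, 0] == 0
        assert p[0, 1, 0, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        levels = int(rng.integers(2, 9))
        h, w = rng.integers(3, 17, size=2)
        img = rng.integers(0, levels, size=(h, w)).astype(np.uint8)
        params = GlcmParams(levels=levels)
        p = glcm(img, params)
        for ai, ang in enumerate(params.angles_deg):
            np.testing.assert_allclose(p[:, :, 0, ai], brute_force_glcm(img, levels, ang))

    def test_image_smaller_than_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            glcm(np.zeros((1, 5), dtype=np.uint8), GlcmParams(distance=2))


class TestFeatures:
    def test_constant_image_degenerate_values(self):
        tv = texture_features(np.full((8, 8), 7, dtype=np.uint8))
        assert tv.contrast == 0 and tv.dissimilarity == 0
        assert tv.homogeneity == pytest.approx(1.0)
        assert tv.asm == pytest.approx(1.0) and tv.energy == pytest.approx(1.0)
        assert not tv.correlation_defined and np.isnan(tv.correlation)

    def test_two_row_example_matches_hand_sums(self):
        # GLCM at 0 deg is diag(0.5, 0.5): contrast 0, homog 1, ASM 0.5
        img = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        tv = texture_features(img, GlcmParams(levels=2, angles_deg=(0,)))
        assert tv.contrast == pytest.approx(0.0)
        assert tv.homogeneity == pytest.approx(1.0)
        assert tv.asm == pytest.approx(0.5)
        assert tv.energy == pytest.approx(np.sqrt(0.5))
        # marginals are (0.5, 0.5); cov = E[ij] - mu^2 = 0.5 - 0.25 = sigma^2
        assert tv.correlation == pytest.approx(1.0)

    def test_checkerboard_homogeneity_and_contrast(self):
        img = (np.indices((8, 8)).sum(axis=0) % 2).astype(np.uint8)
        tv = texture_features(img, GlcmParams(levels=2, angles_deg=(0,)))
        assert tv.homogeneity == pytest.approx(0.5)
        assert tv.contrast == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_feature_formulas_match_direct_sums(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
        params = GlcmParams(levels=8, angles_deg=(0, 45, 90, 135))
        p = glcm(img, params)
        i, j = np.indices((8, 8))
        per_angle = {k: [] for k in FEATURE_NAMES}
        for a in range(4):
            m = p[:, :, 0, a]
            per_angle["contrast"].append((m * (i - j) ** 2).sum())
            per_angle["dissimilarity"].append((m * np.abs(i - j)).sum())
            per_angle["homogeneity"].append((m / (1.0 + (i - j) ** 2)).sum())
            asm = (m**2).sum()
            per_angle["asm"].append(asm)
            mu_i = (m.sum(axis=1) * np.arange(8)).sum()
            mu_j = (m.sum(axis=0) * np.arange(8)).sum()
            s_i = np.sqrt((m.sum(axis=1) * (np.arange(8) - mu_i) ** 2).sum())
            s_j = np.sqrt((m.sum(axis=0) * (np.arange(8) - mu_j) ** 2).sum())
            per_angle["correlation"].append(
                (m * np.outer(np.arange(8) - mu_i, np.arange(8) - mu_j)).sum() / (s_i * s_j)
            )
        tv = texture_features(img, params)
        for k in FEATURE_NAMES:
            if k == "energy":
                expected = np.sqrt(np.mean(per_angle["asm"]))
            else:
                expected = np.mean(per_angle[k])
            assert getattr(tv, k) == pytest.approx(expected, rel=1e-10)

    def test_energy_is_sqrt_asm_and_bounds(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            img = rng.integers(0, 256, size=(20, 30)).astype(np.uint8)
            tv = texture_features(img)
            assert tv.energy == pytest.approx(np.sqrt(tv.asm))
            assert 0 < tv.homogeneity <= 1 and 0 < tv.asm <= 1
            assert -1 <= tv.correlation <= 1
            assert tv.contrast >= 0 and tv.dissimilarity >= 0


def _vec(age, sex, **feat):
    base = dict.fromkeys(FEATURE_NAMES, 0.5)
    base.update(feat)
    return TextureVector(subject_id="s", age_months=age, sex=sex, **base)


class TestAgeReport:
    def test_exact_linear_feature_gives_pearson_one(self):
        vecs = [_vec(60 + 12 * k, "F", homogeneity=0.1 + 0.01 * k) for k in range(8)]
        rep = age_feature_report(vecs)
        row = rep[(rep.feature == "homogeneity") & (rep.sex == "F")].iloc[0]
        assert row.pearson == pytest.approx(1.0)
        assert row.spearman == pytest.approx(1.0)

    def test_constant_feature_flagged_zero(self):
        vecs = [_vec(60 + 12 * k, "M") for k in range(5)]
        rep = age_feature_report(vecs)
        row = rep[(rep.feature == "contrast") & (rep.sex == "M")].iloc[0]
        assert row.pearson == 0.0 and not row.defined

    def test_small_group_skipped_with_warning(self):
        vecs = [_vec(100, "F"), _vec(120, "F"), _vec(140, "F"), _vec(100, "M")]
        with pytest.warns(UserWarning, match="M"):
            rep = age_feature_report(vecs)
        assert set(rep.sex) == {"F"}
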