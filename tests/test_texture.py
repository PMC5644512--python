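import numpy as np
import pytest
from helpers import bf_glcm_counts, bf_runlength_features, bf_runs, random_textured_nucleus

from chromatex import (
    NucleusImage,
    build_glcm,
    build_glcm_set,
    build_rlm,
    build_rlm_set,
    haralick_features,
    runlength_features,
)
from chromatex.texture import ANGLES, GLCM_DISTANCES, RLM_LEVELS


def full(img):
    img = np.asarray(img, np.uint8)
    return NucleusImage(img, np.ones(img.shape, bool))


class TestGlcmConstruction:
    def test_constant_image_single_cell(self):
        m = build_glcm(full(np.full((2, 2), 7)), r=1, theta=0)
        assert m.P[7, 7] == 1.0
        assert m.P.sum() == pytest.approx(1.0)

    def test_alternating_line(self):
        img = np.array([[0, 255] * 4])
        m = build_glcm(full(img), r=1, theta=0)
        assert m.P[0, 255] == pytest.approx(0.5)
        assert m.P[255, 0] == pytest.approx(0.5)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            nuc = random_textured_nucleus(rng)
            for r in GLCM_DISTANCES[:2]:
                for theta in ANGLES:
                    m = build_glcm(nuc, r, theta)
                    bf = bf_glcm_counts(nuc.intensities, nuc.mask, r, theta)
                    if bf.sum() == 0:
                        assert m.pair_count == 0
                    else:
                        np.testing.assert_allclose(m.P, bf / bf.sum(), atol=1e-15)

    def test_probability_conservation_and_symmetry(self):
        rng = np.random.default_rng(11)
        nuc = random_textured_nucleus(rng, n=12)
        for m in build_glcm_set(nuc):
            if m.pair_count:
                assert m.P.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(m.P, m.P.T)

    def test_oversized_displacement_flagged_empty(self):
        nuc = full(np.full((3, 3), 5))
        with pytest.warns(UserWarning, match="no valid pixel pairs"):
            m = build_glcm(nuc, r=8, theta=0)
        assert m.pair_count == 0


class TestHaralickFeatures:
    def test_constant_image_identities(self):
        c = 90
        f = haralick_features(build_glcm_set(full(np.full((8, 8), c))))
        assert f["f19"] == 0.0          # contrast
        assert f["f20"] == 1.0          # energy
        assert f["f23"] == 0.0          # entropy
        assert f["f28"] == 1.0          # inverse difference moment
        assert f["f36"] == pytest.approx(2 * c)  # sum average

    def test_alternating_contrast(self):
        img = np.array([[0, 255] * 4])
        f = haralick_features([build_glcm(full(img), 1, 0)])
        assert f["f19"] == pytest.approx(255**2)

    def test_ranges_on_random_images(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            nuc = random_textured_nucleus(rng, n=10)
            f = haralick_features(build_glcm_set(nuc))
            assert 0 < f["f20"] <= 1
            assert f["f23"] >= 0
            assert 0 <= f["f38"] < 1
            assert -1e-9 <= f["f39"] <= 1 + 1e-9

    def test_transposition_invariance_of_angle_average(self):
        rng = np.random.default_rng(13)
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        f1 = haralick_features(build_glcm_set(full(img)))
        f2 = haralick_features(build_glcm_set(full(img.T)))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-9)


class TestRunLength:
    def test_constant_image_rows(self):
        m = build_rlm(full(np.full((8, 8), 50)), theta=0, levels=2)
        assert m.total_runs == 8
        assert m.R[0, 7] == 8  # 8 runs of length 8, level floor(50*2/256)=0

    def test_alternating_unit_runs(self):
        img = np.array([[0, 255] * 4])
        m = build_rlm(full(img), theta=0, levels=2)
        assert m.total_runs == 8
        assert m.R[:, 0].sum() == 8

    def test_matches_brute_force_runs(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            nuc = random_textured_nucleus(rng)
            for theta in ANGLES:
                for levels in RLM_LEVELS:
                    m = build_rlm(nuc, theta, levels)
                    bf = bf_runs(nuc.intensities, nuc.mask, theta, levels)
                    R = np.zeros_like(m.R)
                    for lv, ln in bf:
                        R[lv, ln - 1] += 1
                    np.testing.assert_array_equal(m.R, R)

    def test_pixel_conservation(self):
        rng = np.random.default_rng(15)
        nuc = random_textured_nucleus(rng, n=16)
        n_masked = nuc.area
        for m in build_rlm_set(nuc):
            lengths = np.arange(1, m.R.shape[1] + 1)
            assert int((m.R * lengths).sum()) == n_masked


class TestRunLengthFeatures:
    def test_constant_image_closed_forms(self):
        m = build_rlm(full(np.full((8, 8), 50)), theta=0, levels=2)
        f = runlength_features([m])
        assert f["f32"] == pytest.approx(64)      # long-run emphasis
        assert f["f31"] == pytest.approx(1 / 64)  # short-run emphasis
        assert f["f30"] == pytest.approx(8 / 64)  # run percentage

    def test_unit_runs_emphases(self):
        img = np.arange(64).reshape(8, 8) % 2 * 255
        img = np.where(np.indices((8, 8)).sum(0) % 2, 255, 0)
        m = build_rlm(full(img.astype(np.uint8)), theta=0, levels=2)
        f = runlength_features([m])
        assert f["f31"] == pytest.approx(1.0)
        assert f["f32"] == pytest.approx(1.0)

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(16)
        nuc = random_textured_nucleus(rng, n=10)
        for theta in (0, 45):
            m = build_rlm(nuc, theta, 16)
            runs = bf_runs(nuc.intensities, nuc.mask, theta, 16)
            bf = bf_runlength_features(runs, int(nuc.mask.sum()))
            f = runlength_features([m])
            for k, v in bf.items():
                assert f[k] == pytest.approx(v, rel=1e-12)
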