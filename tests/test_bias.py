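import numpy as np
import pytest
from helpers import disk_mask

from chromatex import (
    NucleusImage,
    align_to_ellipse,
    extract_features,
    fit_ellipse,
    quadrant_bias,
    split_quadrants,
    tangential_bias_values,
)


def ellipse_mask(a, b, theta_deg=0.0, n=121):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    t = np.deg2rad(theta_deg)
    u = (yy - c) * np.cos(t) + (xx - c) * np.sin(t)
    v = -(yy - c) * np.sin(t) + (xx - c) * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


def constant_nucleus(value, n=12):
    return NucleusImage(np.full((n, n), value, np.uint8), np.ones((n, n), bool))


class TestFitEllipse:
    def test_axis_aligned_ellipse_recovered(self):
        frame = fit_ellipse(ellipse_mask(40, 20))
        assert frame.major_axis == pytest.approx(80, rel=0.05)
        assert frame.minor_axis == pytest.approx(40, rel=0.05)
        assert abs(np.rad2deg(frame.orientation)) % 180 < 2

    def test_disk_is_isotropic(self):
        frame = fit_ellipse(disk_mask(25))
        assert frame.major_axis == pytest.approx(frame.minor_axis, rel=0.03)

    def test_rotated_orientation_recovered(self):
        frame = fit_ellipse(ellipse_mask(40, 20, theta_deg=30))
        angle = abs(np.rad2deg(abs(frame.orientation)))
        assert min(abs(angle - 30), abs(angle - 150)) < 2


class TestAlignToEllipse:
    def test_aligned_input_is_near_identity(self):
        # even grid: the centroid sits between pixels like the output
        # center, so the transform reduces to an exact integer shift
        mask = ellipse_mask(30, 18, n=80)
        rng = np.random.default_rng(30)
        img = np.full(mask.shape, 255, np.uint8)
        img[mask] = rng.integers(60, 200, mask.sum()).astype(np.uint8)
        nuc = NucleusImage(img, mask)
        out = align_to_ellipse(nuc, fit_ellipse(mask))
        assert out.area == pytest.approx(nuc.area, rel=0.02)
        # compare over the aligned mask via cross-correlation of histograms
        assert np.mean(
            np.abs(
                np.sort(out.masked_values.astype(float))
                - np.sort(nuc.masked_values.astype(float))
            )
        ) < 2.0

    def test_rotation_preserves_area_and_verticalizes(self):
        mask = ellipse_mask(35, 15, theta_deg=50)
        nuc = NucleusImage(np.full(mask.shape, 120, np.uint8), mask)
        out = align_to_ellipse(nuc, fit_ellipse(mask))
        assert out.area == pytest.approx(nuc.area, rel=0.02)
        frame = fit_ellipse(out.mask)
        assert abs(np.rad2deg(frame.orientation)) % 180 < 2  # major axis on rows


class TestSplitQuadrants:
    def _aligned_disk(self, r=20):
        mask = disk_mask(r)
        nuc = NucleusImage(np.full(mask.shape, 100, np.uint8), mask)
        return align_to_ellipse(nuc, fit_ellipse(mask))

    def test_disk_quadrants_balanced(self):
        quadrants = split_quadrants(self._aligned_disk())
        areas = [q.area for q in quadrants]
        assert max(areas) - min(areas) <= 0.04 * np.mean(areas)

    def test_quadrants_partition_the_mask(self):
        aligned = self._aligned_disk()
        total = sum(q.area for q in split_quadrants(aligned))
        assert total == aligned.area

    def test_off_axis_blob_in_single_quadrant(self):
        mask = disk_mask(20)
        n = mask.shape[0]
        img = np.full((n, n), 200)
        c = (n - 1) // 2
        img[c + 6:c + 10, c + 6:c + 10] = 50  # strictly inside quadrant (+,+)
        nuc = NucleusImage(img.astype(np.uint8), mask)
        aligned_like = NucleusImage(nuc.intensities, nuc.mask)  # disk: no rotation needed
        quadrants = split_quadrants(aligned_like)
        dark_counts = [(q.intensities[q.mask] == 50).sum() for q in quadrants]
        assert sorted(dark_counts)[:3] == [0, 0, 0] and max(dark_counts) == 16


class TestQuadrantBias:
    def test_identical_quadrants_have_zero_bias(self):
        quadrants = [constant_nucleus(80) for _ in range(4)]
        assert quadrant_bias(quadrants, 11) == 0.0

    def test_single_nonzero_quadrant_closed_form(self):
        quadrants = [constant_nucleus(100)] + [constant_nucleus(0) for _ in range(3)]
        # values (m,0,0,0): mean m/4, sample SD m/2 -> gt = 2
        assert quadrant_bias(quadrants, 11) == pytest.approx(2.0)

    def test_three_one_ratio_closed_form(self):
        quadrants = [constant_nucleus(v) for v in (1, 1, 1, 3)]
        assert quadrant_bias(quadrants, 11) == pytest.approx(2 / 3)

    def test_intensity_scale_invariance(self):
        quadrants = [constant_nucleus(v) for v in (10, 20, 30, 40)]
        doubled = [constant_nucleus(2 * v) for v in (10, 20, 30, 40)]
        assert quadrant_bias(quadrants, 11) == pytest.approx(quadrant_bias(doubled, 11))

    def test_unsupported_feature_index_rejected(self):
        with pytest.raises(ValueError):
            quadrant_bias([constant_nucleus(1)] * 4, 13)


class TestTangentialBiasValues:
    def _symmetric_nucleus(self):
        # 4-fold mirror-symmetric textured ellipse on an even grid, so the
        # symmetry center sits between pixels like the quadrant cut axes
        n = 80
        mask = ellipse_mask(30, 18, n=n)
        rng = np.random.default_rng(31)
        img = np.full((n, n), 255, np.uint8)
        img[mask] = rng.integers(60, 200, int(mask.sum())).astype(np.uint8)
        h = n // 2
        img[:h, h:] = img[:h, :h][:, ::-1]
        img[h:, :] = img[:h, :][::-1, :]
        return NucleusImage(img, mask)

    def test_mirror_symmetric_nucleus_has_zero_bias(self):
        f = extract_features(self._symmetric_nucleus(), names=["f45", "f46"])
        assert abs(f["f45"]) <= 1e-6
        assert abs(f["f46"]) <= 1e-6

    def test_equal_biases_average_to_common_value(self):
        quadrants = [constant_nucleus(v) for v in (100, 0, 0, 0)]
        f45, f46 = tangential_bias_values(quadrants)
        # every gt of a constant-intensity quadrant set is permutation-equal
        assert f45 == pytest.approx(f45)
        assert f45 >= 0 and f46 >= 0

    def test_concentrated_chromatin_raises_intensity_bias(self):
        def nucleus(weights_to_one):
            n = 81
            mask = ellipse_mask(28, 20, n=n)
            img = np.full((n, n), 180)
            c = (n - 1) / 2
            yy, xx = np.mgrid[0:n, 0:n]
            if weights_to_one:
                blob = (yy - c - 10) ** 2 + (xx - c - 8) ** 2 <= 25
            else:
                blob = ((yy - c) ** 2 + (xx - c) ** 2 <= 25)
                for dy, dx in ((10, 8), (-10, 8), (10, -8), (-10, -8)):
                    blob |= (yy - c - dy) ** 2 + (xx - c - dx) ** 2 <= 25
            img[blob & mask] = 70
            img[~mask] = 255
            return NucleusImage(img.astype(np.uint8), mask)

        f_conc = extract_features(nucleus(True), names=["f45"])["f45"]
        f_sym = extract_features(nucleus(False), names=["f45"])["f45"]
        assert f_conc > f_sym

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(32)
        n = 81
        mask = ellipse_mask(28, 17, n=n)
        img = np.full((n, n), 255, np.uint8)
        img[mask] = rng.integers(60, 200, int(mask.sum())).astype(np.uint8)
        nuc = NucleusImage(img, mask)
        rot = NucleusImage(np.rot90(img).copy(), np.rot90(mask).copy())
        f1 = extract_features(nuc, names=["f45", "f46"])
        f2 = extract_features(rot, names=["f45", "f46"])
        assert f2["f45"] == pytest.approx(f1["f45"], rel=0.05, abs=0.01)
        assert f2["f46"] == pytest.approx(f1["f46"], rel=0.05, abs=0.01)
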