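import numpy as np
import pytest

import vertebeam as vb
from vertebeam.io_core import ImageGrid, ValidationError
from vertebeam.metrics import (ROI, box_stats, cnr, compare_bone_contact,
                               contour_area_6db, filter_out_of_plane, gcnr,
                               peak_to_com_distance, snr)


def make_grid(n=100, d=0.1):
    return ImageGrid.from_extent(0, (n - 1) * d, 0, (n - 1) * d, d, d)


@pytest.fixture
def grid():
    return make_grid()


def two_roi_image(vals_in, vals_out, grid):
    """Left half <- vals_in, right half <- vals_out."""
    img = np.zeros(grid.shape)
    img[:, :50] = np.asarray(vals_in).reshape(100, 50)
    img[:, 50:] = np.asarray(vals_out).reshape(100, 50)
    roi_in = ROI(0, 4.9, 0, 9.9)
    roi_out = ROI(5.0, 9.9, 0, 9.9)
    return img, roi_in, roi_out


class TestGcnr:
    def test_identical_distributions_give_zero(self, grid):
        rng = np.random.default_rng(0)
        v = rng.random(5000)
        img, ri, ro = two_roi_image(v, v, grid)
        assert gcnr(img, ri, ro, grid) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self, grid):
        img, ri, ro = two_roi_image(np.full(5000, 2.0), np.full(5000, 1.0), grid)
        assert gcnr(img, ri, ro, grid) == 1.0

    def test_uniform_half_overlap(self):
        """U(0,1) vs U(0.5,1.5): overlap mass is exactly 0.5."""
        grid = make_grid(n=448)  # ~1e5 pixels per half
        rng = np.random.default_rng(123)
        n = 448 * 224
        img = np.zeros(grid.shape)
        img[:, :224] = rng.uniform(0, 1, (448, 224))
        img[:, 224:] = rng.uniform(0.5, 1.5, (448, 224))
        ri = ROI(0, 22.3, 0, 44.7)
        ro = ROI(22.4, 44.7, 0, 44.7)
        assert gcnr(img, ri, ro, grid) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_constant_rois_give_zero(self, grid):
        img, ri, ro = two_roi_image(np.ones(5000), np.ones(5000), grid)
        assert gcnr(img, ri, ro, grid) == 0.0

    def test_gain_invariance_exact(self, grid):
        rng = np.random.default_rng(1)
        img, ri, ro = two_roi_image(rng.random(5000), rng.random(5000) + 0.3, grid)
        assert gcnr(img, ri, ro, grid) == gcnr(7.3 * img, ri, ro, grid)

    def test_bounded_unit_interval(self, grid):
        rng = np.random.default_rng(2)
        img, ri, ro = two_roi_image(rng.random(5000) ** 2,
                                    rng.random(5000) * 3, grid)
        assert 0.0 <= gcnr(img, ri, ro, grid) <= 1.0

    def test_monotone_transform_stability(self, grid):
        """gCNR is distribution-overlap based: a log transform moves it by
        less than 0.05 on continuous ROIs (binning error only)."""
        rng = np.random.default_rng(3)
        img, ri, ro = two_roi_image(rng.lognormal(0, 0.4, 5000),
                                    rng.lognormal(0.8, 0.4, 5000), grid)
        g1 = gcnr(img, ri, ro, grid)
        g2 = gcnr(np.log1p(img), ri, ro, grid)
        assert abs(g1 - g2) < 0.05


class TestCnr:
    def test_equal_means_give_zero(self, grid):
        img, ri, ro = two_roi_image(np.ones(5000), np.ones(5000), grid)
        assert cnr(img, ri, ro, grid) == 0.0

    def test_reference_value(self, grid):
        rng = np.random.default_rng(0)
        a = rng.choice([2 - 1 / np.sqrt(2), 2 + 1 / np.sqrt(2)], 5000)
        b = rng.choice([1 - 1 / np.sqrt(2), 1 + 1 / np.sqrt(2)], 5000)
        img, ri, ro = two_roi_image(a, b, grid)
        # means 2 and 1, variances ~1/2 each -> CNR ~ 1
        assert cnr(img, ri, ro, grid) == pytest.approx(1.0, rel=0.05)

    def test_gain_invariance(self, grid):
        rng = np.random.default_rng(1)
        img, ri, ro = two_roi_image(rng.random(5000) + 1, rng.random(5000), grid)
        assert cnr(3.7 * img, ri, ro, grid) == pytest.approx(
            cnr(img, ri, ro, grid), rel=1e-12)

    def test_zero_variance_unequal_means_rejected(self, grid):
        img, ri, ro = two_roi_image(np.full(5000, 2.0), np.full(5000, 1.0), grid)
        with pytest.raises(ValidationError):
            cnr(img, ri, ro, grid)


class TestSnr:
    def test_exact_ratio(self, grid):
        rng = np.random.default_rng(0)
        b = rng.normal(5.0, 1.0, 5000)
        t = np.full(5000, 3.0 * b.std())
        img, ri, ro = two_roi_image(t, b, grid)
        assert snr(img, ri, ro, grid) == pytest.approx(3.0, rel=1e-12)

    def test_gain_invariance(self, grid):
        rng = np.random.default_rng(1)
        img, ri, ro = two_roi_image(rng.random(5000) + 2, rng.random(5000), grid)
        assert snr(5.0 * img, ri, ro, grid) == pytest.approx(
            snr(img, ri, ro, grid), rel=1e-12)

    def test_rayleigh_self_snr(self):
        """A Rayleigh ROI measured against itself: mean/std = sqrt(pi/(4-pi))
        ~ 1.91."""
        grid = make_grid(n=142)  # ~1e4 per half
        rng = np.random.default_rng(7)
        v = rng.rayleigh(1.0, 142 * 142)
        img = v.reshape(142, 142)
        roi = ROI(0, 14.1, 0, 14.1)
        expect = np.sqrt(np.pi / (4 - np.pi))
        assert snr(img, roi, roi, grid) == pytest.approx(expect, rel=0.05)

    def test_zero_background_std_rejected(self, grid):
        img, ri, ro = two_roi_image(np.ones(5000), np.ones(5000), grid)
        with pytest.raises(ValidationError):
            snr(img, ri, ro, grid)


class TestOutOfPlaneFilter:
    def test_boundary_value_discarded(self):
        kept, discarded = filter_out_of_plane([3.0, 3.01, 2.0, 10.0])
        assert kept == [1, 3]
        assert discarded == [0, 2]

    def test_partition_exhaustive_disjoint(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 6, 50)
        kept, discarded = filter_out_of_plane(vals)
        assert sorted(kept + discarded) == list(range(50))
        assert not set(kept) & set(discarded)


class TestContourArea:
    def test_single_pixel_impulse(self, grid):
        img = np.zeros(grid.shape)
        img[50, 50] = 1.0
        a = contour_area_6db(img, (5.0, 5.0), roi_size_mm=4.0, grid=grid)
        assert a == pytest.approx(grid.dx * grid.dz)

    def test_gaussian_spot_closed_form(self):
        """-6 dB area of an isotropic Gaussian amplitude spot matches
        pi * (sigma * sqrt(2 ln(1/0.5012)))^2 within 3 %."""
        grid = make_grid(n=400, d=0.025)
        sigma = 0.8
        xx = grid.lateral_coords[None, :] - 5.0
        zz = grid.axial_coords[:, None] - 5.0
        img = np.exp(-(xx ** 2 + zz ** 2) / (2 * sigma ** 2))
        a = contour_area_6db(img, (5.0, 5.0), roi_size_mm=8.0, grid=grid)
        expect = np.pi * (sigma * np.sqrt(2 * np.log(1 / 0.5012))) ** 2
        assert a == pytest.approx(expect, rel=0.03)

    def test_amplitude_doubling_invariance(self, grid):
        rng = np.random.default_rng(0)
        img = rng.random(grid.shape)
        a1 = contour_area_6db(img, (5.0, 5.0), roi_size_mm=6.0, grid=grid)
        a2 = contour_area_6db(2 * img, (5.0, 5.0), roi_size_mm=6.0, grid=grid)
        assert a1 == a2

    def test_all_zero_roi_rejected(self, grid):
        with pytest.raises(ValidationError):
            contour_area_6db(np.zeros(grid.shape), (5.0, 5.0),
                             roi_size_mm=4.0, grid=grid)


class TestBoneContactComparison:
    def test_identical_groups(self):
        out = compare_bone_contact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t_statistic"] == 0.0
        assert out["p_value"] == 1.0

    def test_shifted_groups_significant(self):
        out = compare_bone_contact([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert out["p_value"] < 0.01
        assert out["mean_difference"] == pytest.approx(10.0)

    def test_outlier_flagged_by_iqr_rule(self):
        s = box_stats([1.0, 2.0, 3.0, 100.0])
        assert s["outliers"] == [100.0]

    def test_no_outliers_in_tight_group(self):
        s = box_stats([1.0, 1.1, 1.2, 1.3])
        assert s["outliers"] == []

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_bone_contact([1.0], [1.0, 2.0])


class TestPeakToCom:
    def test_two_pixel_arithmetic(self):
        grid = ImageGrid.from_extent(0, 1, 0, 1, 1.0, 1.0)
        img = np.array([[1.0, 3.0], [0.0, 0.0]])
        # mass along x at z=0: COM x = 3/4, peak at x=1 -> 0.25 mm
        d = peak_to_com_distance(img, roi=None, grid=grid)
        assert d == pytest.approx(0.25)

    def test_symmetric_gaussian_near_zero(self):
        grid = make_grid(n=201, d=0.05)
        xx = grid.lateral_coords[None, :] - 5.0
        zz = grid.axial_coords[:, None] - 5.0
        img = np.exp(-(xx ** 2 + zz ** 2) / 0.5)
        d = peak_to_com_distance(img, roi=None, grid=grid)
        assert d <= np.hypot(grid.dx, grid.dz)

    def test_matches_direct_weighted_mean(self):
        grid = make_grid(n=30, d=0.2)
        rng = np.random.default_rng(5)
        img = rng.random(grid.shape)
        d = peak_to_com_distance(img, roi=None, grid=grid)
        w = img / img.sum()
        com = np.array([(w * grid.lateral_coords[None, :]).sum(),
                        (w * grid.axial_coords[:, None]).sum()])
        pz, px = np.unravel_index(np.argmax(img), img.shape)
        peak = np.array([grid.lateral_coords[px], grid.axial_coords[pz]])
        assert d == pytest.approx(float(np.linalg.norm(com - peak)), abs=1e-9)
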