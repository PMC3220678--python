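import numpy as np
import pytest

from retrotrack import (
    IntensityImage,
    LabelMap,
    MaskStats,
    RobustFit,
    band_upper,
    classify_masks,
    fit_robust_line,
    make_mismatch,
    measure_mask_stats,
    shape_qc,
)
from retrotrack.mask_qc import MATCHED, MISMATCHED


def _region_image(values, shape=(20, 20)):
    img = np.zeros(shape)
    lab = np.zeros(shape, dtype=np.int32)
    vals = np.asarray(values, dtype=float)
    img.flat[: vals.size] = vals
    lab.flat[: vals.size] = 1
    return IntensityImage(img), LabelMap(lab, "nuclear")


class TestMeasureMaskStats:
    def test_uniform_region(self):
        img, lab = _region_image([100.0] * 9)
        stats, flagged = measure_mask_stats(img, lab)
        assert not flagged
        (s,) = stats
        assert (s.mean_fi, s.sd_fi, s.cv) == (100.0, 0.0, 0.0)

    def test_two_point_region(self):
        img, lab = _region_image([90.0, 110.0])
        (s,), _ = measure_mask_stats(img, lab)
        assert s.mean_fi == pytest.approx(100.0)
        assert s.sd_fi == pytest.approx(10.0)  # population s.d.
        assert s.cv == pytest.approx(0.1)

    def test_intensity_scale_equivariance(self, rng):
        vals = rng.uniform(50, 500, 40)
        img1, lab = _region_image(vals)
        img2, _ = _region_image(2 * vals)
        (a,), _ = measure_mask_stats(img1, lab)
        (b,), _ = measure_mask_stats(img2, lab)
        assert b.mean_fi == pytest.approx(2 * a.mean_fi)
        assert b.sd_fi == pytest.approx(2 * a.sd_fi)
        assert b.cv == pytest.approx(a.cv)

    def test_too_few_valid_pixels_flagged(self):
        img, lab = _region_image([100.0])
        stats, flagged = measure_mask_stats(img, lab)
        assert stats == [] and flagged == [1]

    def test_invalid_pixels_excluded(self):
        img, lab = _region_image([10.0, 10.0, 9999.0])
        img.valid_mask.flat[2] = False
        (s,), _ = measure_mask_stats(img, lab)
        assert s.mean_fi == 10.0 and s.area_px == 2


class TestFitRobustLine:
    def test_exact_line_recovered(self):
        x = np.linspace(10, 100, 50)
        fit = fit_robust_line(np.c_[x, 2 * x + 1])
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-7)
        assert fit.residual_scale == pytest.approx(0.0, abs=1e-9)

    def test_gross_outlier_ignored(self):
        x = np.linspace(10, 100, 50)
        y = 2 * x + 1
        y[25] *= 10.0
        fit = fit_robust_line(np.c_[x, y])
        # oracle: OLS on the outlier-free subset gives exactly slope 2
        assert abs(fit.slope - 2.0) / 2.0 < 0.01
        assert abs(fit.intercept - 1.0) < 0.5

    def test_reference_coefficients_recovered(self, rng):
        # s.d.-vs-mean control relationships in this regime have slopes near
        # 0.08 and small negative intercepts; exact recovery on clean data
        x = rng.uniform(300, 2000, 120)
        fit = fit_robust_line(np.c_[x, 0.07821 * x - 16.83])
        assert fit.slope == pytest.approx(0.07821, abs=1e-8)
        assert fit.intercept == pytest.approx(-16.83, abs=1e-5)

    def test_degenerate_x_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_robust_line(np.c_[np.full(10, 5.0), np.arange(10.0)])

    def test_needs_three_points(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_robust_line(np.c_[[1.0, 2.0], [1.0, 2.0]])


def _fit(residual_scale=1.364, n=800, alpha=0.005):
    return RobustFit(
        slope=0.07821,
        intercept=-16.83,
        residual_scale=residual_scale,
        n=n,
        x_mean=900.0,
        s_xx=2.0e8,
        alpha=alpha,
    )


class TestBandUpper:
    def test_zero_scale_band_is_the_line(self):
        fit = _fit(residual_scale=0.0)
        for x in (300.0, 900.0, 1800.0):
            assert band_upper(fit, x) == pytest.approx(fit.line(x), abs=1e-12)

    def test_large_n_matches_normal_quantile(self):
        from scipy.stats import norm

        fit = _fit(n=100000, residual_scale=2.0)
        expected = fit.line(fit.x_mean) + norm.ppf(1 - fit.alpha / 2) * 2.0
        assert band_upper(fit, fit.x_mean) == pytest.approx(expected, rel=1e-3)

    def test_smaller_alpha_gives_wider_band(self):
        wide, narrow = _fit(alpha=0.005), _fit(alpha=0.05)
        for x in (300.0, 900.0, 1800.0):
            assert band_upper(wide, x) > band_upper(narrow, x)

    def test_band_widens_away_from_center(self):
        fit = _fit()
        w = lambda x: band_upper(fit, x) - fit.line(x)
        assert w(1800.0) > w(900.0) and w(100.0) > w(900.0)


class TestClassifyMasks:
    def test_on_line_point_is_matched(self):
        fit = _fit()
        s = MaskStats(1, 1000.0, 0.07821 * 1000 - 16.83, 200)
        assert s.sd_fi == pytest.approx(61.38)
        (c,) = classify_masks([s], fit)
        assert c.label == MATCHED

    def test_point_far_above_band_is_mismatched(self):
        fit = _fit()
        s = MaskStats(1, 1000.0, fit.line(1000.0) + 10 * fit.residual_scale, 200)
        (c,) = classify_masks([s], fit)
        assert c.label == MISMATCHED

    def test_low_sd_always_matched(self):
        # only the upper boundary gates: points far below the line are matched
        fit = _fit()
        (c,) = classify_masks([MaskStats(1, 1000.0, 0.0, 200)], fit)
        assert c.label == MATCHED

    def test_missing_stats_mismatched_with_reason(self):
        out = classify_masks([], _fit(), missing_ids=[7])
        assert out[0].cell_id == 7 and out[0].label == MISMATCHED and out[0].reason

    def test_affine_intensity_invariance(self, rng):
        x = rng.uniform(200, 1500, 200)
        y = 0.08 * x - 10 + rng.normal(0, 3, 200)
        a, b = 2.5, 120.0
        fit1 = fit_robust_line(np.c_[x, y])
        fit2 = fit_robust_line(np.c_[a * x + b, a * y])
        tests = [MaskStats(i, m, s, 100) for i, (m, s) in enumerate(zip(x, y + rng.normal(0, 6, 200)))]
        scaled = [MaskStats(t.cell_id, a * t.mean_fi + b, a * t.sd_fi, 100) for t in tests]
        l1 = [c.label for c in classify_masks(tests, fit1)]
        l2 = [c.label for c in classify_masks(scaled, fit2)]
        assert l1 == l2

    def test_smaller_alpha_enlarges_matched_set(self, rng):
        x = rng.uniform(200, 1500, 300)
        y = 0.08 * x - 10 + rng.normal(0, 5, 300)
        stats = [MaskStats(i, m, s, 100) for i, (m, s) in enumerate(zip(x, y))]
        fit_wide = fit_robust_line(np.c_[x, y], alpha=0.005)
        fit_narrow = fit_robust_line(np.c_[x, y], alpha=0.1)
        m_wide = {c.cell_id for c in classify_masks(stats, fit_wide) if c.label == MATCHED}
        m_narrow = {c.cell_id for c in classify_masks(stats, fit_narrow) if c.label == MATCHED}
        assert m_narrow <= m_wide


class TestMakeMismatch:
    def _disk(self, r=8, shape=(40, 40), center=(20, 20)):
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r**2

    def test_identity_transform(self):
        m = self._disk()
        moved, inter = make_mismatch(m, 0, 0, 0.0)
        np.testing.assert_array_equal(moved, m)
        np.testing.assert_array_equal(inter, m)

    def test_half_width_shift_shrinks_intersection(self):
        m = self._disk(r=8)  # width 16
        moved, inter = make_mismatch(m, 8, 0, 0.0)
        assert inter.sum() < m.sum()
        assert moved.sum() == m.sum()

    @pytest.mark.parametrize("args", [(3, -2, 0.0), (0, 0, 30.0), (5, 5, 45.0)])
    def test_intersection_subset_of_both(self, args):
        m = self._disk()
        moved, inter = make_mismatch(m, *args)
        assert not (inter & ~m).any()
        assert not (inter & ~moved).any()

    def test_rotation_roughly_preserves_area(self):
        m = self._disk(r=8)
        moved, _ = make_mismatch(m, 0, 0, 37.0)
        assert abs(moved.sum() - m.sum()) / m.sum() < 0.05

    def test_far_shift_gives_empty_intersection(self):
        m = self._disk(r=5, shape=(60, 60), center=(15, 15))
        moved, inter = make_mismatch(m, 25, 0, 0.0)
        assert moved.any() and not inter.any()


class TestShapeQc:
    def _field_of_disks(self, solidities_off=()):
        shape = (240, 240)
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        nuc = np.zeros(shape, dtype=np.int32)
        cyto = np.zeros(shape, dtype=np.int32)
        k = 0
        for r in (40, 120, 200):
            for c in (40, 120, 200):
                k += 1
                disk = (rr - r) ** 2 + (cc - c) ** 2 <= 10**2
                if k in solidities_off:  # carve a bite: low solidity
                    disk &= ~(((rr - r) ** 2 + (cc - (c + 6)) ** 2) <= 8**2)
                nuc[disk] = k
                ring = ((rr - r) ** 2 + (cc - c) ** 2 <= 18**2) & ~disk
                cyto[ring] = k
        img = IntensityImage(np.full(shape, 500.0))
        return LabelMap(nuc, "nuclear"), LabelMap(cyto, "cytoplasmic"), img

    def test_identical_cells_not_flagged(self):
        nuc, cyto, img = self._field_of_disks()
        df = shape_qc(nuc, cyto, img, img)
        assert not df["qc_flag"].any()

    def test_low_solidity_cell_flagged(self):
        nuc, cyto, img = self._field_of_disks(solidities_off=(5,))
        df = shape_qc(nuc, cyto, img, img)
        flagged = set(df.loc[df.qc_flag, "cell_id"])
        assert flagged == {5}
        # oracle: robust z-score on solidity directly
        sol = df.set_index("cell_id")["nuclear_solidity"]
        med = sol.median()
        mad = 1.4826 * (sol - med).abs().median()
        assert abs(sol[5] - med) > 3 * mad

    def test_disk_perimeter_near_circumference(self):
        nuc, cyto, img = self._field_of_disks()
        df = shape_qc(nuc, cyto, img, img)
        per = df["nuclear_perimeter"].iloc[0]
        assert abs(per - 2 * np.pi * 10) / (2 * np.pi * 10) < 0.15
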