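"""Mask morphometry: boundary, ellipse fit, RD/MD/WP, area, staging."""

import math

import numpy as np
import pytest
from skimage.measure import EllipseModel

from pterymeter.geometry import (EllipseParams, EmptyMaskError, center_and_rd,
                                 classify_status, compute_area_mm2, compute_wp,
                                 extract_boundary, fit_ellipse, measure,
                                 min_center_distance, rasterize_ellipse,
                                 xor_masks)
from pterymeter.synthetic import (EyePhantomParams, generate_phantom,
                                  truth_measurements)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestBoundary:
    def test_all_foreground_3x3_gives_ring(self):
        pts = extract_boundary(np.ones((3, 3), dtype=bool))
        assert len(pts) == 8
        assert [1, 1] not in pts.tolist()

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        assert extract_boundary(m).tolist() == [[2, 3]]

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_boundary(np.zeros((4, 4), dtype=bool))


class TestEllipseFit:
    def test_exact_samples_recovered(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([256 + 150 * np.sin(t), 256 + 200 * np.cos(t)])
        e = fit_ellipse(pts)
        assert e.center == pytest.approx((256, 256), rel=1e-6)
        assert e.semi_axis_a == pytest.approx(200, rel=1e-6)
        assert e.semi_axis_b == pytest.approx(150, rel=1e-6)
        assert abs(e.rotation) < 1e-6

    def test_circle_gives_equal_axes(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([100 + 80 * np.sin(t), 120 + 80 * np.cos(t)])
        e = fit_ellipse(pts)
        assert e.semi_axis_a == pytest.approx(e.semi_axis_b, rel=1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))

    @pytest.mark.parametrize("trial", range(20))
    def test_noisy_fit_matches_independent_oracle(self, trial):
        """Gaussian pixel noise: center within 1 px, axes within 2%, and
        agreement with scikit-image's independent ellipse estimator."""
        rng = np.random.default_rng(1000 + trial)
        a, b = rng.uniform(150, 210), rng.uniform(120, 150)
        cy, cx = rng.uniform(240, 270, size=2)
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.column_stack([cy + b * np.sin(t), cx + a * np.cos(t)])
        pts += rng.normal(0, 1.0, size=pts.shape)
        e = fit_ellipse(pts)
        assert e.center == pytest.approx((cy, cx), abs=1.0)
        assert e.semi_axis_a == pytest.approx(a, rel=0.02)
        assert e.semi_axis_b == pytest.approx(b, rel=0.02)
        oracle = EllipseModel.from_estimate(pts[:, ::-1])  # (x, y) convention
        assert oracle
        oxc, oyc = oracle.center
        assert e.center == pytest.approx((oyc, oxc), abs=0.5)
        assert sorted([e.semi_axis_a, e.semi_axis_b]) == pytest.approx(
            sorted(oracle.axis_lengths), rel=0.01)


class TestRasterize:
    def test_circle_area_matches_analytic(self):
        e = EllipseParams(center=(256, 256), semi_axis_a=100, semi_axis_b=100)
        mask = rasterize_ellipse(e, (512, 512))
        assert mask.sum() == pytest.approx(math.pi * 100**2, rel=0.01)

    def test_tiny_ellipse_nonempty(self):
        e = EllipseParams(center=(10, 10), semi_axis_a=1, semi_axis_b=1)
        assert rasterize_ellipse(e, (20, 20)).sum() >= 1

    @pytest.mark.parametrize("trial", range(10))
    def test_fit_rasterize_roundtrip(self, trial):
        rng = np.random.default_rng(trial)
        e = EllipseParams(center=tuple(rng.uniform(220, 290, 2)),
                          semi_axis_a=rng.uniform(150, 200),
                          semi_axis_b=rng.uniform(100, 140),
                          rotation=rng.uniform(-0.3, 0.3))
        rec = fit_ellipse(extract_boundary(rasterize_ellipse(e, (512, 512))))
        assert rec.center == pytest.approx(e.center, abs=1.0)
        assert rec.semi_axis_a == pytest.approx(e.semi_axis_a, abs=1.0)
        assert rec.semi_axis_b == pytest.approx(e.semi_axis_b, abs=1.0)


class TestXor:
    def test_empty_pterygium_returns_cornea(self):
        c = disk_mask((64, 64), (32, 32), 20)
        assert (xor_masks(c, np.zeros_like(c)) == c).all()

    def test_identical_masks_cancel(self):
        c = disk_mask((64, 64), (32, 32), 20)
        assert not xor_masks(c, c).any()

    def test_subset_pixel_count_arithmetic(self):
        c = disk_mask((256, 256), (128, 128), 100)
        p = np.zeros_like(c)
        sel = np.argwhere(c)[:1000]
        p[sel[:, 0], sel[:, 1]] = True
        assert xor_masks(c, p).sum() == c.sum() - 1000

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            xor_masks(np.zeros((4, 4)), np.zeros((5, 5)))


class TestCenterRd:
    def test_disk(self):
        (cy, cx), rd = center_and_rd(disk_mask((512, 512), (256, 256), 100))
        assert (cy, cx) == pytest.approx((256, 256), abs=1)
        assert rd == pytest.approx(100, abs=1)

    def test_axis_aligned_ellipse_rd_is_transverse(self):
        e = EllipseParams(center=(256, 256), semi_axis_a=200, semi_axis_b=150)
        _, rd = center_and_rd(rasterize_ellipse(e, (512, 512)))
        assert rd == pytest.approx(200, abs=1)

    @pytest.mark.parametrize("trial", range(10))
    def test_translation_equivariance(self, trial):
        rng = np.random.default_rng(trial)
        dy, dx = rng.integers(-40, 40, size=2)
        base = disk_mask((512, 512), (256, 256), 90)
        moved = disk_mask((512, 512), (256 + dy, 256 + dx), 90)
        (cy0, cx0), _ = center_and_rd(base)
        (cy1, cx1), _ = center_and_rd(moved)
        assert (cy1 - cy0, cx1 - cx0) == pytest.approx((dy, dx), abs=0.51)


class TestMd:
    def test_full_disk_md_equals_radius(self):
        m = disk_mask((512, 512), (256, 256), 100)
        md = min_center_distance(m, (256, 256))
        assert md == pytest.approx(100, abs=1)

    def test_wedge_removed_to_depth(self):
        c = disk_mask((512, 512), (256, 256), 100)
        rr, cc = np.mgrid[0:512, 0:512]
        wedge = (cc - 256 >= 50) & (np.abs(rr - 256) <= (cc - 256 - 50) * 0.5)
        residual = c & ~wedge
        assert min_center_distance(residual, (256, 256)) == pytest.approx(50, abs=1)

    def test_single_pixel_at_center(self):
        m = np.zeros((64, 64), dtype=bool)
        m[32, 32] = True
        assert min_center_distance(m, (32, 32)) == 0.0

    def test_transverse_mode_ignores_vertical_minimum(self):
        e = EllipseParams(center=(256, 256), semi_axis_a=200, semi_axis_b=150)
        m = rasterize_ellipse(e, (512, 512))
        assert min_center_distance(m, (256, 256)) == pytest.approx(150, abs=1)
        assert min_center_distance(m, (256, 256), mode="transverse") == \
            pytest.approx(200, abs=1)


class TestFormulas:
    @pytest.mark.parametrize("rd,md,expected", [
        (208, 208, 0.0),
        (212, 106, 2.875),
        (212, 51, 4.366745283018868),
    ])
    def test_wp_worked_values(self, rd, md, expected):
        assert compute_wp(rd, md, 11.5) == pytest.approx(expected, abs=1e-9)

    def test_wp_validation(self):
        with pytest.raises(ValueError):
            compute_wp(100, 120, 11.5)
        with pytest.raises(ValueError):
            compute_wp(0, 0, 11.5)

    @pytest.mark.parametrize("ap,ac,expected", [
        (0, 100, 0.0),
        (100, 100, math.pi * 5.75**2),
        (10, 100, math.pi * 5.75**2 * 0.1),
    ])
    def test_area_worked_values(self, ap, ac, expected):
        assert compute_area_mm2(ap, ac, 11.5) == pytest.approx(expected)

    @pytest.mark.parametrize("wp,expected", [
        (0.0, 0), (1.43, 1), (2.999, 1), (3.0, 2), (4.68, 2)])
    def test_status_classes(self, wp, expected):
        assert classify_status(wp) == expected

    def test_wp_monotone_in_invasion_depth(self):
        wps = [compute_wp(200, md, 11.5) for md in range(200, -1, -10)]
        assert all(b > a for a, b in zip(wps, wps[1:]))


class TestMeasure:
    def _phantom(self, frac, side="right", size=512, a=200.0):
        return EyePhantomParams(
            image_height=size, image_width=size,
            cornea_center=(size / 2, size / 2), semi_axis_a=a, semi_axis_b=a,
            pterygium_side=side if frac > 0 else "none",
            invasion_fraction=frac)

    def test_no_pterygium_is_normal(self):
        s = generate_phantom(self._phantom(0.0), seed=0)
        r = measure(s.cornea_mask, s.pterygium_mask)
        assert (r.wp_mm, r.status, r.area_mm2) == (0.0, 0, 0.0)
        assert r.md_px == r.rd_px

    @pytest.mark.parametrize("frac,expected_wp,expected_cls", [
        (0.5, 2.875, 1), (0.8, 4.6, 2)])
    def test_invasion_recovers_closed_form(self, frac, expected_wp, expected_cls):
        s = generate_phantom(self._phantom(frac), seed=0)
        r = measure(s.cornea_mask, s.pterygium_mask)
        assert r.wp_mm == pytest.approx(expected_wp, abs=0.15)
        assert r.status == expected_cls

    def test_scale_invariance(self):
        p1 = self._phantom(0.6, size=256, a=100.0)
        p2 = self._phantom(0.6, size=512, a=200.0)
        r1 = measure(*_masks(p1))
        r2 = measure(*_masks(p2))
        assert abs(r1.wp_mm - r2.wp_mm) < 0.05

    def test_truth_and_measure_agree_on_random_phantoms(self):
        # working-resolution (512 px) phantoms keep rasterization error ~1%
        rng = np.random.default_rng(7)
        for _ in range(12):
            frac = rng.uniform(0.15, 0.85)
            p = self._phantom(frac, side="left" if rng.random() < 0.5 else "right",
                              size=512, a=float(rng.uniform(160, 220)))
            truth = truth_measurements(p)
            r = measure(*_masks(p))
            assert r.wp_mm == pytest.approx(truth.wp_mm, abs=0.15)
            assert r.area_mm2 == pytest.approx(truth.area_mm2, rel=0.03, abs=0.02)

    def test_empty_cornea_raises(self):
        with pytest.raises(EmptyMaskError):
            measure(np.zeros((64, 64), dtype=bool), np.zeros((64, 64), dtype=bool))


def _masks(params):
    s = generate_phantom(params, seed=3)
    return s.cornea_mask, s.pterygium_mask
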