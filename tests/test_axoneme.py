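import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exmquant import (
    CentroidTrack,
    EllipseFit,
    ImageStack,
    NoiseParams,
    ReferenceConstants,
    blur_correct,
    close_mask,
    equivalent_diameter,
    expansion_from_diameter,
    fit_ellipse,
    make_tube,
    perpendicularity_check,
    perpendicularity_threshold,
    plane_centroid,
    register_planes,
    run_axoneme_pipeline,
    sum_planes,
    threshold_isodata,
)
from exmquant.axoneme import (
    CorrectionError,
    DegenerateFitError,
    NoObjectError,
    RegistrationError,
    ThresholdUndefinedError,
)
from exmquant.image_model import ValidationError
from conftest import random_blob_mask


def brute_force_moment_ellipse(mask):
    """Independent second-moment ellipse: covariance eigenvalues of the pixel
    coordinates; full axes 4 sqrt(lambda)."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols]).astype(float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return 4.0 * np.sqrt(lam[0]), 4.0 * np.sqrt(lam[1]), c


class TestThreshold:
    def test_bimodal_image_segmented_to_high_jaccard(self, rng):
        truth = np.zeros((80, 80), dtype=bool)
        yy, xx = np.mgrid[0:80, 0:80]
        truth[(xx - 40) ** 2 + (yy - 40) ** 2 <= 15**2] = True
        img = rng.normal(10.0, 1.0, (80, 80))
        img[truth] = rng.normal(100.0, 1.0, int(truth.sum()))
        mask = threshold_isodata(img)
        jac = (mask & truth).sum() / (mask | truth).sum()
        assert jac >= 0.95

    def test_two_valued_image_threshold_between_classes(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        mask = threshold_isodata(img)
        assert np.array_equal(mask, img == 100.0)

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_mask_invariant_under_affine_intensity_map(self, a, b):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(5, 1, 600), rng.normal(40, 2, 200)])
        img = img.reshape(20, 40)
        assert np.array_equal(threshold_isodata(img), threshold_isodata(a * img + b))

    def test_agrees_with_histogram_isodata_reference(self, rng):
        from skimage.filters import threshold_isodata as sk_isodata

        img = np.concatenate([rng.normal(10, 1, 3000), rng.normal(100, 1, 500)])
        img = img.reshape(50, 70)
        mine = threshold_isodata(img)
        ref = img > sk_isodata(img)
        agree = (mine == ref).mean()
        assert agree > 0.999

    def test_constant_image_rejected(self):
        with pytest.raises(ThresholdUndefinedError):
            threshold_isodata(np.full((8, 8), 3.0))


class TestCloseMask:
    def test_one_pixel_pinhole_filled(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 10**2
        holed = disc.copy()
        holed[20, 20] = False
        assert close_mask(holed)[20, 20]

    def test_convex_disc_unchanged(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 10**2
        assert np.array_equal(close_mask(disc), disc)

    @pytest.mark.parametrize("seed", range(5))
    def test_closing_is_extensive(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng)
        closed = close_mask(mask)
        assert np.all(closed[mask])  # output contains input


class TestCentroid:
    def test_centred_disc_centroid_at_image_centre(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 10**2
        x, y = plane_centroid(disc, 70.0)
        assert x == pytest.approx(20 * 70.0, abs=35.0)
        assert y == pytest.approx(20 * 70.0, abs=35.0)

    def test_small_speck_ignored_in_favour_of_largest_component(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True  # 100 px
        mask[40:41, 40:45] = True  # 5 px
        x, y = plane_centroid(mask, 1.0)
        assert (x, y) == pytest.approx((14.5, 14.5))

    def test_translation_equivariance(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:20, 10:20] = True
        shifted = np.roll(np.roll(mask, 4, axis=0), 3, axis=1)
        x0, y0 = plane_centroid(mask, 70.0)
        x1, y1 = plane_centroid(shifted, 70.0)
        assert (x1 - x0, y1 - y0) == pytest.approx((3 * 70.0, 4 * 70.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(NoObjectError):
            plane_centroid(np.zeros((8, 8), dtype=bool), 70.0)


class TestPerpendicularity:
    def test_threshold_matches_printed_formula(self):
        # 4 x z-step / tan(85 deg) at 100 nm z-step: ~35.0 nm
        assert perpendicularity_threshold(100.0, 5.0) == pytest.approx(
            400.0 / math.tan(math.radians(85.0))
        )
        assert perpendicularity_threshold(100.0, 5.0) == pytest.approx(35.0, abs=0.01)

    @pytest.mark.parametrize("limit", [1.0, 5.0, 10.0])
    def test_cotangent_form_equals_tangent_form(self, limit):
        a = 4.0 * 100.0 / math.tan(math.radians(90.0 - limit))
        b = 4.0 * 100.0 * math.tan(math.radians(limit))
        assert perpendicularity_threshold(100.0, limit) == pytest.approx(a)
        assert a == pytest.approx(b)

    def test_static_centroids_pass(self):
        track = CentroidTrack(np.zeros((6, 2)), np.arange(6), 100.0)
        assert perpendicularity_check(track) == [True, True]

    def test_displacement_exactly_at_threshold_passes(self):
        thr = perpendicularity_threshold(100.0, 5.0)
        xy = np.zeros((5, 2))
        xy[4, 0] = thr
        track = CentroidTrack(xy, np.arange(5), 100.0)
        assert perpendicularity_check(track) == [True]

    def test_fewer_than_five_planes_rejected(self):
        track = CentroidTrack(np.zeros((4, 2)), np.arange(4), 100.0)
        with pytest.raises(ValidationError):
            perpendicularity_check(track)

    def test_three_degree_tube_passes_ten_degree_fails(self, mild_noise):
        verdicts = {}
        for tilt in (3.0, 10.0):
            stack, _ = make_tube(
                1056.0, tilt_deg=tilt, pixel_size_xy=50.0, field_size=128,
                noise=mild_noise, seed=3,
            )
            res = run_axoneme_pipeline(stack)
            verdicts[tilt] = [m.perpendicular for m in res]
        assert all(verdicts[3.0])
        assert not any(verdicts[10.0])


class TestRegistration:
    def test_zero_drift_yields_identity_transforms(self, mild_noise):
        stack, _ = make_tube(
            1056.0, pixel_size_xy=70.0, length_planes=5, noise=mild_noise, seed=6
        )
        _, transforms = register_planes(stack)
        for _, dy, dx in transforms:
            assert abs(dy) <= 0.25 and abs(dx) <= 0.25

    def test_known_drift_recovered_cumulatively(self, mild_noise):
        # (dx, dy) = (350, -210) nm/plane at 70 nm/px -> (5, -3) px per plane
        stack, _ = make_tube(
            1056.0, drift_per_plane=(350.0, -210.0), pixel_size_xy=70.0,
            field_size=128, length_planes=5, psf_fwhm_axial=1e-9,
            noise=mild_noise, seed=5,
        )
        _, transforms = register_planes(stack)
        for k, (_, dy, dx) in enumerate(transforms):
            assert dy == pytest.approx(3.0 * k, abs=0.5)
            assert dx == pytest.approx(-5.0 * k, abs=0.5)

    def test_registration_is_idempotent(self, mild_noise):
        stack, _ = make_tube(
            1056.0, drift_per_plane=(140.0, 0.0), pixel_size_xy=70.0,
            field_size=128, length_planes=5, psf_fwhm_axial=1e-9,
            noise=mild_noise, seed=8,
        )
        registered, _ = register_planes(stack)
        _, transforms = register_planes(registered)
        for _, dy, dx in transforms:
            assert abs(dy) <= 0.25 and abs(dx) <= 0.25

    def test_divergent_shift_rejected(self):
        rng = np.random.default_rng(0)
        base = rng.random((48, 48)) * 0.01
        yy, xx = np.mgrid[0:48, 0:48]
        planes = []
        for k in range(5):
            img = base.copy()
            img[(xx - 8 - 7 * k) ** 2 + (yy - 8) ** 2 <= 16] += 1.0
            planes.append(img)
        stack = ImageStack(np.stack(planes), 70.0, 100.0)
        with pytest.raises(RegistrationError):
            register_planes(stack, rotation_range_deg=0.0)


class TestSumPlanes:
    def test_five_identical_planes_sum_to_five_times_plane(self, rng):
        p = rng.random((20, 20))
        stack = ImageStack(np.stack([p] * 5), 70.0, 100.0)
        assert np.allclose(sum_planes(stack).pixels, 5.0 * p)

    def test_sum_equals_five_times_average_projection(self, rng):
        from exmquant import project

        stack = ImageStack(rng.random((5, 16, 16)), 70.0, 100.0)
        assert np.allclose(
            sum_planes(stack).pixels, 5.0 * project(stack, "average").pixels
        )

    def test_summing_raises_disc_snr_above_single_plane(self):
        noise = NoiseParams(gaussian_sd=0.1, poisson_scale=20.0)
        stack, _ = make_tube(
            1056.0, pixel_size_xy=70.0, length_planes=5, noise=noise, seed=9
        )
        clean, _ = make_tube(1056.0, pixel_size_xy=70.0, length_planes=5, seed=9)
        disc = clean.voxels[2] > 0.5
        bg = clean.voxels[2] < 0.01

        def snr(img, scale=1.0):
            return (img[disc].mean() - img[bg].mean()) / img[bg].std()

        summed = sum_planes(stack).pixels
        assert snr(summed) > snr(stack.voxels[2])


class TestEllipseFit:
    def test_rasterized_circle_is_circular_with_correct_area(self):
        yy, xx = np.mgrid[0:121, 0:121]
        disc = (xx - 60) ** 2 + (yy - 60) ** 2 <= 50**2
        fit = fit_ellipse(disc, 1.0)
        assert fit.aspect_ratio <= 1.02
        assert fit.area == pytest.approx(math.pi * 50**2, rel=0.02)

    def test_axis_aligned_ellipse_aspect_and_orientation(self):
        yy, xx = np.mgrid[0:201, 0:201]
        ell = (xx - 100) ** 2 / 60**2 + (yy - 100) ** 2 / 30**2 <= 1
        fit = fit_ellipse(ell, 1.0)
        assert fit.aspect_ratio == pytest.approx(2.0, abs=0.05)
        assert min(fit.orientation_deg, 180.0 - fit.orientation_deg) <= 2.0

    def test_rotation_leaves_aspect_ratio_unchanged(self):
        t = math.radians(30.0)
        yy, xx = np.mgrid[0:201, 0:201]
        u = (xx - 100) * math.cos(t) + (yy - 100) * math.sin(t)
        v = -(xx - 100) * math.sin(t) + (yy - 100) * math.cos(t)
        ell = u**2 / 60**2 + v**2 / 30**2 <= 1
        fit = fit_ellipse(ell, 1.0)
        assert fit.aspect_ratio == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(20))
    def test_moments_match_brute_force_to_1e6(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, n_seeds=4, dilations=4)
        from exmquant.axoneme import _largest_component

        comp = _largest_component(mask)
        fit = fit_ellipse(comp, 1.0)
        major, minor, centre = brute_force_moment_ellipse(comp)
        assert fit.major_axis == pytest.approx(major, rel=1e-6)
        assert fit.minor_axis == pytest.approx(minor, rel=1e-6)
        assert fit.centre[0] == pytest.approx(centre[1], rel=1e-6)
        assert fit.centre[1] == pytest.approx(centre[0], rel=1e-6)

    def test_one_pixel_wide_component_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 3:15] = True
        with pytest.raises(DegenerateFitError):
            fit_ellipse(mask, 1.0)


class TestDiameterAndFactor:
    def test_equivalent_diameter_inverts_circle_area(self):
        fit = EllipseFit(1060.0, 1060.0, 1.0, math.pi * 530.0**2, (0.0, 0.0))
        assert equivalent_diameter(fit) == pytest.approx(1060.0)

    def test_unit_area_circle(self):
        fit = EllipseFit(2.0, 2.0, 1.0, math.pi, (0.0, 0.0))
        assert equivalent_diameter(fit) == pytest.approx(2.0)

    def test_raster_disc_diameter_within_two_percent(self):
        yy, xx = np.mgrid[0:101, 0:101]
        disc = (xx - 50) ** 2 + (yy - 50) ** 2 <= 20**2
        fit = fit_ellipse(disc, 1.0)
        assert equivalent_diameter(fit) == pytest.approx(40.0, rel=0.02)

    def test_blur_correction_modes(self):
        assert blur_correct(1060.0, 200.0, "none") == 1060.0
        assert blur_correct(1060.0, 200.0, "quadrature") == pytest.approx(
            math.sqrt(1060.0**2 - 200.0**2)
        )
        assert blur_correct(1060.0, 200.0, "quadrature") == pytest.approx(1040.96, abs=0.01)
        assert blur_correct(1060.0, 200.0, "linear") == pytest.approx(860.0)

    def test_correction_below_blur_rejected(self):
        with pytest.raises(CorrectionError):
            blur_correct(150.0, 200.0, "quadrature")

    @pytest.mark.parametrize(
        "diameter,expected", [(1060.0, 4.8), (946.0, 4.3), (220.0, 1.0)]
    )
    def test_expansion_factor_from_diameter(self, diameter, expected):
        est = expansion_from_diameter(diameter)
        assert est.factor_1dp == expected
        assert est.method == "diameter_ratio"


class TestPipeline:
    def test_recovers_diameter_and_isotropy_of_perpendicular_tube(self, mild_noise):
        stack, _ = make_tube(1056.0, pixel_size_xy=70.0, noise=mild_noise, seed=2)
        res = run_axoneme_pipeline(stack, blur_mode="quadrature")
        ok = [m for m in res if m.perpendicular]
        assert ok
        mean_ar = np.mean([m.ellipse.aspect_ratio for m in ok])
        mean_f = np.mean([m.expansion_factor for m in ok])
        assert mean_ar <= 1.05
        assert mean_f == pytest.approx(1056.0 / 220.0, rel=0.05)

    def test_strongly_tilted_tube_yields_no_passing_window(self, mild_noise):
        stack, _ = make_tube(
            1056.0, tilt_deg=10.0, pixel_size_xy=50.0, field_size=128,
            noise=mild_noise, seed=3,
        )
        res = run_axoneme_pipeline(stack)
        assert res  # windows reported with their verdicts
        assert not any(m.perpendicular for m in res)
        assert all(m.ellipse is None for m in res)

    def test_anisotropy_detected_in_aspect_ratio(self, mild_noise):
        stack, _ = make_tube(
            1056.0, anisotropy_yx=1.3, pixel_size_xy=70.0, field_size=112,
            noise=mild_noise, seed=4,
        )
        ok = [m for m in run_axoneme_pipeline(stack) if m.perpendicular]
        mean_ar = np.mean([m.ellipse.aspect_ratio for m in ok])
        assert mean_ar == pytest.approx(1.3, rel=0.10)

    def test_aspect_ratio_monotone_in_anisotropy(self, mild_noise):
        ratios = []
        for a in (1.0, 1.1, 1.2, 1.3, 1.5):
            stack, _ = make_tube(
                1056.0, anisotropy_yx=a, pixel_size_xy=70.0, field_size=112,
                length_planes=5, noise=mild_noise, seed=4,
            )
            ok = [m for m in run_axoneme_pipeline(stack) if m.perpendicular]
            ratios.append(float(np.mean([m.ellipse.aspect_ratio for m in ok])))
        assert all(x < y for x, y in zip(ratios, ratios[1:]))

    @pytest.mark.parametrize("seed", range(20))
    def test_isotropy_null_noise_free_tubes_are_circular(self, seed):
        stack, _ = make_tube(
            1056.0, pixel_size_xy=70.0, field_size=64, length_planes=5, seed=seed
        )
        ok = [m for m in run_axoneme_pipeline(stack) if m.perpendicular]
        assert ok
        for m in ok:
            assert 1.0 <= m.ellipse.aspect_ratio <= 1.05

    def test_interval_shorter_than_window_rejected(self, mild_noise):
        stack, _ = make_tube(
            1056.0, pixel_size_xy=70.0, length_planes=6, noise=mild_noise, seed=0
        )
        with pytest.raises(ValidationError):
            run_axoneme_pipeline(stack, plane_interval=(0, 3))
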