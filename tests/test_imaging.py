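"""Tests for the volumetric image statistics (moments, fits, profiles,
pockets), anchored by uniform-ellipse and synthetic-mound oracles."""

from __future__ import annotations

import numpy as np
import pytest

from myxofruit.imaging import (
    DegenerateImageError,
    IntensityVolume,
    angular_profile,
    axes_vs_height,
    ellipse_fit,
    extract_plane,
    image_moments,
    isovolume_pockets,
    plane_intensity_distributions,
    radial_profile,
    to_grayscale,
)
from myxofruit.synth import MoundTruth, synth_ellipse_image, synth_mound_volume


class TestGrayscale:
    def test_neutral_gray_identity(self):
        img = np.full((4, 4, 3), 137, dtype=np.uint8)
        assert (to_grayscale(img) == 137).all()

    def test_black_maps_to_zero(self):
        assert (to_grayscale(np.zeros((3, 3, 3), dtype=np.uint8)) == 0).all()

    def test_pure_red_luminance(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert to_grayscale(img)[0, 0] == 76  # 0.299 * 255 rounded

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((3, 3, 2)))


class TestMoments:
    def test_single_pixel_centroid(self):
        img = np.zeros((10, 10))
        img[7, 3] = 42.0  # (x=3, y=7)
        m = image_moments(img)
        assert (m["xbar"], m["ybar"]) == (3.0, 7.0)
        assert m["mu20"] == m["mu02"] == m["mu11"] == 0.0

    def test_two_point_mass(self):
        img = np.zeros((5, 12))
        img[0, 0] = img[0, 10] = 3.0
        m = image_moments(img)
        assert (m["xbar"], m["ybar"]) == (5.0, 0.0)
        assert m["mu20"] / m["m00"] == pytest.approx(25.0)

    def test_translation_invariance_of_central_moments(self, rng):
        img = np.zeros((40, 40))
        img[10:18, 5:20] = rng.uniform(1, 255, (8, 15))
        shifted = np.roll(np.roll(img, 7, axis=0), 11, axis=1)
        m0, m1 = image_moments(img), image_moments(shifted)
        for k in ("mu20", "mu11", "mu02"):
            assert m1[k] == pytest.approx(m0[k], rel=1e-12)

    def test_zero_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            image_moments(np.zeros((5, 5)))


class TestEllipseFit:
    @pytest.mark.parametrize("a,b", [(10, 5), (30, 10), (50, 25), (40, 40)])
    @pytest.mark.parametrize("angle", [0.0, 40.0, 90.0, 130.0])
    def test_uniform_ellipse_recovery(self, a, b, angle):
        """Moment fit recovers a uniform ellipse: orientation within 1 degree,
        axes within 2%, centroid within 0.5 px."""
        img, truth = synth_ellipse_image(a, b, angle)
        fit = ellipse_fit(img)
        assert fit.semi_major == pytest.approx(a, rel=0.02)
        assert fit.semi_minor == pytest.approx(b, rel=0.02)
        assert abs(fit.centroid[0] - truth.center[0]) < 0.5
        assert abs(fit.centroid[1] - truth.center[1]) < 0.5
        assert fit.eccentricity == pytest.approx(truth.eccentricity, abs=0.01)
        if a > b:  # orientation undefined for circles
            diff = (fit.orientation_deg - angle + 90.0) % 180.0 - 90.0
            assert abs(diff) < 1.0

    def test_circle_flagged_isotropic(self):
        img, _ = synth_ellipse_image(20, 20)
        fit = ellipse_fit(img)
        assert fit.eccentricity < 0.05
        assert fit.degenerate

    def test_collinear_mass_is_degenerate_or_thin(self):
        img = np.zeros((20, 20))
        img[10, 2:18] = 50.0
        fit = ellipse_fit(img)
        assert fit.semi_minor < 0.1 or fit.degenerate


class TestRadialProfile:
    def test_constant_image_flat_profile(self):
        img, _ = synth_ellipse_image(25, 15, intensity=100)
        fit = ellipse_fit(img)
        rp = radial_profile(img, fit, n_rings=10, max_radius=0.9)
        assert np.allclose(rp.mean, 100.0)
        assert np.allclose(rp.sd, 0.0)

    def test_bright_ring_peaks_in_matching_annulus(self):
        from myxofruit.imaging import elliptical_radius

        img, _ = synth_ellipse_image(40, 30, intensity=100)
        fit = ellipse_fit(img)
        rho = elliptical_radius(img.shape, fit)
        img = img.astype(float)
        img[(rho > 0.55) & (rho < 0.65)] *= 2.0
        rp = radial_profile(img, ellipse_fit(img), n_rings=20, max_radius=1.0)
        assert 0.5 < rp.bin_edges[np.nanargmax(rp.mean)] < 0.7

    def test_annulus_counts_partition_outermost_ellipse(self):
        from myxofruit.imaging import elliptical_radius

        img, _ = synth_ellipse_image(30, 20)
        fit = ellipse_fit(img)
        rp = radial_profile(img, fit, n_rings=12, max_radius=1.4)
        rho = elliptical_radius(img.shape, fit)
        assert rp.count.sum() == (rho < 1.4).sum()

    def test_quarter_turn_consistency(self):
        img, _ = synth_ellipse_image(30, 12, angle_deg=25, noise_sd=10, seed=4)
        rot = np.rot90(img)
        p0 = radial_profile(img, ellipse_fit(img), n_rings=10, max_radius=1.0)
        p1 = radial_profile(rot, ellipse_fit(rot), n_rings=10, max_radius=1.0)
        assert np.allclose(p0.mean, p1.mean, rtol=1e-9, equal_nan=True)

    def test_invalid_ring_count(self):
        img, _ = synth_ellipse_image(10, 5)
        with pytest.raises(ValueError):
            radial_profile(img, ellipse_fit(img), n_rings=0)


class TestAngularProfile:
    def test_rotationally_symmetric_image(self):
        n = 101
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - 50, yy - 50)
        img = np.where(r < 40, 200.0 - r, 0.0)
        ap = angular_profile(img, (50.0, 50.0), sector_width_deg=10, mask=r < 40)
        assert np.nanstd(ap.mean) / np.nanmean(ap.mean) < 0.005

    def test_dark_wedge_detected(self):
        n = 101
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - 50, yy - 50)
        ang = np.degrees(np.arctan2(yy - 50, xx - 50)) % 360
        img = np.where(r < 40, 200.0, 0.0)
        img[(ang > 75) & (ang < 105) & (r < 40)] = 50.0
        ap = angular_profile(img, (50.0, 50.0), sector_width_deg=10, mask=r < 40)
        centers = 0.5 * (ap.sector_edges_deg[:-1] + ap.sector_edges_deg[1:])
        assert centers[np.nanargmin(ap.mean)] == pytest.approx(90.0, abs=10.0)

    def test_sector_counts_partition_mask(self):
        img, _ = synth_ellipse_image(20, 12, intensity=150)
        mask = img > 0
        ap = angular_profile(img, (26.0, 26.0), sector_width_deg=15, mask=mask)
        assert ap.count.sum() == mask.sum()

    def test_non_divisor_width_rejected(self):
        with pytest.raises(ValueError):
            angular_profile(np.ones((5, 5)), (2, 2), sector_width_deg=7)


class TestPlaneHistograms:
    def test_constant_plane_point_mass(self):
        vol = IntensityVolume(np.full((2, 8, 8), 140, dtype=np.uint8))
        h = plane_intensity_distributions(vol)[0]
        assert h.counts[140] == 64
        assert h.counts.sum() == 64

    def test_normalized_histogram_sums_to_one(self):
        vol, _ = synth_mound_volume(seed=5)
        for h in plane_intensity_distributions(vol, (0, 5)):
            assert h.normalized.sum() == pytest.approx(1.0)

    def test_smoothing_conserves_mass(self):
        vol, _ = synth_mound_volume(seed=6)
        for h in plane_intensity_distributions(vol, (0, 5)):
            assert h.smoothed.sum() == pytest.approx(h.counts.sum(), abs=1e-9)


class TestAxesVsHeight:
    def test_cone_taper_slopes(self):
        # base semi-axes (60, 40) µm tapering to zero at 90 µm: slopes
        # -2/3 and -4/9 µm/µm
        vol, _ = synth_mound_volume(MoundTruth(noise_sd=0.0), seed=0)
        tr = axes_vs_height(vol)
        assert tr.slope_major_um_per_um == pytest.approx(-60 / 90, rel=0.10)
        assert tr.slope_minor_um_per_um == pytest.approx(-40 / 90, rel=0.10)
        assert tr.r2_major > 0.98 and tr.r2_minor > 0.98

    def test_cylinder_has_flat_axes(self):
        data = np.zeros((20, 41, 41), dtype=np.uint8)
        yy, xx = np.mgrid[0:41, 0:41]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2
        data[:, disc] = 130
        tr = axes_vs_height(IntensityVolume(data))
        assert abs(tr.slope_major_um_per_um) < 1e-6
        assert abs(tr.slope_minor_um_per_um) < 1e-6

    def test_too_few_planes_rejected(self):
        data = np.zeros((4, 20, 20), dtype=np.uint8)
        data[0, 5:15, 5:15] = 100
        with pytest.raises(ValueError):
            axes_vs_height(IntensityVolume(data))


class TestPockets:
    def test_single_sphere_equivalent_diameter(self):
        data = np.full((30, 30, 30), 2, dtype=np.uint8)
        zz, yy, xx = np.mgrid[0:30, 0:30, 0:30]
        r = np.sqrt((xx - 15.0) ** 2 + (yy - 15.0) ** 2 + (zz - 15.0) ** 2)
        data[r <= 10.0 / 3.3] = 200  # 20 µm diameter at 3.3 µm voxels
        table = isovolume_pockets(IntensityVolume(data), 100)
        assert len(table) == 1
        assert table.equiv_diameter_um.iloc[0] == pytest.approx(20.0, abs=2.0)

    def test_disjoint_pockets_counted_separately(self):
        data = np.full((20, 20, 20), 2, dtype=np.uint8)
        data[3:6, 3:6, 3:6] = 200
        data[14:17, 14:17, 14:17] = 200
        assert len(isovolume_pockets(IntensityVolume(data), 100)) == 2

    def test_isovalue_above_maximum_empty(self):
        vol = IntensityVolume(np.full((5, 5, 5), 100, dtype=np.uint8))
        assert isovolume_pockets(vol, 200).empty

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_pocket_recovery(self, seed):
        """Five planted pockets (12-25 µm) are recovered individually with
        diameters within 20% when thresholding halfway up the boost."""
        vol, truth = synth_mound_volume(n_pockets=5, seed=seed)
        table = isovolume_pockets(
            vol, truth.base_intensity + truth.pocket_boost / 2, min_voxels=5
        )
        assert abs(len(table) - 5) <= 1
        rec = np.sort(table.equiv_diameter_um.to_numpy())
        true = np.sort([d for _, d in truth.pockets])
        if len(rec) == 5:
            assert (np.abs(rec - true) / true < 0.20).all()


class TestVolumeAccess:
    def test_extract_plane_bounds(self):
        vol, _ = synth_mound_volume(seed=1)
        assert extract_plane(vol, 0).shape == vol.data.shape[1:]
        with pytest.raises(IndexError):
            extract_plane(vol, vol.n_planes)

    def test_base_plane_largest_cross_section(self):
        vol, _ = synth_mound_volume(MoundTruth(noise_sd=0.0), seed=1)
        areas = [(vol.data[z] >= 10).sum() for z in range(vol.n_planes)]
        assert np.argmax(areas) == 0

    def test_plane_above_apex_is_background(self):
        vol, truth = synth_mound_volume(MoundTruth(noise_sd=0.0), seed=1)
        assert (extract_plane(vol, vol.n_planes - 1) < 10).all()
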