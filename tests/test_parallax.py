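"""Parallax pipeline: disk finding, shift measurement, fitting, splatting."""

import numpy as np
import pytest

from tcbfstem.optics import AberrationSurface, OpticalConfig, shift_field_model
from tcbfstem import parallax as par
from tcbfstem.parallax import (
    BFMask,
    DataCube4D,
    Reconstruction,
    ShiftField,
    correct_kernel_rolloff,
    dpc_images,
    find_bf_disk,
    fit_aberration_surface,
    fourier_downsample,
    measure_shifts,
    radial_power_spectrum,
    reconstruct_tcbf,
    regularize_shifts,
    virtual_image,
)


class TestDataCube4D:
    def test_validation(self):
        with pytest.raises(ValueError):
            DataCube4D(counts=np.zeros((4, 4, 8)), scan_step=8.0,
                       det_pixel=1e-3)
        with pytest.raises(ValueError):
            DataCube4D(counts=np.zeros((2, 2, 4, 4)), scan_step=-1.0,
                       det_pixel=1e-3)

    def test_default_center_and_angles(self):
        cube = DataCube4D(counts=np.zeros((2, 2, 5, 5)), scan_step=8.0,
                          det_pixel=1e-3)
        assert cube.det_center == (2.0, 2.0)
        ty, tx = cube.detector_angles()
        assert tx[2, 4] == pytest.approx(2e-3)
        assert ty[0, 2] == pytest.approx(-2e-3)


class TestFindBfDisk:
    def test_center_and_radius(self, small_cube, small_cube_truth):
        mask = find_bf_disk(small_cube)
        alpha = small_cube_truth["alpha"]
        assert mask.radius_rad == pytest.approx(alpha, rel=0.05)
        # simulator stores the true optic-axis position
        dy = np.hypot(mask.center[0] - small_cube.det_center[0],
                      mask.center[1] - small_cube.det_center[1])
        assert dy < 0.5

    def test_updates_cube_center(self, small_cube):
        before = small_cube.det_center
        mask = find_bf_disk(small_cube, update_center=True)
        assert small_cube.det_center == mask.center
        small_cube.det_center = before

    def test_empty_pattern_rejected(self):
        cube = DataCube4D(counts=np.zeros((2, 2, 8, 8)), scan_step=8.0,
                          det_pixel=1e-3)
        with pytest.raises(ValueError):
            find_bf_disk(cube)

    def test_threshold_validated(self, small_cube):
        with pytest.raises(ValueError):
            find_bf_disk(small_cube, threshold=1.5)

    def test_edge_weights(self, small_cube):
        mask = find_bf_disk(small_cube)
        w = mask.edge_weights(margin=1.0)
        assert set(np.unique(w)) <= {0.0, 0.5, 1.0}
        assert np.all(w[~mask.mask] == 0.0)


class TestVirtualImage:
    def test_mask_and_list_agree(self, small_cube):
        mask = find_bf_disk(small_cube)
        a = virtual_image(small_cube, mask.mask)
        b = virtual_image(small_cube, list(map(tuple, np.argwhere(mask.mask))))
        np.testing.assert_allclose(a, b)

    def test_wrong_mask_shape(self, small_cube):
        with pytest.raises(ValueError):
            virtual_image(small_cube, np.ones((3, 3), dtype=bool))


class TestMeasureShifts:
    def test_recovers_defocus_shifts(self, small_cube, small_cube_truth):
        mask = find_bf_disk(small_cube)
        sf = measure_shifts(small_cube, mask, upsample=20, max_iter=3)
        fit = fit_aberration_surface(sf)
        # the 16x16 smoke fixture has a 128-A field and ~130 BF pixels, so
        # registration noise caps the fit quality below what the larger
        # acceptance-geometry cubes reach (see test_acceptance)
        assert fit.surface.defocus == pytest.approx(
            small_cube_truth["defocus"], rel=0.03)
        assert fit.r_squared > 0.97

    def test_axial_pixel_zero(self, small_cube):
        mask = find_bf_disk(small_cube)
        sf = measure_shifts(small_cube, mask, upsample=20, max_iter=2)
        ay, ax = par._axial_pixel(mask)
        assert sf.wy[ay, ax] == 0.0 and sf.wx[ay, ax] == 0.0

    def test_contrast_free_rejected(self):
        cube = DataCube4D(counts=np.ones((8, 8, 8, 8)), scan_step=8.0,
                          det_pixel=1e-3)
        mask = BFMask(mask=np.ones((8, 8), dtype=bool), center=(3.5, 3.5),
                      radius_px=4.0, det_pixel=1e-3)
        with pytest.raises(ValueError, match="contrast"):
            measure_shifts(cube, mask)

    def test_too_few_pixels_rejected(self, small_cube):
        m = np.zeros(small_cube.detector_shape, dtype=bool)
        m[0, 0] = True
        mask = BFMask(mask=m, center=(0.0, 0.0), radius_px=1.0,
                      det_pixel=small_cube.det_pixel)
        with pytest.raises(ValueError, match="fewer"):
            measure_shifts(small_cube, mask)


def synthetic_shift_field(ab, alpha=4e-3, det=15, det_pixel=None, noise=0.0,
                          seed=0, weights=None):
    det_pixel = det_pixel or (2.2 * alpha / det)
    c = (det - 1) / 2.0
    ty = (np.arange(det) - c)[:, None] * det_pixel * np.ones((1, det))
    tx = (np.arange(det) - c)[None, :] * det_pixel * np.ones((det, 1))
    mask = np.hypot(ty, tx) <= alpha
    wx, wy = shift_field_model(ab, tx, ty)
    rng = np.random.default_rng(seed)
    wx = np.where(mask, wx + noise * rng.normal(size=wx.shape), np.nan)
    wy = np.where(mask, wy + noise * rng.normal(size=wy.shape), np.nan)
    w = np.where(mask, 1.0, 0.0) if weights is None else weights
    return ShiftField(wy=wy, wx=wx, weights=w, mask=mask, theta_y=ty,
                      theta_x=tx, scan_step=8.0)


class TestFitAberrationSurface:
    def test_exact_recovery_with_astig(self):
        ab = AberrationSurface(defocus=9000.0, astig=600.0, astig_angle=0.7)
        sf = synthetic_shift_field(ab)
        fit = fit_aberration_surface(sf)
        assert fit.surface.defocus == pytest.approx(9000.0, rel=1e-9)
        assert fit.surface.astig == pytest.approx(600.0, rel=1e-9)
        assert fit.surface.astig_angle == pytest.approx(0.7, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rms == pytest.approx(0.0, abs=1e-9)

    def test_offset_nuisance_absorbed(self):
        ab = AberrationSurface(defocus=9000.0)
        sf = synthetic_shift_field(ab)
        sf.wx += 3.0
        sf.wy -= 2.0
        fit = fit_aberration_surface(sf)
        assert fit.surface.defocus == pytest.approx(9000.0, rel=1e-9)
        assert fit.offset[0] == pytest.approx(-2.0, abs=1e-9)
        assert fit.offset[1] == pytest.approx(3.0, abs=1e-9)

    def test_order_one(self):
        ab = AberrationSurface(defocus=9000.0)
        fit = fit_aberration_surface(synthetic_shift_field(ab), order=1)
        assert fit.surface.defocus == pytest.approx(9000.0, rel=1e-9)
        assert fit.surface.astig == 0.0

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            fit_aberration_surface(
                synthetic_shift_field(AberrationSurface()), order=3)

    def test_rank_deficient(self):
        sf = synthetic_shift_field(AberrationSurface(defocus=9000.0))
        keep = np.zeros_like(sf.mask)
        keep[7, 7] = True  # single axial pixel cannot constrain the model
        sf.weights = np.where(keep, 1.0, 0.0)
        sf.mask = keep
        with pytest.raises(ValueError, match="rank"):
            fit_aberration_surface(sf)


class TestRegularizeShifts:
    def test_blend_unit_confidence_is_identity(self):
        ab = AberrationSurface(defocus=9000.0)
        sf = synthetic_shift_field(ab, noise=1.0)
        fit = fit_aberration_surface(sf)
        out = regularize_shifts(sf, fit, mode="blend")
        np.testing.assert_allclose(out.wx[sf.mask], sf.wx[sf.mask])
        np.testing.assert_allclose(out.wy[sf.mask], sf.wy[sf.mask])

    def test_replace_gives_model(self):
        ab = AberrationSurface(defocus=9000.0)
        sf = synthetic_shift_field(ab, noise=2.0, seed=3)
        fit = fit_aberration_surface(sf)
        out = regularize_shifts(sf, fit, mode="replace")
        wx_m, wy_m = shift_field_model(fit.surface, sf.theta_x, sf.theta_y)
        np.testing.assert_allclose(out.wx[sf.mask],
                                   (wx_m + fit.offset[1])[sf.mask])
        np.testing.assert_allclose(out.wy[sf.mask],
                                   (wy_m + fit.offset[0])[sf.mask])

    def test_unknown_mode(self):
        sf = synthetic_shift_field(AberrationSurface(defocus=9000.0))
        with pytest.raises(ValueError):
            regularize_shifts(sf, AberrationSurface(), mode="average")


def splat_oracle(images, offsets, weights, s, out_shape):
    """Reference bilinear splat, one sample at a time."""
    acc = np.zeros(out_shape)
    cov = np.zeros(out_shape)
    for img, (oy, ox), w in zip(images, offsets, weights):
        if w <= 0:
            continue
        for iy in range(img.shape[0]):
            for ix in range(img.shape[1]):
                fy, fx = iy * s + oy, ix * s + ox
                y0, x0 = int(np.floor(fy)), int(np.floor(fx))
                ry, rx = fy - y0, fx - x0
                for dy, cy in ((0, 1 - ry), (1, ry)):
                    for dx, cx in ((0, 1 - rx), (1, rx)):
                        if cy * cx == 0:
                            continue
                        yy = (y0 + dy) % out_shape[0]
                        xx = (x0 + dx) % out_shape[1]
                        acc[yy, xx] += w * cy * cx * img[iy, ix]
                        cov[yy, xx] += w * cy * cx
    return acc, cov


class TestReconstruct:
    def test_zero_shift_equals_weighted_mean(self, small_cube):
        mask = find_bf_disk(small_cube)
        pix = np.argwhere(mask.mask)
        sf = ShiftField(
            wy=np.where(mask.mask, 0.0, np.nan),
            wx=np.where(mask.mask, 0.0, np.nan),
            weights=mask.mask.astype(float), mask=mask.mask,
            theta_y=small_cube.detector_angles()[0],
            theta_x=small_cube.detector_angles()[1],
            scan_step=small_cube.scan_step)
        rec = reconstruct_tcbf(small_cube, sf, upsample=1)
        expected = virtual_image(small_cube, mask.mask) / len(pix)
        np.testing.assert_allclose(rec.image, expected, rtol=1e-12)
        np.testing.assert_allclose(rec.image, rec.uncorrected, rtol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        scan, det_n, s = (6, 6), 5, 3
        counts = rng.random((*scan, det_n, det_n))
        cube = DataCube4D(counts=counts, scan_step=8.0, det_pixel=1e-3)
        mask = np.ones((det_n, det_n), dtype=bool)
        wy = rng.uniform(-12, 12, (det_n, det_n))
        wx = rng.uniform(-12, 12, (det_n, det_n))
        w = rng.uniform(0.2, 1.0, (det_n, det_n))
        ty, tx = cube.detector_angles()
        sf = ShiftField(wy=wy, wx=wx, weights=w, mask=mask, theta_y=ty,
                        theta_x=tx, scan_step=8.0)
        rec = reconstruct_tcbf(cube, sf, upsample=s)
        pix = np.argwhere(mask)
        images = [counts[:, :, dy, dx] for dy, dx in pix]
        offsets = [(-wy[dy, dx] * s / 8.0, -wx[dy, dx] * s / 8.0)
                   for dy, dx in pix]
        weights = [w[dy, dx] for dy, dx in pix]
        acc, cov = splat_oracle(images, offsets, weights, s,
                                (scan[0] * s, scan[1] * s))
        np.testing.assert_allclose(rec.coverage, cov, rtol=1e-10)
        np.testing.assert_allclose(rec.image, np.where(cov > 0, acc / cov, 0),
                                   rtol=1e-9)

    def test_sparse_coverage_warns(self, rng):
        counts = rng.random((4, 4, 3, 3))
        cube = DataCube4D(counts=counts, scan_step=8.0, det_pixel=1e-3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        ty, tx = cube.detector_angles()
        sf = ShiftField(wy=np.zeros((3, 3)), wx=np.zeros((3, 3)),
                        weights=mask.astype(float), mask=mask, theta_y=ty,
                        theta_x=tx, scan_step=8.0)
        with pytest.warns(UserWarning, match="coverage"):
            reconstruct_tcbf(cube, sf, upsample=4)

    def test_invalid_upsample(self, small_cube):
        mask = find_bf_disk(small_cube)
        sf = ShiftField(wy=np.zeros(small_cube.detector_shape),
                        wx=np.zeros(small_cube.detector_shape),
                        weights=mask.mask.astype(float), mask=mask.mask,
                        theta_y=small_cube.detector_angles()[0],
                        theta_x=small_cube.detector_angles()[1],
                        scan_step=small_cube.scan_step)
        with pytest.raises(ValueError):
            reconstruct_tcbf(small_cube, sf, upsample=0)

    def test_correction_sharpens(self, small_cube):
        mask = find_bf_disk(small_cube)
        sf = measure_shifts(small_cube, mask, upsample=20, max_iter=3)
        fit = fit_aberration_surface(sf)
        reg = regularize_shifts(sf, fit, mode="replace")
        rec = reconstruct_tcbf(small_cube, reg, upsample=1)
        assert rec.image.var() > 5 * rec.uncorrected.var()


class TestKernelRolloff:
    def test_divides_by_sinc_squared(self, small_cube):
        mask = find_bf_disk(small_cube)
        sf = measure_shifts(small_cube, mask, upsample=10, max_iter=1)
        rec = reconstruct_tcbf(small_cube, sf, upsample=2)
        out = correct_kernel_rolloff(rec)
        F_in = np.fft.fft2(rec.image)
        F_out = np.fft.fft2(out.image)
        fy = np.fft.fftfreq(rec.image.shape[0])[:, None]
        fx = np.fft.fftfreq(rec.image.shape[1])[None, :]
        mtf = np.sinc(fy) ** 2 * np.sinc(fx) ** 2
        np.testing.assert_allclose(F_out * mtf, F_in, atol=1e-9 *
                                   np.abs(F_in).max())
        assert out.pixel_size == rec.pixel_size
        assert out.upsample == rec.upsample

    def test_boosts_band_edge(self):
        # a Nyquist-frequency checkerboard gains amplitude (2/pi)^-4
        img = ((-1.0) ** (np.arange(16)[:, None] + np.arange(16)[None, :]))
        rec = Reconstruction(image=img, coverage=np.ones((16, 16)),
                             uncorrected=img, pixel_size=8.0, upsample=1)
        out = correct_kernel_rolloff(rec)
        np.testing.assert_allclose(out.image, img * (np.pi / 2) ** 4,
                                   rtol=1e-10)


class TestFourierDownsample:
    def test_preserves_in_band_sinusoid(self):
        x = np.arange(64)
        img = np.cos(2 * np.pi * 3 * x[None, :] / 64) * np.ones((64, 1))
        down = fourier_downsample(img, 4)
        xd = np.arange(16)
        expected = np.cos(2 * np.pi * 3 * xd[None, :] / 16) * np.ones((16, 1))
        np.testing.assert_allclose(down, expected, atol=1e-10)

    def test_removes_out_of_band_sinusoid(self):
        x = np.arange(64)
        img = np.cos(2 * np.pi * 20 * x[None, :] / 64) * np.ones((64, 1))
        down = fourier_downsample(img, 4)
        np.testing.assert_allclose(down, 0.0, atol=1e-10)

    def test_mean_preserved(self, rng):
        img = rng.random((32, 32))
        assert fourier_downsample(img, 2).mean() == pytest.approx(img.mean())

    def test_factor_validation(self, rng):
        img = rng.random((32, 32))
        with pytest.raises(ValueError):
            fourier_downsample(img, 0)
        with pytest.raises(ValueError):
            fourier_downsample(img, 5)


class TestRadialPowerSpectrum:
    def test_sinusoid_peak(self):
        n, period = 64, 8.0
        x = np.arange(n)
        img = np.cos(2 * np.pi * x[None, :] / period) * np.ones((n, 1))
        prof = radial_power_spectrum(img, pixel_size=1.0, n_bins=32)
        assert prof.freq[np.argmax(prof.power)] == pytest.approx(
            1.0 / period, abs=prof.freq[1] - prof.freq[0])

    def test_mean_removed(self):
        prof = radial_power_spectrum(np.full((32, 32), 7.0), 1.0)
        assert np.max(prof.power) == pytest.approx(0.0, abs=1e-20)


class TestDpcImages:
    def test_shapes_and_keys(self, small_cube):
        mask = find_bf_disk(small_cube)
        out = dpc_images(small_cube, mask)
        assert set(out) == {"dpc_x", "dpc_y", "idpc"}
        for v in out.values():
            assert v.shape == small_cube.scan_shape

    def test_symmetric_pattern_gives_zero_dpc(self):
        # rotationally symmetric patterns carry no first-moment signal
        det = np.zeros((9, 9))
        yy, xx = np.mgrid[0:9, 0:9]
        det[np.hypot(yy - 4, xx - 4) <= 3] = 1.0
        counts = np.tile(det, (4, 4, 1, 1))
        cube = DataCube4D(counts=counts, scan_step=8.0, det_pixel=1e-3)
        mask = BFMask(mask=det > 0, center=(4.0, 4.0), radius_px=3.0,
                      det_pixel=1e-3)
        out = dpc_images(cube, mask)
        np.testing.assert_allclose(out["dpc_x"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["dpc_y"], 0.0, atol=1e-12)
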