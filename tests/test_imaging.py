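"""Unit and property tests for the 2-D OSL image-correction chain."""

import numpy as np
import pytest

from lmposl import imaging, synthdata
from lmposl.imaging import DetectorGeometry, DetectorImage, Role

from conftest import make_disc_image, make_uniform_image


class TestDriftCorrection:
    @pytest.mark.parametrize(
        "rate, t, value, expected",
        [
            (0.0, 5.0, 1100.0, 1100.0),   # zero-rate identity
            (0.1, 0.0, 1100.0, 1100.0),   # first-frame reference
            (0.1, 1.0, 1100.0, 1000.0),   # divisive model: 1100 / 1.1
        ],
    )
    def test_divisive_model(self, rate, t, value, expected):
        img = make_uniform_image(value, n=64, acquired_at=t)
        out = imaging.correct_drift(img, rate)
        np.testing.assert_allclose(out.pixels, expected)
        assert out.role == img.role and out.detector_id == img.detector_id

    def test_negative_elapsed_time_rejected(self):
        img = make_uniform_image(10, n=16, acquired_at=-0.5)
        with pytest.raises(ValueError, match="mis-ordered"):
            imaging.correct_drift(img, 0.1)


class TestBackgroundSubtraction:
    def test_self_subtraction_is_zero(self):
        a = make_uniform_image(500, n=32, detector_id="d")
        b = make_uniform_image(500, n=32, detector_id="d", role=Role.BACKGROUND)
        assert imaging.subtract_background(a, b).pixels.max() == 0

    def test_constant_shift_and_clipping(self):
        sig = make_uniform_image(500, n=32, detector_id="d")
        bg_px = np.full((32, 32), 120.0)
        bg_px[3, 7] = 510.0  # exceeds the signal by 10 -> clips to 0
        bg = DetectorImage(bg_px, detector_id="d", role=Role.BACKGROUND)
        out = imaging.subtract_background(sig, bg)
        assert out.pixels[3, 7] == 0.0
        assert out.pixels[0, 0] == 380.0

    def test_detector_pairing_enforced(self):
        sig = make_uniform_image(500, n=16, detector_id="d1")
        bg = make_uniform_image(100, n=16, detector_id="d2", role=Role.BACKGROUND)
        with pytest.raises(ValueError, match="pairing mismatch"):
            imaging.subtract_background(sig, bg)


class TestLocateDetector:
    def test_disc_centre_and_radius_recovered(self):
        lv = make_disc_image(cx=400.0, cy=610.0, radius=280.0, role=Role.LIVEVIEW)
        geom = imaging.locate_detector(lv)
        assert abs(geom.centre_x - 400.0) < 1.0
        assert abs(geom.centre_y - 610.0) < 1.0
        assert abs(geom.radius - 280.0) < 2.0

    def test_uniform_frame_has_no_contour(self):
        lv = make_uniform_image(100, n=256, role=Role.LIVEVIEW)
        with pytest.raises(ValueError, match="no detector found"):
            imaging.locate_detector(lv)

    @pytest.mark.parametrize("angle", [90.0, -45.0, 170.0])
    def test_marker_angle_from_rim_notch(self, angle):
        lv = make_disc_image(radius=300.0, marker_angle=angle, role=Role.LIVEVIEW)
        geom = imaging.locate_detector(lv)
        delta = (geom.marker_angle - angle + 180.0) % 360.0 - 180.0
        assert abs(delta) < 2.0

    def test_noisy_background_does_not_swallow_the_disc(self, rng):
        # the 30% quantile sits below the background median, so >half of the
        # noisy background is above threshold; the opening must still isolate
        # the disc as the largest component
        lv = make_disc_image(cx=480, cy=540, radius=300, value=8000, background=0)
        noisy = lv.pixels + rng.poisson(100.0, size=lv.pixels.shape)
        geom = imaging.locate_detector(DetectorImage(noisy, role=Role.LIVEVIEW))
        assert abs(geom.centre_x - 480) < 1.5
        assert abs(geom.centre_y - 540) < 1.5


class TestFlatField:
    def test_uniform_flat_is_identity(self):
        sig = make_uniform_image(700.0)
        flat = make_uniform_image(30000.0, role=Role.FLAT)
        np.testing.assert_allclose(
            imaging.flat_field_correct(sig, flat).pixels, 700.0)

    def test_bright_flat_pixel_halves_signal(self):
        sig = make_uniform_image(700.0)
        fl = np.full((1024, 1024), 1000.0)
        fl[512, 700] = 2000.0  # twice the central mean (to rounding)
        flat = DetectorImage(fl, role=Role.FLAT)
        out = imaging.flat_field_correct(sig, flat)
        assert out.pixels[512, 700] == pytest.approx(350.0, rel=1e-3)
        assert out.pixels[20, 20] == pytest.approx(700.0, rel=1e-3)

    def test_vignette_round_trip(self):
        n = 1024
        yy, xx = np.ogrid[:n, :n]
        r2 = ((xx - 512) ** 2 + (yy - 512) ** 2) / (2.0 * 512.0**2)
        vignette = 1.0 - 0.2 * r2  # 20% radial falloff at the corner
        scene = 900.0
        sig = DetectorImage(scene * vignette)
        flat = DetectorImage(30000.0 * vignette, role=Role.FLAT)
        out = imaging.flat_field_correct(sig, flat)
        roi = imaging.disk_mask(n, 512, 512, 300)
        vals = out.pixels[roi]
        assert (vals.max() - vals.min()) / vals.mean() < 0.01

    def test_zero_flat_pixel_in_roi_rejected(self):
        sig = make_uniform_image(700.0)
        fl = np.full((1024, 1024), 1000.0)
        fl[512, 512] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            imaging.flat_field_correct(sig, DetectorImage(fl, role=Role.FLAT))

    def test_literal_gain_imprints_pattern(self):
        sig = make_uniform_image(700.0)
        fl = np.full((1024, 1024), 1000.0)
        fl[100, 100] = 2000.0
        out = imaging.flat_field_correct(sig, DetectorImage(fl, role=Role.FLAT),
                                         literal_gain=True)
        assert out.pixels[100, 100] == pytest.approx(1400.0, rel=1e-3)


class TestAlignment:
    def test_identity_transform(self):
        img = make_disc_image(radius=280.0, value=1000.0, background=0.0)
        geom = DetectorGeometry(512.0, 512.0, 280.0, 0.0)
        out = imaging.align_detector(img, geom)
        interior = imaging.disk_mask(1024, 512, 512, 270)
        np.testing.assert_allclose(out.pixels[interior], img.pixels[interior],
                                   atol=1e-6)

    def test_centroid_moves_to_frame_centre(self):
        img = make_disc_image(cx=400.0, cy=610.0, radius=280.0, background=0.0)
        geom = imaging.locate_detector(img.replace(role=Role.LIVEVIEW))
        out = imaging.align_detector(img, geom)
        mask = out.pixels > 500
        ys, xs = np.nonzero(mask)
        assert abs(xs.mean() - 512.0) < 0.5
        assert abs(ys.mean() - 512.0) < 0.5

    def test_marker_rotates_to_top(self):
        img = make_disc_image(radius=300.0, marker_angle=90.0, background=0.0,
                              role=Role.LIVEVIEW)
        geom = imaging.locate_detector(img)
        out = imaging.align_detector(img, geom)
        geom_after = imaging.locate_detector(out)
        assert abs(geom_after.marker_angle) < 2.0

    def test_relocalisation_is_a_contraction(self):
        img = make_disc_image(cx=460.0, cy=575.0, radius=290.0, marker_angle=30.0,
                              role=Role.LIVEVIEW)
        geom = imaging.locate_detector(img)
        aligned = imaging.align_detector(img, geom)
        geom2 = imaging.locate_detector(aligned)
        assert abs(geom2.centre_x - 512.0) <= 1.0
        assert abs(geom2.centre_y - 512.0) <= 1.0

    def test_roi_mean_preserved_for_radial_scene(self):
        # radially symmetric scene about the detector centre
        n = 1024
        cx, cy = 450.0, 580.0
        yy, xx = np.ogrid[:n, :n]
        rho = np.hypot(xx - cx, yy - cy)
        px = 1000.0 * np.exp(-((rho / 400.0) ** 2))
        img = DetectorImage(px)
        before = px[imaging.disk_mask(n, cx, cy, 300)].mean()
        out = imaging.align_detector(img, DetectorGeometry(cx, cy, 300.0, 25.0))
        after = imaging.extract_osl(out).mean
        assert abs(after / before - 1.0) < 0.005


class TestExtractOsl:
    def test_uniform_field(self):
        osl = imaging.extract_osl(make_uniform_image(321.5))
        assert osl.mean == pytest.approx(321.5)
        assert osl.sd == 0.0

    def test_half_and_half_mean(self):
        px = np.full((1024, 1024), 100.0)
        px[:, 512:] = 300.0  # symmetric split through the ROI centre column?
        img = DetectorImage(px)
        osl = imaging.extract_osl(img)
        # brute-force oracle over the same mask
        mask = imaging.disk_mask(1024, 512, 512, 300)
        assert osl.mean == pytest.approx(px[mask].mean())
        assert osl.mean == pytest.approx(200.0, abs=0.5)

    def test_gaussian_mean_within_sampling_error(self, rng):
        px = rng.normal(250.0, 10.0, size=(1024, 1024)).clip(min=0)
        osl = imaging.extract_osl(DetectorImage(px))
        assert abs(osl.mean - 250.0) < 3 * 10.0 / np.sqrt(osl.n_pixels)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            imaging.extract_osl(make_uniform_image(1, n=64), roi_radius=0)


class TestProcessStack:
    def _mini_session(self, doses, cam, seed=5, interval=0.2):
        rng = np.random.default_rng(seed)
        frames = [synthdata.render_flat(cam, 0.0, rng)]
        t = interval
        for i, dose in enumerate(doses):
            det = f"d{i:02d}"
            geom = synthdata.random_geometry(cam, rng, max_offset_px=30)
            frames.append(synthdata.render_liveview(geom, cam, t, rng, det))
            frames.append(synthdata.render_detector_frame(
                dose, geom, cam, t, rng, Role.SIGNAL, det))
            t += interval
            frames.append(synthdata.render_detector_frame(
                0.0, geom, cam, t, rng, Role.BACKGROUND, det))
            t += interval
        return frames

    def test_linear_closed_loop_and_drift_independence(self):
        cam = synthdata.CameraModel(vignette_strength=0.08).noiseless()
        doses = [2.0, 5.0, 10.0, 20.0]
        table = imaging.process_stack(self._mini_session(doses, cam),
                                      drift_rate=cam.drift_rate)
        assert table["error"].isna().all()
        ratio = table["mean"].to_numpy() / np.asarray(doses)
        # means proportional to dose, independent of the staggered timestamps
        assert ratio.std() / ratio.mean() < 0.005

    def test_missing_background_yields_error_row_only(self):
        cam = synthdata.CameraModel().noiseless()
        frames = self._mini_session([3.0, 6.0], cam)
        frames = [f for f in frames
                  if not (f.detector_id == "d01" and f.role is Role.BACKGROUND)]
        table = imaging.process_stack(frames, drift_rate=cam.drift_rate)
        assert table.set_index("detector_id").loc["d01", "error"] is not None
        assert table.set_index("detector_id").loc["d00", "error"] is None

    def test_drift_correct_before_subtract_matches_commutative_result(self):
        # signal and background acquired at different times: correcting both
        # frames first reproduces the true net signal; subtracting raw frames
        # does not
        cam = synthdata.CameraModel(vignette_strength=0.0).noiseless()
        rng = np.random.default_rng(0)
        geom = DetectorGeometry(512.0, 512.0, 330.0, 0.0)
        sig = synthdata.render_detector_frame(8.0, geom, cam, 4.0, rng,
                                              Role.SIGNAL, "d")
        bg = synthdata.render_detector_frame(0.0, geom, cam, 6.0, rng,
                                             Role.BACKGROUND, "d")
        net = imaging.subtract_background(imaging.correct_drift(sig, 0.1),
                                          imaging.correct_drift(bg, 0.1))
        expected = cam.signal_per_gray * 8.0
        centre_val = net.pixels[512, 512]
        assert centre_val == pytest.approx(expected, rel=0.005)
        raw = imaging.subtract_background(sig, bg)
        assert abs(raw.pixels[512, 512] - expected) / expected > 0.05
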