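"""Normalisation, flat-field, large-feature removal, stitching."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import gaussian_spot
from iscatflow.preprocess import (ContrastImage, FlatField, RawFrame,
                                  build_flat_field, estimate_offset,
                                  flat_field_correct, normalize_counts,
                                  preprocess_frame, remove_large_features,
                                  stitch_scan)
from iscatflow.synthetic import (CameraModel, OpticsModel, illumination_seed,
                                 make_flatfield_frames, make_scene,
                                 random_particles, render_scan)


class TestNormalize:
    def test_constant_frame(self):
        out = normalize_counts(RawFrame(np.full((32, 32), 1000.0)))
        assert np.allclose(out.pixels, 1.0)

    def test_robust_to_sparse_spots(self):
        """Spots covering <2% of pixels shift the scale by <0.5%."""
        rng = np.random.default_rng(0)
        pix = np.full((128, 128), 1000.0)
        idx = rng.choice(128 * 128, size=300, replace=False)
        pix.flat[idx] *= 1.5
        out = normalize_counts(RawFrame(pix))
        assert np.median(out.pixels) == pytest.approx(1.0, rel=0.005)

    def test_zero_frame_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(RawFrame(np.zeros((16, 16))))


class TestFlatField:
    def test_median_of_identical_frames(self):
        pix = 1.0 + 0.1 * np.random.default_rng(1).random((64, 64))
        frames = [RawFrame(pix) for _ in range(60)]
        ff = build_flat_field(frames)
        assert np.allclose(ff.pixels, pix / pix.mean(), rtol=1e-6)

    def test_too_few_frames_strict(self):
        frames = [RawFrame(np.ones((16, 16)))] * 10
        with pytest.raises(ValueError, match="at least 60"):
            build_flat_field(frames)

    def test_too_few_frames_permissive_warns(self):
        frames = [RawFrame(np.ones((16, 16)))] * 10
        with pytest.warns(UserWarning):
            build_flat_field(frames, strict=False)

    def test_recovers_illumination_from_spotted_frames(self):
        """Median across 60 frames with disjoint random spots recovers the
        shared illumination within 1% everywhere."""
        optics = OpticsModel(fov_pixels=128)
        camera = CameraModel(shot_noise_enabled=False)
        frames = make_flatfield_frames(optics, camera, n_frames=60, seed=7)
        ff = build_flat_field([normalize_counts(f) for f in frames])
        truth = make_scene([], optics, seed=0,
                           illum_seed=illumination_seed(7))
        illum = truth.illumination_field / truth.illumination_field.mean()
        assert np.max(np.abs(ff.pixels / illum - 1)) < 0.01


class TestFlatFieldCorrect:
    def test_self_division(self):
        pix = 1.0 + 0.05 * np.random.default_rng(2).random((32, 32))
        out = flat_field_correct(RawFrame(pix), FlatField(pix, 60))
        assert np.allclose(out.pixels, 1.0, atol=1e-6)
        assert out.stage == "flatfielded"

    def test_exact_algebra(self):
        flat = 1.0 + 0.1 * np.random.default_rng(3).random((64, 64))
        spot = gaussian_spot((64, 64), 32, 32, 1.9, 0.02)
        frame = RawFrame(flat * (1.0 + spot))
        out = flat_field_correct(frame, FlatField(flat, 60))
        assert np.max(np.abs(out.pixels - (1.0 + spot))) < 1e-6

    def test_zero_flat_pixel_rejected(self):
        flat = np.ones((16, 16)); flat[3, 3] = 0.0
        with pytest.raises(ValueError):
            flat_field_correct(RawFrame(np.ones((16, 16))),
                               FlatField(flat, 60))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            flat_field_correct(RawFrame(np.ones((16, 16))),
                               FlatField(np.ones((8, 8)), 60))


class TestRemoveLargeFeatures:
    def _img(self, pix):
        return ContrastImage(pix, stage="flatfielded")

    def test_constant_to_zero(self):
        out = remove_large_features(self._img(np.full((64, 64), 1.0)))
        assert np.allclose(out.pixels, 0.0)
        assert out.stage == "background_removed"

    def test_psf_scale_spot_preserved(self):
        """17-px median filter attenuates a PSF-sized spot peak by <2%
        (oracle: direct median-filter computation on the analytic spot)."""
        spot = gaussian_spot((64, 64), 31.5, 30.5, 1.9, 0.02)
        out = remove_large_features(self._img(1.0 + spot))
        oracle = (1.0 + spot) - ndimage.median_filter(
            (1.0 + spot).astype(np.float32), 17, mode="reflect")
        assert np.allclose(out.pixels, oracle, atol=1e-7)
        assert out.pixels.max() == pytest.approx(spot.max(), rel=0.02)

    def test_broad_blob_suppressed(self):
        blob = gaussian_spot((256, 256), 128, 128, 30.0, 0.05)
        out = remove_large_features(self._img(1.0 + blob))
        assert np.abs(out.pixels).max() < 0.1 * 0.05

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            remove_large_features(self._img(np.ones((64, 64))), kernel=16)

    def test_median_subtraction_zero_centres(self):
        rng = np.random.default_rng(4)
        img = self._img(1.0 + 1e-3 * rng.standard_normal((128, 128)))
        out = remove_large_features(img)
        assert abs(np.median(out.pixels)) < 1e-4


def test_stage_order_roundtrip(rendered_scene_512):
    """normalise -> flat-field -> background removal recovers the known
    particle contrast field within shot-noise bounds."""
    d = rendered_scene_512
    img = preprocess_frame(d["frame"], d["flat"])
    p = d["optics"].pixel_size_um
    for part in d["particles"][:10]:
        r, c = int(round(part.y_um / p)), int(round(part.x_um / p))
        window = img.pixels[r - 1:r + 2, c - 1:c + 2]
        rec = window.flat[np.argmax(np.abs(window))]
        # sub-pixel peak sampling attenuates up to ~9%; noise sigma 5e-4
        assert rec == pytest.approx(part.contrast, rel=0.12, abs=3e-3)


class TestEstimateOffset:
    def test_self_correlation(self):
        img = np.random.default_rng(5).standard_normal((128, 128))
        est = estimate_offset(img, img)
        assert (est.dy, est.dx) == (0.0, 0.0)
        assert not est.low_confidence

    def test_integer_shift_exact(self):
        base = np.pad(np.random.default_rng(6).standard_normal((150, 150)),
                      25)
        a = base[25:125, 25:125]
        b = base[20:120, 28:128]  # content of a moved +5 rows, -3 cols
        est = estimate_offset(a, b)
        assert (est.dy, est.dx) == (5.0, -3.0)

    def test_subpixel_shift(self):
        rng = np.random.default_rng(7)
        img = np.zeros((128, 128))
        for _ in range(40):
            x0, y0 = rng.uniform(15, 113, 2)
            img += gaussian_spot((128, 128), x0, y0, 1.6)
        shifted = ndimage.shift(img, (5.3, -2.7), order=3)
        est = estimate_offset(img, shifted)
        assert abs(est.dy - 5.3) < 0.5 and abs(est.dx + 2.7) < 0.5

    def test_blank_frame_flagged(self):
        blank = np.zeros((64, 64))
        est = estimate_offset(blank, blank, nominal=(10.0, 0.0))
        assert est.low_confidence and (est.dy, est.dx) == (10.0, 0.0)


class TestStitch:
    def _contrast(self, pix):
        return ContrastImage(pix, stage="flatfielded")

    def test_single_frame(self):
        pix = np.random.default_rng(8).standard_normal((64, 64))
        m = stitch_scan([self._contrast(pix)],
                        {"grid": [1, 1], "nominal_step_px": [0, 0]})
        assert np.array_equal(m.pixels, pix.astype(np.float32))
        assert m.valid_mask.all()

    def test_noiseless_scan_roundtrip(self):
        """2x2 noiseless synthetic scan with +-2 px jitter: stitched
        pixels equal the ground-truth canvas on the valid mask."""
        optics = OpticsModel(fov_pixels=64, illumination_inhomogeneity=0.0,
                             flat_top_diameter_um=1e6)
        camera = CameraModel(shot_noise_enabled=False)
        extent = (45 + 64 + 4, 45 + 64 + 4)
        # dense enough that every overlap strip carries several spots
        parts = random_particles(0, 120, optics, seed=9, extent_px=extent,
                                 margin_px=4, min_separation_px=4)
        truth = make_scene(parts, optics, camera, seed=9, extent_px=extent)
        scan = render_scan(truth, (2, 2), overlap_fraction=0.3,
                           stage_jitter_px=2, seed=10)
        imgs = [self._contrast(f.pixels / 1000.0) for f in scan.frames]
        mosaic = stitch_scan(imgs, scan.layout)
        # recovered offsets match the applied ones up to a common shift
        applied = np.array(scan.layout["applied_offsets_px"], dtype=float)
        applied -= applied.min(axis=0)
        got = np.array(mosaic.offsets_px)
        assert np.allclose(np.rint(got), applied)
        assert np.abs(got - applied).max() < 0.5
        # pixel-level agreement with the truth canvas
        origin = (np.array(scan.layout["applied_offsets_px"]).min(axis=0)
                  + 2)  # + jitter margin
        canvas_crop = scan.canvas[
            origin[0]:origin[0] + mosaic.pixels.shape[0],
            origin[1]:origin[1] + mosaic.pixels.shape[1]]
        diff = np.abs(mosaic.pixels - canvas_crop)[mosaic.valid_mask]
        assert diff.max() < 1e-5

    def test_blank_frame_falls_back_to_nominal(self):
        rng = np.random.default_rng(11)
        good = rng.standard_normal((64, 64))
        blank = np.zeros((64, 64))
        with np.errstate(all="ignore"):
            m = stitch_scan([self._contrast(good), self._contrast(blank)],
                            {"grid": [1, 2], "nominal_step_px": [0, 58]})
        assert m.flags[1] == "low_confidence"
        assert m.offsets_px[1] == (0.0, 58.0)
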