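"""Noise model, segmentation and localisation against brute-force and
ground-truth oracles."""

import math

import numpy as np
import pytest

from conftest import gaussian_spot
from iscatflow.detect import (Candidate, NoiseModel, detect_particles,
                              estimate_noise, localize_spot, measure_contrast,
                              merge_localisations, radial_symmetry_center,
                              segment_candidates, snr_map)


# ---------------------------------------------------------------------------
# brute-force oracles (independent per-pixel implementations)
# ---------------------------------------------------------------------------

def mad_sigma_bruteforce(pix):
    med = np.median(pix)
    return 1.4826 * np.median(np.abs(pix - med))


def local_rms_bruteforce(pix, kernel=65, inlier=2.5):
    sg = mad_sigma_bruteforce(pix)
    k2 = kernel // 2
    pad = np.pad(pix, k2, mode="symmetric")
    mask = np.abs(pad) <= inlier * sg
    out = np.empty_like(pix, dtype=float)
    for r in range(pix.shape[0]):
        for c in range(pix.shape[1]):
            w = pad[r:r + kernel, c:c + kernel]
            m = mask[r:r + kernel, c:c + kernel]
            if m.mean() < 0.10:
                out[r, c] = sg
            else:
                out[r, c] = math.sqrt((w[m] ** 2).mean())
    return np.maximum(out, 0.1 * sg)


def segment_bruteforce(snr, threshold, min_cluster):
    """Components by BFS 8-connectivity; survival by exhaustive 3x3-window
    enumeration; peaks with row-then-column tie break."""
    mask = snr >= threshold
    visited = np.zeros_like(mask, dtype=bool)
    peaks = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or visited[r0, c0]:
                continue
            comp = []
            stack = [(r0, c0)]
            visited[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and mask[rr, cc] and not visited[rr, cc]):
                            visited[rr, cc] = True
                            stack.append((rr, cc))
            comp_set = set(comp)
            ok = False
            for wr in range(-2, rows):
                for wc in range(-2, cols):
                    n_in = sum((wr + i, wc + j) in comp_set
                               for i in range(3) for j in range(3))
                    if n_in >= min_cluster:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                best = max(comp, key=lambda rc: (snr[rc], -rc[0], -rc[1]))
                peaks.append(best)
    return sorted(peaks)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

class TestEstimateNoise:
    def test_mad_consistency_on_gaussian(self):
        rng = np.random.default_rng(0)
        pix = 1e-3 * rng.standard_normal((512, 512))
        nm = estimate_noise(pix)
        assert nm.sigma_global == pytest.approx(1e-3, rel=0.02)

    def test_local_map_tracks_ramp(self):
        """sigma ramping 1e-3 -> 2e-3 left to right: the local map follows
        its closed-form expectation within 5% away from the edges.

        The estimator is an RMS over pixels inside +-2.5 sigma_global, i.e.
        a truncated RMS: for local truth sigma its expectation is
        sigma * sqrt(1 - 2 k phi(k) / (2 Phi(k) - 1)) with
        k = 2.5 sigma_global / sigma.  Where sigma <= sigma_global the
        truncation is negligible and the map tracks the truth itself.
        """
        from scipy import stats
        rng = np.random.default_rng(1)
        n = 512
        truth = np.linspace(1e-3, 2e-3, n)[None, :]
        pix = truth * rng.standard_normal((n, n))
        nm = estimate_noise(pix)
        kappa = 2.5 * nm.sigma_global / truth
        shrink = np.sqrt(1 - 2 * kappa * stats.norm.pdf(kappa)
                         / (2 * stats.norm.cdf(kappa) - 1))
        expected = np.broadcast_to(truth * shrink, (n, n))
        inner = slice(64, n - 64)
        ratio = nm.sigma_local[inner, inner] / expected[inner, inner]
        assert np.all(np.abs(ratio - 1) < 0.05)
        # the map rises monotonically with the ramp on average
        col_mean = nm.sigma_local[inner, inner].mean(axis=0)
        # truncation caps the apparent rise below the true 2x ramp
        assert col_mean[-1] > 1.3 * col_mean[0]

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_noise(np.full((64, 64), 0.5))

    def test_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(2)
        pix = 1e-3 * rng.standard_normal((64, 64))
        pix[20:23, 30:33] += 0.05  # a spot excluded by the inlier rule
        nm = estimate_noise(pix)
        oracle = local_rms_bruteforce(pix)
        assert nm.sigma_global == pytest.approx(mad_sigma_bruteforce(pix),
                                                rel=1e-12)
        assert np.allclose(nm.sigma_local, oracle, rtol=1e-9)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def _noise(self, shape, sigma):
        return NoiseModel(sigma, np.full(shape, sigma))

    def test_subthreshold_image_empty(self):
        rng = np.random.default_rng(3)
        pix = 1e-3 * rng.standard_normal((64, 64)) * 0.8
        nm = self._noise(pix.shape, 1e-3)
        pix = np.clip(pix, -3.4e-3, 3.4e-3)  # max SNR 3.5
        assert segment_candidates(pix, nm, snr_threshold=4) == []

    def test_single_spot_single_candidate(self):
        pix = gaussian_spot((64, 64), 30, 25, 1.9, 8e-3)
        nm = self._noise(pix.shape, 1e-3)
        cands = segment_candidates(pix, nm)
        assert len(cands) == 1
        assert cands[0].peak == (25, 30)

    def test_isolated_pixels_rejected_by_cluster_rule(self):
        pix = np.zeros((64, 64))
        pix[10, 10] = 5e-3
        pix[10, 20] = 5e-3
        nm = self._noise(pix.shape, 1e-3)
        assert segment_candidates(pix, nm) == []

    def test_matches_bruteforce_on_random_instances(self):
        """SNR map and segmentation agree exactly with the per-pixel
        oracle on random 64x64 instances."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pix = 1e-3 * rng.standard_normal((64, 64))
            for _ in range(6):
                x0, y0 = rng.uniform(5, 58, 2)
                amp = rng.choice([-1, 1]) * rng.uniform(4e-3, 2e-2)
                pix += gaussian_spot((64, 64), x0, y0, 1.6, amp)
            nm = estimate_noise(pix, kernel=31)
            smap = snr_map(pix, nm)
            assert np.allclose(smap, np.abs(pix) / nm.sigma_local,
                               rtol=1e-12)
            got = sorted(c.peak for c in segment_candidates(pix, nm))
            assert got == segment_bruteforce(smap, 4.0, 3)

    def test_both_polarities_detected(self):
        pix = (gaussian_spot((64, 64), 15, 15, 1.9, 8e-3)
               - gaussian_spot((64, 64), 45, 45, 1.9, 8e-3))
        nm = self._noise(pix.shape, 1e-3)
        peaks = sorted(c.peak for c in segment_candidates(pix, nm))
        assert peaks == [(15, 15), (45, 45)]


# ---------------------------------------------------------------------------
# localisation
# ---------------------------------------------------------------------------

class TestLocalize:
    def test_noiseless_subpixel_accuracy(self):
        roi = gaussian_spot((21, 21), 10.30, 7.75, 1.9)
        x, y, ok = radial_symmetry_center(roi)
        assert ok
        assert abs(x - 10.30) < 0.02 and abs(y - 7.75) < 0.02

    def test_pixel_centred_symmetry(self):
        roi = gaussian_spot((15, 15), 7, 7, 1.9)
        x, y, ok = radial_symmetry_center(roi)
        assert x == pytest.approx(7.0, abs=1e-9)
        assert y == pytest.approx(7.0, abs=1e-9)

    def test_translation_equivariance(self):
        """Shifting ROI content by whole pixels shifts the centre by the
        same amount."""
        img = np.zeros((64, 64))
        img += gaussian_spot((64, 64), 30.37, 28.81, 1.9, 0.02)
        c1 = Candidate((0, 0, 0, 0), (29, 30), 10.0, 9)
        x1, y1, _ = localize_spot(img, c1)
        shifted = np.roll(np.roll(img, 7, axis=0), -4, axis=1)
        c2 = Candidate((0, 0, 0, 0), (36, 26), 10.0, 9)
        x2, y2, _ = localize_spot(shifted, c2)
        assert abs((x2 - x1) + 4) < 1e-6
        assert abs((y2 - y1) - 7) < 1e-6

    def test_monte_carlo_precision_at_snr10(self):
        """RMSE < 0.15 px at peak SNR 10 over 500 noisy draws."""
        rng = np.random.default_rng(4)
        sigma_noise = 1e-3
        errs = []
        for _ in range(500):
            x0 = 10 + rng.uniform(-0.5, 0.5)
            y0 = 10 + rng.uniform(-0.5, 0.5)
            roi = gaussian_spot((21, 21), x0, y0, 1.9, 10 * sigma_noise)
            roi += sigma_noise * rng.standard_normal(roi.shape)
            x, y, _ = radial_symmetry_center(roi)
            errs.append((x - x0) ** 2 + (y - y0) ** 2)
        rmse = math.sqrt(np.mean(errs) / 2.0)
        assert rmse < 0.15

    def test_flat_roi_falls_back_to_centroid(self):
        img = np.zeros((32, 32))
        cand = Candidate((0, 0, 0, 0), (16, 16), 5.0, 3)
        x, y, flags = localize_spot(img, cand)
        assert "centroid_fallback" in flags

    def test_edge_candidate_flagged(self):
        img = gaussian_spot((32, 32), 2, 2, 1.9, 0.02)
        cand = Candidate((0, 0, 0, 0), (2, 2), 8.0, 5)
        x, y, flags = localize_spot(img, cand)
        assert "edge_clipped" in flags
        assert abs(x - 2) < 0.5 and abs(y - 2) < 0.5


class TestMeasureContrast:
    def test_sign_handling(self):
        img = -gaussian_spot((32, 32), 16, 16, 1.9, 0.01)
        c, integ = measure_contrast(img, (16.0, 16.0))
        assert c == pytest.approx(-0.01, rel=1e-6)
        assert integ < 0

    def test_zero_roi(self):
        assert measure_contrast(np.zeros((32, 32)), (16.0, 16.0)) == (0.0,
                                                                      0.0)

    def test_integrated_exceeds_peak_for_extended_spot(self):
        img = gaussian_spot((32, 32), 16, 16, 1.9, 0.02)
        c, integ = measure_contrast(img, (16.0, 16.0))
        assert integ > c > 0


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

class TestDetectParticles:
    def test_recovers_constructed_spots(self):
        rng = np.random.default_rng(5)
        pix = 5e-4 * rng.standard_normal((256, 256))
        spots = [(40.3, 60.7, 0.02), (120.1, 33.6, -0.015),
                 (200.9, 210.2, 0.008)]
        for x0, y0, amp in spots:
            pix += gaussian_spot((256, 256), x0, y0, 1.63, amp)
        locs = detect_particles(pix, pixel_size_um=0.065)
        assert len(locs) == 3
        locs = locs.sort_values("x_px").reset_index(drop=True)
        for (x0, y0, amp), (_, row) in zip(sorted(spots),
                                           locs.iterrows()):
            assert abs(row.x_px - x0) < 0.3 and abs(row.y_px - y0) < 0.3
            assert row.contrast == pytest.approx(amp, rel=0.15)

    def test_count_monotone_in_contrast(self):
        """At fixed noise, raising every particle's contrast never loses
        detections."""
        rng = np.random.default_rng(6)
        noise = 5e-4 * rng.standard_normal((256, 256))
        xs = rng.uniform(15, 240, 12)
        ys = rng.uniform(15, 240, 12)
        counts = []
        for scale in (1.0, 2.0, 4.0):
            pix = noise.copy()
            for x0, y0 in zip(xs, ys):
                pix += gaussian_spot((256, 256), x0, y0, 1.63,
                                     scale * 2.2e-3)
            counts.append(len(detect_particles(pix)))
        assert counts == sorted(counts)

    def test_merging_idempotent_and_order_independent(self):
        import pandas as pd
        locs = pd.DataFrame({
            "x_px": [10.0, 10.5, 50.0], "y_px": [10.0, 10.2, 50.0],
            "snr": [8.0, 6.0, 9.0]})
        merged = merge_localisations(locs)
        assert len(merged) == 2
        assert set(merged["snr"]) == {8.0, 9.0}
        again = merge_localisations(merged)
        assert len(again) == 2
        shuffled = merge_localisations(locs.iloc[::-1])
        assert set(shuffled["snr"]) == {8.0, 9.0}
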