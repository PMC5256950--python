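"""Cluster detection: filters, labelling oracle, density recovery."""

import numpy as np
import pytest

from nanoflim.clusters import (
    bandpass_subtract,
    detect_clusters,
    pool_summaries,
    receptors_per_cluster,
    roi_bleach_trace,
    rolling_ball_subtract,
    summarize_clusters,
    threshold_label,
)
from nanoflim.containers import FrameStack
from nanoflim.simulate import MembraneSimParams, render_spots, simulate_membrane_stack


def _spot_frame(centers, amp=1200.0, shape=(96, 96), sigma_px=110 / 130):
    return render_spots(shape, centers, amp, sigma_px)


class TestBackgroundFilters:
    def test_rolling_ball_constant_to_zero(self):
        out = rolling_ball_subtract(np.full((64, 64), 37.0), 10)
        assert np.allclose(out, 0.0)

    def test_rolling_ball_preserves_spike(self):
        img = np.full((64, 64), 20.0)
        img[30, 30] += 500.0
        out = rolling_ball_subtract(img, 10)
        assert out[30, 30] == pytest.approx(500.0, rel=0.01)

    def test_rolling_ball_radius_exceeding_image(self):
        img = np.full((32, 32), 5.0)
        img[10, 10] = 25.0
        out = rolling_ball_subtract(img, radius=100)
        assert np.allclose(out, img - 5.0)

    def test_bandpass_constant_to_zero(self):
        out = bandpass_subtract(np.full((64, 64), 80.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_bandpass_suppresses_ramp(self):
        ramp = np.linspace(0, 1000, 256)[None, :] * np.ones((256, 1))
        out = bandpass_subtract(ramp)
        margin = 50  # away from the reflective boundary
        assert np.abs(out[margin:-margin, margin:-margin]).max() < 10.0

    def test_bandpass_delta_attenuation_closed_form(self):
        # a delta spike loses exactly the blur kernel's central weight,
        # ~ 1/(2 pi sigma_px^2) for a continuous Gaussian
        img = np.zeros((128, 128))
        img[64, 64] = 1000.0
        sigma_px = 2.0 * 1000 / 130.0
        out = bandpass_subtract(img, sigma_um=2.0, pixel_size_nm=130.0)
        expected = 1000.0 * (1 - 1 / (2 * np.pi * sigma_px**2))
        assert out[64, 64] == pytest.approx(expected, rel=1e-3)


class TestThresholdLabel:
    def test_all_below_threshold(self):
        cs = threshold_label(np.full((32, 32), 10.0), threshold=80)
        assert len(cs) == 0

    def test_isolated_pixels_removed_by_min_area(self):
        # a homogeneous-marker-style image leaves only single pixels, all
        # removed by the 2-px minimum area
        frame = np.zeros((64, 64))
        frame[::4, ::4] = 200.0
        assert len(threshold_label(frame, min_area=2)) == 0
        assert len(threshold_label(frame, min_area=1)) == 16 * 16

    def test_two_blobs_counted(self):
        frame = np.zeros((32, 32))
        frame[2:5, 2:5] = 100.0
        frame[20:23, 20:23] = 100.0
        cs = threshold_label(frame, threshold=80)
        assert len(cs) == 2
        assert sorted(r.area_px for r in cs.records) == [9, 9]

    def test_roi_polygon_restricts_analysis(self):
        frame = np.zeros((40, 40))
        frame[5:8, 5:8] = 100.0
        frame[30:33, 30:33] = 100.0
        roi = np.array([[0, 0], [0, 20], [20, 20], [20, 0]])  # upper-left box
        cs = threshold_label(frame, roi=roi)
        assert len(cs) == 1
        assert cs.roi_area_um2 < 40 * 40 * 0.0169

    def test_flood_fill_oracle_equivalence(self):
        # component counts/sizes match a recursive flood fill on random masks
        def flood_count(mask):
            seen = np.zeros_like(mask, dtype=bool)
            sizes = []
            for i in range(mask.shape[0]):
                for j in range(mask.shape[1]):
                    if mask[i, j] and not seen[i, j]:
                        stack, size = [(i, j)], 0
                        seen[i, j] = True
                        while stack:
                            y, x = stack.pop()
                            size += 1
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    yy, xx = y + dy, x + dx
                                    if (0 <= yy < mask.shape[0]
                                            and 0 <= xx < mask.shape[1]
                                            and mask[yy, xx]
                                            and not seen[yy, xx]):
                                        seen[yy, xx] = True
                                        stack.append((yy, xx))
                        sizes.append(size)
            return sorted(sizes)

        rng = np.random.default_rng(123)
        for _ in range(1000):
            mask = rng.random((16, 16)) < 0.4
            cs = threshold_label(mask * 100.0, threshold=50, min_area=1)
            assert sorted(r.area_px for r in cs.records) == flood_count(mask)

    def test_threshold_monotonicity(self):
        # raising the threshold never increases the count on spot images
        centers = [(r, c) for r in (15, 45, 75) for c in (15, 45, 75)]
        frame = _spot_frame(centers)
        counts = [len(threshold_label(frame, threshold=t))
                  for t in (10, 20, 40, 80, 160, 240, 300)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_equivariance(self):
        centers = [(30.2, 33.7), (60.5, 20.1)]
        frame = _spot_frame(centers, shape=(96, 96))
        shifted = np.roll(np.roll(frame, 7, axis=0), 11, axis=1)
        a = threshold_label(frame).centroids
        b = threshold_label(shifted).centroids
        a = a[np.lexsort(a.T)]
        b = b[np.lexsort(b.T)] - np.array([7, 11])
        assert np.allclose(a, b, atol=1e-9)


class TestSummaries:
    def test_density_arithmetic(self):
        frame = np.zeros((60, 60))
        for k in range(9):
            r, c = 6 * (k // 3) + 2, 20 * (k % 3) + 2
            frame[r:r + 2, c:c + 2] = 100.0
        cs = threshold_label(frame, threshold=80)
        s = summarize_clusters(cs, roi_area_um2=9.0)
        assert s.n_clusters == 9
        assert s.density_per_um2 == pytest.approx(1.0)

    def test_five_pixel_cluster_size_and_diameter(self):
        # a 5-px cluster at 130 nm pixels: 0.0845 um^2, diameter ~328 nm,
        # inside the expected 300-500 nm band for these nanoclusters
        frame = np.zeros((16, 16))
        frame[5, 4:7] = 100.0
        frame[4, 5] = 100.0
        frame[6, 5] = 100.0
        cs = threshold_label(frame, threshold=80, pixel_size_nm=130.0)
        (rec,) = cs.records
        assert rec.area_px == 5
        assert rec.area_um2 == pytest.approx(5 * 0.0169, rel=1e-9)
        assert rec.equivalent_diameter_nm == pytest.approx(328.0, abs=1.0)
        assert 300 <= rec.equivalent_diameter_nm <= 500

    def test_pooling_over_images(self):
        frame = np.zeros((60, 60))
        frame[5:8, 5:8] = 100.0
        summaries = [summarize_clusters(threshold_label(frame), roi_area_um2=10.0)
                     for _ in range(3)]
        pooled = pool_summaries(summaries)
        assert pooled.n_images == 3
        assert pooled.density_per_um2 == pytest.approx(0.1)
        assert pooled.sem_density_per_um2 == pytest.approx(0.0)


class TestReceptorsPerCluster:
    @pytest.mark.parametrize(
        "receptor,cluster,expected",
        [(12, 2, 6), (5, 3, 2), (0, 2, 0)],
    )
    def test_table_ratios(self, receptor, cluster, expected):
        n, _ = receptors_per_cluster(receptor, cluster)
        assert n == expected

    def test_sem_propagation(self):
        n, sem = receptors_per_cluster(12, 2, 1, 0.4)
        assert n == 6
        assert sem == pytest.approx(6 * np.sqrt((1 / 12) ** 2 + 0.2**2))

    def test_zero_cluster_density_flagged(self):
        with pytest.raises(ValueError):
            receptors_per_cluster(12, 0)


class TestBleachROI:
    def test_constant_stack_and_length(self):
        stack = FrameStack(np.full((7, 32, 32), 42.0), 130.0)
        trace = roi_bleach_trace(stack, (16, 16))
        assert trace.n_frames == 7
        assert np.allclose(trace.values, 42.0)

    def test_staircase_plateaus(self):
        data = np.concatenate([np.full((4, 16, 16), 200.0),
                               np.full((4, 16, 16), 100.0)])
        trace = roi_bleach_trace(FrameStack(data, 130.0), (8, 8))
        assert np.allclose(trace.values[:4], 200.0)
        assert np.allclose(trace.values[4:], 100.0)

    def test_edge_window_rejected(self):
        stack = FrameStack(np.zeros((2, 16, 16)), 130.0)
        with pytest.raises(ValueError):
            roi_bleach_trace(stack, (1, 8))


class TestDensityRecovery:
    def test_gradient_background_removed_by_rolling_ball(self):
        p = MembraneSimParams(field_px=128, seed=5)
        stack, _ = simulate_membrane_stack(p)
        ramp = np.linspace(0, 300, 128)[None, :] * np.ones((128, 1))
        with_grad = FrameStack(stack.data[0] + ramp, 130.0)
        n_plain = len(detect_clusters(stack, rolling_ball_radius=None))
        n_corr = len(detect_clusters(with_grad, rolling_ball_radius=50))
        assert n_corr == pytest.approx(n_plain, rel=0.10)

    @pytest.mark.parametrize("density", [0.25, 0.5, 1.0, 2.0])
    def test_detection_unbiased_against_noiseless_oracle(self, density):
        """Shot/read noise does not bias the detected count.

        The reference for each seed is detection on the noiseless expected
        image, which already accounts for diffraction-limited merging of
        nearby clusters; the paired difference must be statistically zero.
        """
        diffs, clean_counts = [], []
        for seed in range(25):
            p = MembraneSimParams(field_px=128, cluster_density=density,
                                  seed=seed)
            stack, gt = simulate_membrane_stack(p)
            noisy = len(detect_clusters(stack, rolling_ball_radius=None))
            clean = len(detect_clusters(
                FrameStack(gt.expected[None], 130.0), rolling_ball_radius=None))
            diffs.append(noisy - clean)
            clean_counts.append(clean)
        diffs = np.asarray(diffs, dtype=float)
        sem = diffs.std(ddof=1) / np.sqrt(diffs.size)
        tol = max(3 * sem, 0.01 * np.mean(clean_counts))
        assert abs(diffs.mean()) <= tol
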