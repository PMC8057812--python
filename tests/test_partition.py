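"""Partitioning-index pipeline: background subtraction, line scans, ratio."""

import numpy as np
import pytest

from nvjquant.partition import (
    LineScan,
    PartitionScore,
    QuantConfig,
    background_subtract,
    line_profile,
    partition_ratio,
    quantify_image,
    summarize_field,
)


def gaussian_kernel_1d(sigma):
    """Sampled, normalized Gaussian kernel truncated at 4 sigma -- the
    explicit-convolution oracle for the background filter."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def blur_by_explicit_convolution(img, sigma):
    """Separable direct convolution with reflect ('mirror') boundaries."""
    k = gaussian_kernel_1d(sigma)
    r = k.size // 2
    padded = np.pad(img, r, mode="symmetric")  # edge-repeating mirror
    tmp = np.empty_like(padded, dtype=float)
    for i in range(padded.shape[0]):
        tmp[i] = np.convolve(padded[i], k, mode="same")
    out = np.empty_like(padded, dtype=float)
    for j in range(padded.shape[1]):
        out[:, j] = np.convolve(tmp[:, j], k, mode="same")
    return out[r:-r, r:-r]


class TestBackgroundSubtract:
    def test_constant_image_maps_to_zero(self):
        img = np.full((32, 32), 500.0)
        assert np.allclose(background_subtract(img), 0.0, atol=1e-9)

    def test_single_bright_pixel_vs_kernel_oracle(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1000.0
        cfg = QuantConfig(blur_sigma=3.0, clamp_negative=False)
        got = background_subtract(img, cfg)
        expected = img - blur_by_explicit_convolution(img, 3.0)
        assert np.allclose(got, expected, atol=1e-6)
        assert got[16, 16] > 0
        # far field essentially untouched
        assert abs(got[0, 0]) < 1e-6

    def test_linear_ramp_interior_near_zero(self):
        """Gaussian blur preserves affine images away from borders, so the
        subtraction leaves the interior at ~0."""
        col = np.arange(64, dtype=float)
        img = np.tile(col, (64, 1)) * 3.0 + 100.0
        out = background_subtract(img, QuantConfig(clamp_negative=False))
        interior = out[24:40, 24:40]
        assert np.abs(interior).max() < 1e-6

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            background_subtract(np.zeros((4, 4, 4)))
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            background_subtract(img)


class TestLineProfile:
    def test_constant_image_profile_and_auc(self):
        img = np.full((40, 40), 7.0)
        scan = line_profile(img, [(0.5, 2.0), (3.5, 2.0)], QuantConfig(), pixel_size=0.1)
        assert np.allclose(scan.profile, 7.0)
        spacing = np.diff(scan.sample_positions)[0]
        assert scan.auc == pytest.approx(7.0 * scan.profile.size * spacing)

    def test_width_one_axis_aligned_reproduces_pixel_row(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (20, 30))
        cfg = QuantConfig(scan_width=1)
        scan = line_profile(img, [(0.0, 0.5), (2.9, 0.5)], cfg, pixel_size=0.1)
        np.testing.assert_allclose(scan.profile, img[5, :30], atol=1e-9)

    def test_ne_crossing_profile_unimodal_with_peak_at_ring(self, render_noise_free):
        img = render_noise_free(1.0)
        gt = img.ground_truth[0]
        scan = line_profile(img.pixels[0].astype(float), gt["scanline_nvj"],
                            QuantConfig(), pixel_size=0.1)
        peak_pos = scan.sample_positions[np.argmax(scan.profile)]
        # scan is 1.5 um centred on the NE crossing -> peak at ~0.75 um
        assert peak_pos == pytest.approx(0.75, abs=0.15)

    def test_errors(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="outside"):
            line_profile(img, [(0.0, 0.0), (5.0, 0.0)], pixel_size=0.1)
        with pytest.raises(ValueError, match="zero-length"):
            line_profile(img, [(0.3, 0.3), (0.3, 0.3)], pixel_size=0.1)


class TestPartitionRatio:
    def make_scan(self, auc):
        return LineScan(np.arange(3.0), np.full(3, auc / 3), auc)

    def test_identical_scans_ratio_one(self):
        s = self.make_scan(30.0)
        score = partition_ratio(s, s)
        assert score.ratio == 1.0
        assert not score.partitioned

    def test_threshold_is_strict(self):
        """A ratio exactly at 2.0 is not classified as partitioned."""
        assert not partition_ratio(self.make_scan(4.0), self.make_scan(2.0)).partitioned
        assert partition_ratio(self.make_scan(4.0 + 1e-9), self.make_scan(2.0)).partitioned

    def test_degenerate_opposite_auc_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            partition_ratio(self.make_scan(3.0), self.make_scan(0.0))

    def test_noise_free_enrichment_recovered(self, render_noise_free):
        img = render_noise_free(15.0)
        row = quantify_image(img.pixels[0].astype(float), img.ground_truth,
                             QuantConfig(), pixel_size=0.1)[0]
        assert row["ratio"] == pytest.approx(15.0, rel=0.10)
        assert row["partitioned"]


class TestSummarizeField:
    def test_counts(self):
        scores = [PartitionScore(3.0, True)] * 3 + [PartitionScore(1.0, False)] * 7
        s = summarize_field(scores)
        assert s == {"n": 10, "n_partitioned": 3, "percent_partitioned": 30.0}

    def test_all_unpartitioned(self):
        assert summarize_field([PartitionScore(1.0, False)] * 4)["percent_partitioned"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_field([])


class TestPipelineInvariants:
    def test_scale_invariance(self, render_noise_free):
        """Multiplying a noise-free image by c > 0 leaves the ratio unchanged."""
        img = render_noise_free(10.0)
        base = img.pixels[0].astype(float)
        r1 = quantify_image(base, img.ground_truth, QuantConfig(), 0.1)[0]["ratio"]
        r2 = quantify_image(3.7 * base, img.ground_truth, QuantConfig(), 0.1)[0]["ratio"]
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_ratio_monotone_in_enrichment(self, render_noise_free):
        ratios = []
        for e in (1.0, 2.0, 5.0, 10.0, 15.0):
            img = render_noise_free(e)
            ratios.append(
                quantify_image(img.pixels[0].astype(float), img.ground_truth,
                               QuantConfig(), 0.1)[0]["ratio"]
            )
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_blind_null_recovery(self, demo_spec):
        """Over 100 noisy cells without enrichment the mean ratio stays near 1
        and essentially no cell is misclassified as partitioned."""
        from nvjquant.synthetic import ImagingConfig, render_cell

        ratios = []
        for seed in range(100):
            img = render_cell(demo_spec(1.0), ImagingConfig(rng_seed=seed))
            ratios.append(
                quantify_image(img.pixels[0].astype(float), img.ground_truth,
                               QuantConfig(), 0.1)[0]["ratio"]
            )
        ratios = np.asarray(ratios)
        assert 0.9 <= ratios.mean() <= 1.1
        assert (ratios > 2.0).mean() <= 0.05
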