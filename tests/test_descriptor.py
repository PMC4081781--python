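import numpy as np
import pytest
from scipy import ndimage

from vowrhog.descriptor import (
    FeatureVector,
    gradient_map,
    hog,
    hog_features,
    rhog,
    rigo_at,
    rihog,
    wrhog,
)
from vowrhog.fractal import DBCParams, fractal_dimension
from conftest import ridge_image


def hog_oracle(mag, ang, n_bins):
    """Brute-force pixel-by-pixel accumulation."""
    bins = np.zeros(n_bins)
    for m, a in zip(mag.ravel(), ang.ravel()):
        k = int(a * n_bins / (2 * np.pi))
        if k >= n_bins:
            k = 0
        bins[k] += m
    s = bins.sum()
    return bins / s if s > 0 else bins


class TestGradientMap:
    def test_constant_has_zero_magnitude(self):
        omap = gradient_map(np.full((8, 8), 9.0))
        np.testing.assert_array_equal(omap.mag, 0.0)

    def test_horizontal_ramp(self):
        img = np.tile(np.arange(8.0), (8, 1))
        omap = gradient_map(img)
        assert omap.mag[3, 3] == pytest.approx(2.0)  # central difference of ramp
        assert omap.ang[3, 3] == pytest.approx(0.0)

    def test_decreasing_vertical_ramp_points_three_half_pi(self):
        img = np.tile(-np.arange(8.0)[:, None], (1, 8))
        omap = gradient_map(img)
        # +y is the increasing-row direction, so a decrease in i points to 3pi/2
        assert omap.ang[3, 3] == pytest.approx(3 * np.pi / 2)

    def test_angles_in_range(self, ridges):
        omap = gradient_map(ridges)
        assert np.all(omap.ang >= 0) and np.all(omap.ang < 2 * np.pi)
        assert np.all(omap.mag >= 0)


class TestHog:
    def test_constant_gives_zero_histogram(self):
        h = hog(gradient_map(np.full((8, 8), 1.0)), 12)
        np.testing.assert_array_equal(h, 0.0)

    def test_ramp_concentrates_in_bin_zero(self):
        img = np.tile(np.arange(16.0), (16, 1))
        h = hog(gradient_map(img), 4)
        assert h[0] == pytest.approx(1.0)

    def test_matches_accumulation_oracle(self, rng):
        for _ in range(10):
            img = rng.uniform(0, 255, (6, 6))
            omap = gradient_map(img)
            got = hog(omap, 12)
            np.testing.assert_allclose(got, hog_oracle(omap.mag, omap.ang, 12), atol=1e-12)

    def test_rejects_single_bin(self, ridges):
        with pytest.raises(ValueError):
            hog(gradient_map(ridges), 1)


class TestRigo:
    def test_constant_image_all_zero(self):
        pairs = rigo_at(np.full((12, 12), 5.0), (6, 6))
        assert all(m == 0.0 for m, _ in pairs)

    def test_cone_gives_identical_local_angles(self):
        n = 15
        rows, cols = np.indices((n, n)).astype(np.float64)
        cone = -np.hypot(rows - 7, cols - 7)
        pairs = rigo_at(cone, (7, 7))
        angles = [a for m, a in pairs if m > 1e-9]
        mags = [m for m, _ in pairs]
        np.testing.assert_allclose(angles, angles[0], atol=1e-9)
        # magnitudes agree only up to bilinear-interpolation error of the
        # (non-bilinear) cone surface at the off-grid sample points
        np.testing.assert_allclose(mags, mags[0], rtol=0.1)

    def test_90_degree_rotation_preserves_pair_multiset(self, rng):
        img = rng.uniform(0, 255, (17, 17))
        rot = np.rot90(img)
        c = 8
        pairs = sorted(rigo_at(img, (c, c)))
        pairs_rot = sorted(rigo_at(rot, (c, c)))
        np.testing.assert_allclose(pairs, pairs_rot, atol=1e-6)

    def test_border_pixel_rejected(self, rng):
        with pytest.raises(ValueError):
            rigo_at(rng.uniform(0, 1, (12, 12)), (1, 6))


def rihog_oracle(img, n_bins, r=2.0, K=8):
    """Double-loop accumulation over interior pixels via rigo_at."""
    m = int(np.ceil(r)) + 1
    bins = np.zeros(n_bins)
    for i in range(m, img.shape[0] - m):
        for j in range(m, img.shape[1] - m):
            for mag, ang in rigo_at(img, (i, j), r, K):
                k = int(ang * n_bins / (2 * np.pi))
                if k >= n_bins:
                    k = 0
                bins[k] += mag
    s = bins.sum()
    return bins / s if s > 0 else bins


class TestRihog:
    def test_constant_zero_histogram(self):
        np.testing.assert_array_equal(rihog(np.full((16, 16), 3.0), 12), 0.0)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        np.testing.assert_allclose(rihog(img, 12), rihog_oracle(img, 12), atol=1e-10)

    def test_exact_invariance_under_grid_rotations(self, rng):
        img = rng.uniform(0, 255, (24, 24))
        base = rihog(img, 12)
        for k in (1, 2, 3):
            np.testing.assert_allclose(rihog(np.rot90(img, k), 12), base, atol=1e-6)

    def test_small_rotation_moves_rihog_less_than_hog(self):
        wins = 0
        n_fix = 12
        for s in range(n_fix):
            img = ridge_image(size=48, freq=0.12 + 0.01 * s, angle=0.3 + 0.2 * s, seed=s)
            rot = ndimage.rotate(img, 8.0, reshape=False, order=1, mode="nearest")
            inner = (slice(8, -8), slice(8, -8))
            d_ri = np.abs(rihog(img[inner], 12) - rihog(rot[inner], 12)).sum()
            d_hog = np.abs(
                hog(gradient_map(img[inner]), 12) - hog(gradient_map(rot[inner]), 12)
            ).sum()
            wins += d_ri < d_hog
        assert wins >= 0.75 * n_fix


class TestBlockFeatures:
    def test_rhog_length_bookkeeping(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        fv = rhog(img, b=16, n_bins=12)
        assert len(fv) == 4 * 12
        assert not fv.weighted

    def test_constant_image_zero_vector(self):
        fv = rhog(np.full((32, 32), 7.0), b=16, n_bins=12)
        np.testing.assert_array_equal(fv.values, 0.0)

    def test_block_permutation_permutes_segments(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        swapped = img.copy()
        swapped[:16, :16], swapped[:16, 16:] = img[:16, 16:].copy(), img[:16, :16].copy()
        a = rhog(img, 16, 12).values
        b = rhog(swapped, 16, 12).values
        np.testing.assert_allclose(b[:12], a[12:24], atol=1e-12)
        np.testing.assert_allclose(b[12:24], a[:12], atol=1e-12)

    def test_wrhog_is_blockwise_weighted_rhog(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        r = rhog(img, 16, 12).values.reshape(4, 12)
        w = wrhog(img, 16, 12).values.reshape(4, 12)
        from vowrhog.imaging import partition_blocks

        ds = [
            fractal_dimension(blk, DBCParams.for_block_size(16))
            for _, _, blk in partition_blocks(img, 16).blocks
        ]
        np.testing.assert_allclose(w, r * np.asarray(ds)[:, None], atol=1e-12)

    def test_wrhog_single_block_is_d_times_rihog(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        d = fractal_dimension(img, DBCParams.for_block_size(16))
        np.testing.assert_allclose(
            wrhog(img, 16, 12).values, d * rihog(img, 12), atol=1e-12
        )

    def test_rough_block_outweighs_smooth_block(self, rng):
        img = np.empty((16, 32))
        img[:, :16] = rng.uniform(0, 255, (16, 16))  # rough noise block
        img[:, 16:] = np.linspace(80, 120, 16)[None, :]  # smooth gradient block
        fv = wrhog(img, 16, 12).values.reshape(2, 12)
        # equal unweighted L1 mass (both histograms normalized), so the
        # rougher block's fractal weight gives it more weighted mass
        assert fv[0].sum() > fv[1].sum()

    def test_hog_features_blockwise_concatenation(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        fv = hog_features(img, b=16, n_bins=12)
        assert isinstance(fv, FeatureVector)
        assert len(fv) == 48
        np.testing.assert_allclose(fv.values[:12], hog(gradient_map(img[:16, :16]), 12))
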