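"""Segmentation tests: per-stage oracles and end-to-end soma recovery."""

import numpy as np
import pytest

import ablatemap as am
from ablatemap.movie import Movie
from ablatemap.segmentation import (SegmentationParams, WienerParams,
                                    binarize_tile, circularity_filter,
                                    clean_mask, enhance_contrast,
                                    extract_traces, gaussian_smooth,
                                    otsu_threshold, reference_image, segment,
                                    watershed_split, wiener_filter,
                                    _segment_tile, SomaSegmenter)
from ablatemap.synthetic import noiseless

from conftest import centroid_recall_precision


# ---------------------------------------------------------------- oracles

def wiener_oracle(img, size=(3, 3), noise=None):
    """Direct per-pixel evaluation over border-truncated neighborhoods."""
    img = np.asarray(img, dtype=float)
    H, W = img.shape
    hn, hm = size[0] // 2, size[1] // 2
    mu = np.zeros_like(img)
    var = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            acc = acc2 = 0.0
            cnt = 0
            for di in range(-hn, hn + 1):
                for dj in range(-hm, hm + 1):
                    if 0 <= i + di < H and 0 <= j + dj < W:
                        v = img[i + di, j + dj]
                        acc += v
                        acc2 += v * v
                        cnt += 1
            mu[i, j] = acc / cnt
            var[i, j] = acc2 / cnt - mu[i, j] ** 2
    nu2 = var.mean() if noise is None else noise
    out = np.where(var <= nu2, mu,
                   mu + np.divide(var - nu2, np.where(var > 0, var, 1.0))
                   * (img - mu))
    return out


def gaussian_oracle(img, sigma):
    """Dense convolution with the sampled kernel, mirrored borders.

    Border convention matches the implementation's reflective handling:
    the edge pixel is included in its own mirror image (numpy 'symmetric').
    """
    half = int(np.ceil(2 * sigma))
    x = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    kern = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    kern /= kern.sum()
    padded = np.pad(np.asarray(img, dtype=float), half, mode="symmetric")
    H, W = img.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = np.sum(padded[i:i + 2 * half + 1,
                                      j:j + 2 * half + 1] * kern)
    return out


def otsu_oracle(img, nbins=256):
    """Exhaustive threshold search minimizing weighted intra-class variance."""
    counts, edges = np.histogram(np.asarray(img).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best, best_t = np.inf, centers[0]
    for t in centers:
        lo = (centers <= t) & (counts > 0)
        hi = (centers > t) & (counts > 0)
        if not lo.any() or not hi.any():
            continue
        w0, w1 = counts[lo].sum(), counts[hi].sum()
        m0 = np.average(centers[lo], weights=counts[lo])
        m1 = np.average(centers[hi], weights=counts[hi])
        v0 = np.average((centers[lo] - m0) ** 2, weights=counts[lo])
        v1 = np.average((centers[hi] - m1) ** 2, weights=counts[hi])
        intra = w0 * v0 + w1 * v1
        if intra < best:
            best, best_t = intra, t
    return best_t


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


# ------------------------------------------------------------- unit tests

class TestWiener:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 0.4)
        assert np.allclose(wiener_filter(img), img)

    def test_zero_noise_variance_is_identity(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = wiener_filter(img, WienerParams(noise_variance=0.0))
        assert np.allclose(out, img)

    def test_matches_bruteforce_oracle(self, rng):
        img = rng.random((8, 8))
        out = wiener_filter(img)
        ref = wiener_oracle(img)
        assert np.allclose(out, ref, rtol=1e-10, atol=1e-12)

    def test_shift_equivariant_with_fixed_noise(self, rng):
        img = rng.random((12, 12))
        p = WienerParams(noise_variance=0.01)
        a = wiener_filter(img, p)
        b = wiener_filter(img + 5.0, p)
        assert np.allclose(a + 5.0, b, atol=1e-10)


class TestGaussian:
    def test_constant_unchanged(self):
        img = np.full((7, 7), 2.5)
        assert np.allclose(gaussian_smooth(img, 0.5), img)

    def test_interior_impulse_gives_kernel(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        out = gaussian_smooth(img, 0.5)
        x = np.arange(-1, 2)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        kern = np.exp(-(xx**2 + yy**2) / (2 * 0.25))
        kern /= kern.sum()
        assert np.allclose(out[2:5, 2:5], kern)
        assert out.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("sigma", [0.5, 1.3])
    def test_matches_dense_convolution(self, rng, sigma):
        img = rng.random((16, 16))
        assert np.allclose(gaussian_smooth(img, sigma),
                           gaussian_oracle(img, sigma), rtol=1e-10, atol=1e-12)

    def test_shift_equivariant(self, rng):
        img = rng.random((16, 16))
        assert np.allclose(gaussian_smooth(img + 3.0, 0.5),
                           gaussian_smooth(img, 0.5) + 3.0)


class TestClahe:
    def test_constant_stays_constant(self):
        img = np.full((64, 64), 0.3)
        out = enhance_contrast(img)
        assert np.allclose(out, out.flat[0])

    def test_output_in_unit_interval(self, rng):
        out = enhance_contrast(rng.random((64, 64)))
        assert out.min() >= 0 and out.max() <= 1

    def test_widens_low_contrast_gradient(self):
        img = np.tile(np.linspace(0.45, 0.55, 64), (64, 1))
        out = enhance_contrast(img)
        assert np.ptp(out) > np.ptp(img)


class TestOtsu:
    def test_two_level_separates(self):
        img = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        t = otsu_threshold(img.reshape(10, 10))
        assert 0.1 < t < 0.9

    def test_single_valued_raises(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((5, 5), 1.0))

    def test_matches_bruteforce_on_mixture(self, rng):
        img = np.concatenate([rng.normal(0.2, 0.04, 300),
                              rng.normal(0.75, 0.05, 200)]).reshape(25, 20)
        assert otsu_threshold(img) == pytest.approx(otsu_oracle(img),
                                                    abs=1e-12)

    def test_matches_bruteforce_three_level(self):
        img = np.concatenate([np.zeros(10), np.full(10, 0.5),
                              np.full(80, 1.0)]).reshape(10, 10)
        assert otsu_threshold(img) == pytest.approx(otsu_oracle(img),
                                                    abs=1e-12)


class TestBinarize:
    def test_constant_tile_empty(self):
        assert not binarize_tile(np.full((32, 32), 0.5)).any()

    def test_dark_tile_uses_otsu_path(self):
        tile = np.full((64, 64), 0.02)
        tile[disk_mask(tile.shape, (16, 16), 5)] = 0.6
        tile[disk_mask(tile.shape, (45, 45), 5)] = 0.6
        assert tile.mean() < 0.1
        mask = binarize_tile(tile)
        expected = tile > otsu_oracle(tile)
        assert np.array_equal(mask, expected)
        assert mask[16, 16] and mask[45, 45]

    def test_bright_tile_uses_adaptive_path(self):
        tile = np.full((64, 64), 0.3)
        tile += np.linspace(0, 0.05, 64)[None, :]  # smooth background
        tile[disk_mask(tile.shape, (32, 32), 4)] = 0.9
        assert tile.mean() >= 0.1
        mask = binarize_tile(tile)
        assert mask[32, 32]
        assert not mask[5, 5]


class TestCleanMask:
    def test_border_touching_removed(self):
        mask = disk_mask((40, 40), (0, 20), 6)
        assert clean_mask(mask, min_area=3).sum() == 0

    def test_holes_filled(self):
        mask = disk_mask((40, 40), (20, 20), 8)
        mask[20, 20] = False
        out = clean_mask(mask, min_area=3)
        assert out[20, 20]

    def test_speckles_opened_away(self, rng):
        mask = np.zeros((40, 40), dtype=bool)
        idx = rng.choice(38 * 38, 40, replace=False)
        mask[1 + idx // 38, 1 + idx % 38] = True
        # ensure no accidental clusters survive opening
        assert clean_mask(mask, min_area=3).sum() == 0


class TestWatershed:
    def test_single_disk_single_label(self):
        mask = disk_mask((50, 50), (25, 25), 10)
        labels = watershed_split(mask)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, mask)

    def test_two_overlapping_disks_split(self):
        r = 10
        mask = disk_mask((60, 60), (30, 21), r) | disk_mask((60, 60), (30, 39), r)
        from scipy import ndimage as ndi
        assert ndi.label(mask)[1] == 1  # genuinely merged
        labels = watershed_split(mask)
        assert labels.max() == 2

    def test_disjoint_components_keep_count(self):
        mask = (disk_mask((80, 80), (20, 20), 7)
                | disk_mask((80, 80), (60, 60), 7)
                | disk_mask((80, 80), (20, 60), 7))
        assert watershed_split(mask).max() == 3


class TestCircularity:
    def test_disk_retained(self):
        labels = disk_mask((40, 40), (20, 20), 10).astype(np.int32)
        assert circularity_filter(labels).max() == 1

    def test_bar_removed(self):
        labels = np.zeros((20, 60), dtype=np.int32)
        labels[9:11, 10:50] = 1  # 2 x 40 bar
        from skimage.measure import regionprops
        p = regionprops(labels)[0]
        circ = 4 * np.pi * p.area / p.perimeter_crofton**2
        assert circ < 0.4
        assert circularity_filter(labels).max() == 0

    def test_square_retained(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[10:20, 10:20] = 1  # ideal circularity 4*pi*100/1600 ~ 0.785
        assert circularity_filter(labels).max() == 1


class TestReferenceImage:
    @staticmethod
    def _movie(frames, rate=10.0):
        return Movie(green=np.asarray(frames, dtype=float), red=None,
                     frame_rate=rate, pixel_size=1.0)

    def test_constant_movie_degenerate_normalization(self):
        movie = self._movie(np.full((50, 8, 8), 3.0))
        assert np.all(reference_image(movie, window=2.0) == 0.0)

    def test_alternating_frames_average(self):
        frames = np.zeros((40, 4, 4))
        frames[1::2] = 2.0
        frames[:, 0, 0] = 0.0  # keep a dark pixel so normalization is defined
        movie = self._movie(frames)
        img = reference_image(movie, window=2.0)
        assert img[1, 1] == pytest.approx(1.0)  # mean c, normalized to max

    def test_matches_bruteforce_mean(self, rng):
        frames = rng.random((10, 6, 6))
        movie = self._movie(frames, rate=1.0)
        img = reference_image(movie, window=10.0)
        ref = frames.mean(axis=0)
        ref = (ref - ref.min()) / (ref.max() - ref.min())
        assert np.allclose(img, ref)

    def test_window_longer_than_movie_raises(self):
        with pytest.raises(ValueError):
            reference_image(self._movie(np.zeros((10, 4, 4))), window=20.0)


class TestExtractTraces:
    def test_constant_movie_constant_traces(self, small_truth_labelmap):
        T = 5
        H, W = small_truth_labelmap.label_image.shape
        movie = Movie(green=np.full((T, H, W), 7.0), red=None,
                      frame_rate=10.0, pixel_size=2.0)
        traces = extract_traces(movie, small_truth_labelmap)
        assert np.all(traces == 7.0)

    def test_three_pixel_mask_matches_hand_mean(self, rng):
        from ablatemap.segmentation import CellROI, LabelMap
        frames = rng.random((8, 10, 10))
        coords = np.array([[2, 3], [2, 4], [5, 5]])
        lm = LabelMap(np.zeros((10, 10), int),
                      [CellROI(1, coords, (3, 4), 3, 0, 1)])
        traces = extract_traces(frames, lm)
        hand = frames[:, [2, 2, 5], [3, 4, 5]].mean(axis=1)
        assert np.allclose(traces[0], hand)


# ------------------------------------------------------------ end to end

class TestSegmentPipeline:
    def test_blank_image_empty_roster(self):
        lm = segment(np.zeros((64, 64)))
        assert lm.n_cells == 0

    def test_single_tile_equals_tiling_machinery(self):
        """An image within one tile gives the same roster with and without
        the tiling path."""
        img = np.full((120, 120), 0.1)
        for c in [(30, 30), (60, 90), (90, 40)]:
            d = np.hypot(*np.mgrid[:120, :120] - np.array(c)[:, None, None])
            img += 0.6 * np.exp(-0.5 * np.clip(d - 3, 0, None) ** 2)
        img = img / img.max()
        params = SegmentationParams()
        via_segment = segment(img, params)
        direct = _segment_tile(img, params)
        assert via_segment.n_cells == len(direct) == 3
        got = sorted(map(tuple, np.round(via_segment.centroids(), 6)))
        want = sorted(tuple(np.round(s["centroid"], 6)) for s in direct)
        assert got == want

    def test_noiseless_scene_recall_precision(self):
        cfg = noiseless(am.SceneConfig(frame_rate=10.0, duration=30.0,
                                       n_neurons=50, seed=21))
        scene = am.generate_scene(cfg)
        movie = am.render_movie(scene)
        lm = segment(reference_image(movie))
        recall, precision = centroid_recall_precision(scene, lm)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_no_duplicate_centroids(self):
        cfg = noiseless(am.SceneConfig(frame_rate=10.0, duration=30.0,
                                       n_neurons=50, seed=22))
        movie = am.render_movie(am.generate_scene(cfg))
        params = SegmentationParams()
        lm = segment(reference_image(movie), params)
        cents = lm.centroids()
        d = np.hypot(cents[:, None, 0] - cents[None, :, 0],
                     cents[:, None, 1] - cents[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= params.dedup_radius_px

    def test_boundary_straddling_soma_found_once(self):
        """A soma sitting in the tile-overlap region is deduplicated."""
        img = np.full((300, 300), 0.1)
        d = np.hypot(*np.mgrid[:300, :300] - np.array([150, 220])[:, None, None])
        img += 0.7 * np.exp(-0.5 * np.clip(d - 3, 0, None) ** 2)
        img /= img.max()
        params = SegmentationParams()
        stride = params.tile_size - params.tile_overlap
        assert stride < 220 < params.tile_size  # in both column-tiles
        lm = segment(img, params)
        assert lm.n_cells == 1
        assert np.hypot(lm.rois[0].centroid[0] - 150,
                        lm.rois[0].centroid[1] - 220) < 3

    def test_estimator_interface(self):
        img = np.zeros((64, 64))
        est = SomaSegmenter(soma_radius_px=3.0)
        out = est.fit_transform(img)
        assert out.shape == img.shape and est.n_cells_ == 0
        assert "soma_radius_px" in est.get_params()
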