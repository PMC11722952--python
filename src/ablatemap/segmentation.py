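"""Tile-based automatic soma segmentation and trace extraction.

The segmentation target is the time-averaged image of the last part of a
recording. The image is normalized to [0, 1], cut into overlapping
238 x 238 tiles, and each tile runs the chain

    Wiener (3x3 local statistics) -> Gaussian (sigma 0.5) -> CLAHE
    -> intensity-dependent binarization (adaptive local-mean threshold on
       bright tiles, global Otsu on dark ones) -> border clearing, hole
       filling, opening, small-object removal -> marker-controlled
       watershed on the distance transform -> circularity filter (4*pi*A/P^2
       >= 0.4).

Detected centroids are mapped back to global coordinates and deduplicated
(closer than ``dedup_radius`` px keeps the larger ROI). Coordinates are
0-based (row, col); masks are pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, measure
from skimage.segmentation import watershed as _watershed
from sklearn.base import BaseEstimator

from .movie import Movie

__all__ = [
    "WienerParams",
    "SegmentationParams",
    "CellROI",
    "LabelMap",
    "reference_image",
    "wiener_filter",
    "gaussian_smooth",
    "enhance_contrast",
    "otsu_threshold",
    "binarize_tile",
    "clean_mask",
    "watershed_split",
    "circularity_filter",
    "segment",
    "extract_traces",
    "SomaSegmenter",
]


@dataclass(frozen=True)
class WienerParams:
    """Adaptive Wiener filter settings.

    ``noise_variance`` is either a fixed value or ``"estimate"``, in which
    case it is set to the mean of all local variances (the usual adaptive
    behaviour of this filter).
    """

    neighborhood: tuple[int, int] = (3, 3)
    noise_variance: float | str = "estimate"

    def __post_init__(self) -> None:
        n, m = self.neighborhood
        if n <= 0 or m <= 0 or n % 2 == 0 or m % 2 == 0:
            raise ValueError("neighborhood sides must be odd and positive")


@dataclass(frozen=True)
class SegmentationParams:
    """All knobs of the soma segmentation pipeline (pixel units)."""

    tile_size: int = 238
    tile_overlap: int = 32
    gauss_sigma: float = 0.5
    mean_intensity_cutoff: float = 0.1
    adaptive_sensitivity: float = 0.006
    # Maps the dimensionless sensitivity onto the local-mean margin:
    # foreground iff I > local_mean * (1 + 0.5 - sensitivity_scale * s).
    sensitivity_scale: float = 50.0
    circularity_min: float = 0.4
    soma_radius_px: float = 3.0
    min_area: float | None = None  # None -> pi * (soma_radius_px / 2)^2
    # None -> 2 * soma_radius_px: merges tile-overlap duplicates (which land
    # within ~2 px of each other) without deleting genuinely adjacent somata.
    dedup_radius: float | None = None
    averaging_window: float = 20.0  # s, taken from the movie end
    clahe_grid: int = 8
    clahe_clip: float = 0.01
    watershed_alpha: float = 0.5  # marker level as fraction of component max dist
    adaptive_window: int | None = None  # None -> odd(4 * soma_radius_px)
    opening_radius: int = 1
    wiener: WienerParams = field(default_factory=WienerParams)

    def __post_init__(self) -> None:
        if not 0 < self.circularity_min <= 1:
            raise ValueError("circularity_min must be in (0, 1]")
        if self.tile_overlap >= self.tile_size:
            raise ValueError("tile_overlap must be smaller than tile_size")

    @property
    def min_area_px(self) -> float:
        if self.min_area is not None:
            return self.min_area
        return np.pi * (self.soma_radius_px / 2.0) ** 2

    @property
    def dedup_radius_px(self) -> float:
        if self.dedup_radius is not None:
            return self.dedup_radius
        return 2.0 * self.soma_radius_px

    @property
    def adaptive_window_px(self) -> int:
        if self.adaptive_window is not None:
            return self.adaptive_window
        w = int(round(4 * self.soma_radius_px))
        return w + 1 if w % 2 == 0 else w


@dataclass
class CellROI:
    """One segmented soma."""

    id: int
    coords: np.ndarray  # (n, 2) int global (row, col) pixels
    centroid: tuple[float, float]  # (row, col) px
    area: int  # px^2
    perimeter: float  # px, Crofton estimate
    circularity: float  # 4*pi*A/P^2 clipped to [0, 1]


@dataclass
class LabelMap:
    """Integer image (0 = background, k = cell k) plus the ROI roster."""

    label_image: np.ndarray
    rois: list[CellROI]

    @property
    def n_cells(self) -> int:
        return len(self.rois)

    def centroids(self) -> np.ndarray:
        return np.asarray([r.centroid for r in self.rois]).reshape(-1, 2)


def reference_image(movie: Movie, window: float | None = None,
                    channel: str = "green") -> np.ndarray:
    """Average of the final ``window`` seconds, min-max normalized to [0, 1].

    A constant average (degenerate normalization) maps to all zeros.
    """
    if window is None:
        window = 20.0
    n = int(np.floor(window * movie.frame_rate))
    if n < 1 or n > movie.n_frames:
        raise ValueError(
            f"averaging window {window} s needs {n} frames; movie has "
            f"{movie.n_frames}"
        )
    img = movie.channel(channel)[-n:].mean(axis=0)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


def wiener_filter(image: np.ndarray,
                  params: WienerParams | None = None) -> np.ndarray:
    """Pixel-wise adaptive Wiener filter from local mean and variance.

    For each pixel, with local mean ``mu`` and variance ``sig2`` over the
    N x M neighborhood (truncated at the image border, normalizing by the
    number of in-image pixels) and noise variance ``nu2``:

        b = mu + (sig2 - nu2) / sig2 * (a - mu)      if sig2 > nu2
        b = mu                                        otherwise
    """
    if params is None:
        params = WienerParams()
    a = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("image must be finite")
    size = params.neighborhood
    count = ndi.uniform_filter(np.ones_like(a), size=size, mode="constant",
                               cval=0.0)
    mu = ndi.uniform_filter(a, size=size, mode="constant", cval=0.0) / count
    sig2 = (ndi.uniform_filter(a * a, size=size, mode="constant", cval=0.0)
            / count - mu**2)
    sig2 = np.clip(sig2, 0.0, None)  # guard tiny negative rounding
    if params.noise_variance == "estimate":
        nu2 = float(sig2.mean())
    else:
        nu2 = float(params.noise_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(sig2 > 0, (sig2 - nu2) / np.where(sig2 > 0, sig2, 1.0), 0.0)
    out = mu + gain * (a - mu)
    return np.where(sig2 <= nu2, mu, out)


def gaussian_smooth(image: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Convolve with a normalized sampled Gaussian, reflective borders.

    Kernel side is ``2 * ceil(2 * sigma) + 1``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = int(np.ceil(2 * sigma))
    x = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    kern = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    kern /= kern.sum()
    return ndi.convolve(np.asarray(image, dtype=float), kern, mode="reflect")


def enhance_contrast(image: np.ndarray, grid: int = 8,
                     clip: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1]."""
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image must be normalized to [0, 1] before CLAHE")
    if img.max() == img.min():
        return img.copy()
    kernel = (max(img.shape[0] // grid, 1), max(img.shape[1] // grid, 1))
    return exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's global threshold over an ``nbins``-bin histogram.

    Minimizes intra-class variance of the two thresholded classes; the
    returned value is a bin centre, so ``image > t`` separates the
    classes. Raises on single-valued images.
    """
    img = np.asarray(image, dtype=float)
    if np.unique(img).size < 2:
        raise ValueError("Otsu threshold requires at least two distinct values")
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    s0 = np.cumsum(counts * centers)
    s1 = s0[-1] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / w0
        m1 = s1 / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between[~np.isfinite(between)] = -np.inf
    return float(centers[np.argmax(between)])


def binarize_tile(tile: np.ndarray,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Intensity-dependent binarization of one tile.

    Tiles with mean intensity above the cutoff (0.1 by default; the
    boundary case goes to this branch) use a local-mean adaptive
    threshold: foreground iff ``I > local_mean * (1 + margin)`` with
    ``margin = 0.5 - sensitivity_scale * sensitivity`` over a window of
    about two soma diameters. Darker tiles use Otsu's global threshold.
    Constant tiles binarize to all background.
    """
    if params is None:
        params = SegmentationParams()
    tile = np.asarray(tile, dtype=float)
    if tile.max() == tile.min():
        return np.zeros(tile.shape, dtype=bool)
    if tile.mean() >= params.mean_intensity_cutoff:
        margin = 0.5 - params.sensitivity_scale * params.adaptive_sensitivity
        local_mean = ndi.uniform_filter(tile, size=params.adaptive_window_px,
                                        mode="reflect")
        return tile > local_mean * (1.0 + margin)
    return tile > otsu_threshold(tile)


def clean_mask(mask: np.ndarray, min_area: float = 7.0,
               opening_radius: int = 1,
               clear_border: bool = True) -> np.ndarray:
    """Morphological cleanup of a binary tile mask.

    Removes border-touching components, fills holes, opens with a disk
    structuring element and drops components below ``min_area``.
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if clear_border:
        lab, n = ndi.label(out)
        if n:
            border = np.unique(np.concatenate([
                lab[0], lab[-1], lab[:, 0], lab[:, -1]
            ]))
            out &= ~np.isin(lab, border[border > 0])
    out = ndi.binary_fill_holes(out)
    if opening_radius > 0:
        r = opening_radius
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        selem = (yy**2 + xx**2) <= r**2
        out = ndi.binary_opening(out, structure=selem)
    lab, n = ndi.label(out)
    if n:
        sizes = ndi.sum_labels(out, lab, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_area) + 1
        out &= ~np.isin(lab, small)
    return out


def watershed_split(mask: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Separate touching somata with a marker-controlled watershed.

    Markers are the connected components of ``distance transform >
    alpha * (per-component maximum distance)``; the watershed floods the
    negated distance transform restricted to the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    comp, n = ndi.label(mask)
    maxes = ndi.maximum(dist, comp, index=np.arange(1, n + 1))
    thresh = np.zeros(mask.shape)
    thresh[mask] = alpha * np.asarray(maxes)[comp[mask] - 1]
    markers, _ = ndi.label(dist > thresh)
    return _watershed(-dist, markers, mask=mask).astype(np.int32)


def _region_stats(labels: np.ndarray) -> list[dict]:
    out = []
    for p in measure.regionprops(labels):
        per = p.perimeter_crofton
        circ = 4 * np.pi * p.area / per**2 if per > 0 else 0.0
        out.append({
            "label": p.label,
            "coords": p.coords,
            "centroid": p.centroid,
            "area": int(p.area),
            "perimeter": float(per),
            "circularity": float(min(circ, 1.0)),
        })
    return out


def circularity_filter(labels: np.ndarray, min_circularity: float = 0.4) -> np.ndarray:
    """Drop labels with circularity ``4*pi*A/P^2`` below the threshold.

    Rejects elongated objects (neurites, vessel fragments) while keeping
    compact somata; the Crofton perimeter estimate avoids the systematic
    circularity understatement of naive pixel-edge counting.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    for st in _region_stats(labels):
        if st["circularity"] < min_circularity:
            out[out == st["label"]] = 0
    return out


def _segment_tile(tile: np.ndarray, params: SegmentationParams) -> list[dict]:
    """Run the full per-tile chain; returns region stats in tile coords."""
    den = wiener_filter(tile, params.wiener)
    den = gaussian_smooth(den, params.gauss_sigma)
    den = np.clip(den, 0.0, 1.0)
    den = enhance_contrast(den, params.clahe_grid, params.clahe_clip)
    mask = binarize_tile(den, params)
    mask = clean_mask(mask, params.min_area_px, params.opening_radius)
    labels = watershed_split(mask, params.watershed_alpha)
    labels = circularity_filter(labels, params.circularity_min)
    # Watershed fragments can dip under the area floor; re-apply it.
    return [s for s in _region_stats(labels) if s["area"] >= params.min_area_px]


def _tile_starts(size: int, tile: int, stride: int) -> tuple[list[int], int]:
    """Tile start offsets along one axis and the padded axis length."""
    if size <= tile:
        return [0], size
    n = int(np.ceil((size - (tile - stride)) / stride))
    padded = n * stride + (tile - stride)
    return [i * stride for i in range(n)], padded


def segment(image: np.ndarray,
            params: SegmentationParams | None = None) -> LabelMap:
    """Segment somata in a normalized 2-D reference image.

    The image is reflect-padded to the tile grid, each tile is processed
    independently, detections are mapped to global coordinates, detections
    centred in the padding are dropped, and centroids closer than
    ``dedup_radius`` are merged keeping the larger-area ROI.
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment expects a 2-D image")
    H, W = img.shape
    stride = params.tile_size - params.tile_overlap
    rows, ph = _tile_starts(H, params.tile_size, stride)
    cols, pw = _tile_starts(W, params.tile_size, stride)
    if (ph, pw) != (H, W):
        img_p = np.pad(img, ((0, ph - H), (0, pw - W)), mode="reflect")
    else:
        img_p = img
    tile_h = min(params.tile_size, ph)
    tile_w = min(params.tile_size, pw)

    found: list[dict] = []
    for r0 in rows:
        for c0 in cols:
            tile = img_p[r0:r0 + tile_h, c0:c0 + tile_w]
            for st in _segment_tile(tile, params):
                cr, cc = st["centroid"]
                cr, cc = cr + r0, cc + c0
                if cr >= H or cc >= W:  # centred in the reflect padding
                    continue
                coords = st["coords"] + np.array([r0, c0])
                keep = (coords[:, 0] < H) & (coords[:, 1] < W)
                st = dict(st, centroid=(cr, cc), coords=coords[keep])
                found.append(st)

    # Deduplicate: larger ROIs claim their neighborhood first.
    found.sort(key=lambda s: -s["area"])
    accepted: list[dict] = []
    for st in found:
        cr, cc = st["centroid"]
        if any(np.hypot(cr - a["centroid"][0], cc - a["centroid"][1])
               < params.dedup_radius_px for a in accepted):
            continue
        accepted.append(st)

    label_img = np.zeros((H, W), dtype=np.int32)
    rois: list[CellROI] = []
    for i, st in enumerate(accepted, start=1):
        rr, cc_ = st["coords"][:, 0], st["coords"][:, 1]
        free = label_img[rr, cc_] == 0
        label_img[rr[free], cc_[free]] = i
        rois.append(CellROI(
            id=i, coords=st["coords"][free],
            centroid=tuple(map(float, st["centroid"])),
            area=int(free.sum()), perimeter=st["perimeter"],
            circularity=st["circularity"],
        ))
    return LabelMap(label_image=label_img, rois=rois)


def extract_traces(movie: Movie | np.ndarray, labelmap: LabelMap,
                   channel: str = "green") -> np.ndarray:
    """Per-cell, per-frame mean raw intensity over each ROI mask.

    Returns an ``(n_cells, T)`` array ordered like ``labelmap.rois``.
    """
    stack = movie.channel(channel) if isinstance(movie, Movie) else np.asarray(movie)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    out = np.empty((labelmap.n_cells, stack.shape[0]))
    for i, roi in enumerate(labelmap.rois):
        if roi.coords.shape[0] == 0:
            raise ValueError(f"ROI {roi.id} has an empty mask")
        out[i] = stack[:, roi.coords[:, 0], roi.coords[:, 1]].mean(axis=1)
    return out


class SomaSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the tiled segmentation pipeline.

    ``fit(image)`` runs the pipeline on a normalized 2-D reference image
    and exposes ``labels_`` (the integer label image), ``rois_`` and
    ``n_cells_``. ``fit_transform`` additionally returns the label image,
    so the estimator composes with sklearn pipelines operating on images.
    """

    def __init__(self, tile_size: int = 238, tile_overlap: int = 32,
                 gauss_sigma: float = 0.5, mean_intensity_cutoff: float = 0.1,
                 adaptive_sensitivity: float = 0.006,
                 sensitivity_scale: float = 50.0, circularity_min: float = 0.4,
                 soma_radius_px: float = 3.0, min_area: float | None = None,
                 dedup_radius: float | None = None, clahe_grid: int = 8,
                 clahe_clip: float = 0.01, watershed_alpha: float = 0.5,
                 adaptive_window: int | None = None, opening_radius: int = 1):
        self.tile_size = tile_size
        self.tile_overlap = tile_overlap
        self.gauss_sigma = gauss_sigma
        self.mean_intensity_cutoff = mean_intensity_cutoff
        self.adaptive_sensitivity = adaptive_sensitivity
        self.sensitivity_scale = sensitivity_scale
        self.circularity_min = circularity_min
        self.soma_radius_px = soma_radius_px
        self.min_area = min_area
        self.dedup_radius = dedup_radius
        self.clahe_grid = clahe_grid
        self.clahe_clip = clahe_clip
        self.watershed_alpha = watershed_alpha
        self.adaptive_window = adaptive_window
        self.opening_radius = opening_radius

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            tile_size=self.tile_size, tile_overlap=self.tile_overlap,
            gauss_sigma=self.gauss_sigma,
            mean_intensity_cutoff=self.mean_intensity_cutoff,
            adaptive_sensitivity=self.adaptive_sensitivity,
            sensitivity_scale=self.sensitivity_scale,
            circularity_min=self.circularity_min,
            soma_radius_px=self.soma_radius_px, min_area=self.min_area,
            dedup_radius=self.dedup_radius, clahe_grid=self.clahe_grid,
            clahe_clip=self.clahe_clip, watershed_alpha=self.watershed_alpha,
            adaptive_window=self.adaptive_window,
            opening_radius=self.opening_radius,
        )

    def fit(self, X: np.ndarray, y=None) -> "SomaSegmenter":
        labelmap = segment(X, self._params())
        self.labelmap_ = labelmap
        self.labels_ = labelmap.label_image
        self.rois_ = labelmap.rois
        self.n_cells_ = labelmap.n_cells
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_
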