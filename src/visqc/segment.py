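"""Region-of-interest extraction: k-means color segmentation and the largest
axis-aligned rectangle inscribed in the ROI mask.

The sample occupies one of k color clusters (default k=4: background, sample,
white reference, indicator).  The sample cluster is chosen by hue proximity
among sufficiently saturated, non-extreme-luminance clusters; the mask is
cleaned morphologically and reduced to its largest connected component.
Structural (texture) features are then computed on the largest rectangle that
fits entirely inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.measure import label
from sklearn.cluster import KMeans

from .exceptions import (DegenerateClusteringError, EmptyMaskError,
                         ROINotFoundError)

#: Default hue of the sample material (fraction of the hue circle; ~24 deg,
#: carrot orange).
DEFAULT_SAMPLE_HUE = 24.0 / 360.0

#: Pixels sampled (at most) to fit k-means; all pixels are then assigned.
_KMEANS_FIT_SAMPLE = 50_000


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned rectangle, 0-based, half-open [top, top+height)."""

    top: int
    left: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.top:self.top + self.height,
                     self.left:self.left + self.width]


def _hue_distance(h1: float, h2: float) -> float:
    d = abs(h1 - h2) % 1.0
    return min(d, 1.0 - d)


def segment_roi(image: np.ndarray, k: int = 4, seed: int = 0,
                sample_hue: float = DEFAULT_SAMPLE_HUE,
                hue_tolerance: float = 0.12,
                min_saturation: float = 0.2,
                min_area_fraction: float = 0.002) -> np.ndarray:
    """Segment the sample region by k-means clustering on pixel color.

    Clusters are ranked by luminance; the darkest (background) and brightest
    (white reference) are excluded, and among the rest the cluster whose mean
    hue is nearest ``sample_hue`` — within ``hue_tolerance`` and with mean
    saturation at least ``min_saturation`` — is taken as the sample.  The
    mask is cleaned by morphological opening and closing; the returned ROI is
    the convex hull of the cluster's non-trivial connected patches, which on
    an intact sample equals the largest component and on a severely whitened
    one recovers the full (convex) slice from the surviving hue islands.
    Deterministic given ``seed``.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if k < 2:
        raise ValueError("k must be at least 2")
    H, W = image.shape[:2]
    pixels = image.reshape(-1, 3).astype(np.float64)
    if np.unique(pixels, axis=0).shape[0] < k:
        raise DegenerateClusteringError(
            f"fewer than k={k} distinct colors in the image")

    rng = np.random.default_rng(seed)
    if pixels.shape[0] > _KMEANS_FIT_SAMPLE:
        fit_idx = rng.choice(pixels.shape[0], _KMEANS_FIT_SAMPLE,
                             replace=False)
        fit_px = pixels[fit_idx]
    else:
        fit_px = pixels
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    km.fit(fit_px)
    labels = km.predict(pixels).reshape(H, W)

    centers = km.cluster_centers_
    luminance = centers.mean(axis=1)
    order = np.argsort(luminance)
    excluded = {order[0], order[-1]}  # background and white reference
    hsv = rgb2hsv(np.clip(centers, 0, 255)[None, :, :] / 255.0)[0]

    best, best_dist = None, np.inf
    for c in range(k):
        if c in excluded:
            continue
        hue, sat = hsv[c, 0], hsv[c, 1]
        if sat < min_saturation:
            continue
        d = _hue_distance(hue, sample_hue)
        if d <= hue_tolerance and d < best_dist:
            best, best_dist = c, d
    if best is None:
        raise ROINotFoundError("no cluster matches the sample hue")

    mask = labels == best
    footprint = morphology.disk(max(1, min(H, W) // 170))
    mask = morphology.opening(mask, footprint)
    mask = morphology.closing(mask, footprint)
    comps = label(mask, connectivity=1)
    if comps.max() == 0:
        raise ROINotFoundError("sample cluster vanished after cleanup")
    sizes = np.bincount(comps.ravel())[1:]
    # keep every non-trivial patch of the sample cluster: under severe
    # surface whitening the sample hue survives only in scattered islands
    keep = np.flatnonzero(sizes >= max(9, 0.05 * sizes.max())) + 1
    mask = np.isin(comps, keep)
    # the sample slice is convex: the hull recovers surface patches (e.g.
    # whitened blotches) whose color moved into another cluster
    mask = morphology.convex_hull_image(mask)
    if mask.sum() < min_area_fraction * H * W:
        raise ROINotFoundError("sample region below the area threshold")
    return mask


def largest_inscribed_rectangle(mask: np.ndarray) -> RectRegion:
    """Largest axis-aligned rectangle fully inside a binary mask.

    Histogram-stack dynamic programming, O(H*W).  Ties on area are broken by
    the lexicographically smallest (top, left).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise EmptyMaskError("cannot inscribe a rectangle in an empty mask")

    H, W = mask.shape
    heights = np.zeros(W, dtype=np.int64)
    best = None  # (area, top, left, height, width)
    for row in range(H):
        heights = np.where(mask[row], heights + 1, 0)
        # largest rectangle in the histogram `heights`
        stack: list[tuple[int, int]] = []  # (start column, height), increasing
        for col in range(W + 1):
            h = int(heights[col]) if col < W else 0
            start = col
            while stack and stack[-1][1] >= h:
                idx, hh = stack.pop()
                cand = (-hh * (col - idx), row - hh + 1, idx, hh, col - idx)
                if best is None or cand < best:
                    best = cand
                start = idx
            if h > 0:
                stack.append((start, h))
    assert best is not None
    _, top, left, height, width = best
    return RectRegion(top=top, left=left, height=height, width=width)
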