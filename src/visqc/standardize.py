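"""Color standardization against in-scene white and black references.

Each scene carries a white reflectance reference and a black background; an
affine (two-point) per-channel map sending the measured reference means to
nominal white/black removes global illumination changes so that features
extracted from different acquisitions are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import trim_mean

from .exceptions import DegenerateReferencesError, ReferenceNotFoundError
from .scene import SceneLayout

#: Nominal targets of the standardization map.
NOMINAL_WHITE = (255.0, 255.0, 255.0)
NOMINAL_BLACK = (0.0, 0.0, 0.0)

#: Proportion trimmed from each tail when averaging a reference patch.
TRIM = 0.1


@dataclass(frozen=True)
class ReferenceEstimate:
    """Measured white/black reference colors and where they were read."""

    white_mean: tuple[float, float, float]
    black_mean: tuple[float, float, float]
    white_region: tuple[int, int, int, int]
    black_region: tuple[int, int, int, int]

    def validate(self) -> None:
        if not all(w > b for w, b in zip(self.white_mean, self.black_mean)):
            raise DegenerateReferencesError(
                "white reference not brighter than black in every channel")


def _patch_mean(image: np.ndarray, region) -> tuple[float, float, float]:
    t, l, b, r = region
    patch = image[t:b, l:r].reshape(-1, 3).astype(np.float64)
    return tuple(trim_mean(patch[:, c], TRIM) for c in range(3))


def _grow_region(gray, seed_box, tol):
    """Bounding box of the connected near-uniform region containing seed_box."""
    t, l, b, r = seed_box
    mean = gray[t:b, l:r].mean()
    mask = np.abs(gray - mean) <= tol
    labels, _ = ndimage.label(mask)
    lab = labels[(t + b) // 2, (l + r) // 2]
    if lab == 0:
        return seed_box
    rows, cols = np.nonzero(labels == lab)
    return (int(rows.min()), int(cols.min()),
            int(rows.max()) + 1, int(cols.max()) + 1)


def locate_references(image: np.ndarray,
                      layout_hint: SceneLayout | None = None,
                      uniform_sd: float = 8.0) -> ReferenceEstimate:
    """Locate the white and black reference patches and measure their colors.

    With a layout hint the given regions are used directly.  Without one, the
    image is scanned in tiles: the brightest tile whose within-tile standard
    deviation is below ``uniform_sd`` seeds the white patch (grown to the
    surrounding uniform region), and the darkest such tile seeds the black
    estimate.  Per-channel trimmed means (central 80%) are returned.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if layout_hint is not None:
        est = ReferenceEstimate(
            white_mean=_patch_mean(image, layout_hint.white_ref_region),
            black_mean=_patch_mean(image, layout_hint.black_ref_region),
            white_region=layout_hint.white_ref_region,
            black_region=layout_hint.black_ref_region)
        est.validate()
        return est

    gray = image.astype(np.float64).mean(axis=2)
    H, W = gray.shape
    tile = max(8, min(H, W) // 16)
    candidates = []  # (mean, sd, box)
    for t in range(0, H - tile + 1, tile):
        for l in range(0, W - tile + 1, tile):
            patch = gray[t:t + tile, l:l + tile]
            candidates.append((patch.mean(), patch.std(),
                               (t, l, t + tile, l + tile)))
    uniform = [c for c in candidates if c[1] < uniform_sd]
    if not uniform:
        raise ReferenceNotFoundError("no low-variance reference patch found")
    white_seed = max(uniform, key=lambda c: c[0])
    black_seed = min(uniform, key=lambda c: c[0])
    if white_seed[0] - black_seed[0] < 20.0:
        raise ReferenceNotFoundError(
            "no bright uniform patch distinct from the background")
    white_box = _grow_region(gray, white_seed[2], tol=3.0 * uniform_sd)
    black_box = black_seed[2]
    est = ReferenceEstimate(white_mean=_patch_mean(image, white_box),
                            black_mean=_patch_mean(image, black_box),
                            white_region=white_box, black_region=black_box)
    est.validate()
    return est


def standardize_image(image: np.ndarray, refs: ReferenceEstimate,
                      nominal_white=NOMINAL_WHITE,
                      nominal_black=NOMINAL_BLACK) -> np.ndarray:
    """Affine per-channel correction mapping the references to their nominals.

    Pixel values equal to the measured white (black) mean map exactly to the
    nominal white (black); output is rounded half-up and clipped to 8 bits.
    """
    refs.validate()
    nw = np.asarray(nominal_white, dtype=np.float64)
    nb = np.asarray(nominal_black, dtype=np.float64)
    if not np.all(nw > nb):
        raise DegenerateReferencesError("nominal white must exceed black")
    w = np.asarray(refs.white_mean, dtype=np.float64)
    b = np.asarray(refs.black_mean, dtype=np.float64)
    out = (image.astype(np.float64) - b) / (w - b) * (nw - nb) + nb
    return np.floor(np.clip(out, 0.0, 255.0) + 0.5).astype(np.uint8)
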