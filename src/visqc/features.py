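"""Appearance feature extraction: color statistics, wavelet texture features
and gray-level co-occurrence matrix (GLCM) entries.

One image yields an ordered vector of M = MC + MW + MG = 12 + 144 + 2420
= 2576 features under the default configuration:

* color (MC=12): mean, population SD, skewness and excess kurtosis of each
  RGB channel over the segmented region of interest;
* wavelet (MW=144): the same four statistics of every detail subband
  (horizontal/vertical/diagonal) of a 4-level 2-D discrete wavelet transform
  (Daubechies-4) of the ROI's largest inscribed rectangle, per RGB channel;
* GLCM (MG=2420): all entries of the symmetric, normalized co-occurrence
  matrix of the 11-level quantized grayscale crop, for displacements 1-5 px
  at 0/45/90/135 degrees (11*11*5*4 = 2420).

Feature order and names are fixed so that vectors from different images are
column-aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from skimage.feature import graycomatrix

from .exceptions import (ConfigInconsistencyError, DecompositionDepthError,
                         EmptyMaskError, InsufficientExtentError)
from .segment import RectRegion

#: ITU-R BT.601 luma weights.
DEFAULT_GRAY_WEIGHTS = (0.299, 0.587, 0.114)

_CHANNELS = ("R", "G", "B")
_STATS = ("mean", "sd", "skew", "kurt")
_SUBBANDS = ("H", "V", "D")


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the appearance feature extractor."""

    wavelet_family: str = "db4"
    wavelet_levels: int = 4
    wavelet_mode: str = "periodization"
    glcm_levels: int = 11
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    glcm_angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    glcm_symmetric: bool = True
    gray_weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS

    @property
    def n_color(self) -> int:
        return 4 * 3

    @property
    def n_wavelet(self) -> int:
        return 4 * len(_SUBBANDS) * self.wavelet_levels * 3

    @property
    def n_glcm(self) -> int:
        return (self.glcm_levels ** 2 * len(self.glcm_distances)
                * len(self.glcm_angles_deg))

    @property
    def n_features(self) -> int:
        return self.n_color + self.n_wavelet + self.n_glcm


@dataclass(frozen=True)
class FeatureVector:
    """Ordered appearance descriptor of one image."""

    values: np.ndarray
    names: tuple[str, ...]

    def __len__(self) -> int:
        return self.values.size


def _four_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population SD, skewness, excess kurtosis.

    Zero-variance input yields skewness = kurtosis = 0 by convention so
    degenerate (constant) regions produce finite features.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    m = x.mean()
    c = x - m
    var = np.mean(c ** 2)
    sd = np.sqrt(var)
    if sd == 0.0:
        return float(m), 0.0, 0.0, 0.0
    skew = np.mean(c ** 3) / sd ** 3
    kurt = np.mean(c ** 4) / var ** 2 - 3.0
    return float(m), float(sd), float(skew), float(kurt)


def color_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Four statistics of each RGB channel over the masked region (length 12)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("color features need a non-empty mask")
    out = []
    for c in range(3):
        out.extend(_four_stats(image[..., c][mask]))
    return np.asarray(out)


def color_feature_names() -> list[str]:
    return [f"color_{ch}_{st}" for ch in _CHANNELS for st in _STATS]


def rgb_to_gray(image: np.ndarray,
                weights=DEFAULT_GRAY_WEIGHTS) -> np.ndarray:
    """Weighted grayscale conversion; float output in [0, 255]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    w = np.asarray(weights, dtype=np.float64)
    return np.clip(image.astype(np.float64) @ w, 0.0, 255.0)


def wavelet_features(image: np.ndarray, rect: RectRegion,
                     config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Detail-subband statistics of a multi-level 2-D DWT of the crop.

    For each RGB channel the crop is decomposed ``wavelet_levels`` times; for
    each level (finest first) and each detail subband (H, V, D) the four
    statistics are computed.  Default: 3 channels x 4 levels x 3 subbands x 4
    stats = 144 values.
    """
    if min(rect.height, rect.width) < 2 ** config.wavelet_levels:
        raise DecompositionDepthError(
            f"rectangle {rect.height}x{rect.width} too small for "
            f"{config.wavelet_levels} decomposition levels")
    crop = rect.crop(image).astype(np.float64)
    out = []
    for c in range(3):
        with warnings.catch_warnings():
            # boundary-effect warning on small crops; depth is config-driven
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec2(crop[..., c], config.wavelet_family,
                                   mode=config.wavelet_mode,
                                   level=config.wavelet_levels)
        details = coeffs[1:]  # coarsest-to-finest list of (cH, cV, cD)
        for level_bands in reversed(details):  # finest first
            for band in level_bands:
                out.extend(_four_stats(band))
    return np.asarray(out)


def wavelet_feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    return [f"wav_{ch}_L{lv}_{sb}_{st}"
            for ch in _CHANNELS
            for lv in range(1, config.wavelet_levels + 1)
            for sb in _SUBBANDS
            for st in _STATS]


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a [0, 255] gray raster to ``levels`` equal-width bins."""
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    q = np.floor(np.clip(gray, 0.0, 255.0) * levels / 256.0).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm_matrix(quantized: np.ndarray, levels: int, distance: int,
                angle_deg: int, symmetric: bool = True) -> np.ndarray:
    """Normalized co-occurrence matrix for one displacement.

    Angles follow the usual image convention: 0 deg pairs a pixel with its
    horizontal neighbor at the given distance, 90 deg with its vertical
    neighbor (direction is immaterial for a symmetric matrix).
    """
    P = graycomatrix(quantized, distances=[distance],
                     angles=[np.deg2rad(angle_deg)], levels=levels,
                     symmetric=symmetric, normed=True)
    return P[:, :, 0, 0]


def glcm_features(gray: np.ndarray, rect: RectRegion,
                  config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """All entries of every (distance, angle) co-occurrence matrix.

    The crop is quantized once; matrices are flattened row-major and
    concatenated distance-major, angle-minor.  Default: 11^2 * 5 * 4 = 2420.
    """
    if min(rect.height, rect.width) <= max(config.glcm_distances):
        raise InsufficientExtentError(
            "crop smaller than the largest co-occurrence distance")
    q = quantize_gray(rect.crop(gray), config.glcm_levels)
    out = []
    for d in config.glcm_distances:
        for a in config.glcm_angles_deg:
            out.append(glcm_matrix(q, config.glcm_levels, d, a,
                                   config.glcm_symmetric).ravel())
    return np.concatenate(out)


def glcm_feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    L = config.glcm_levels
    return [f"glcm_d{d}_a{a}_i{i}_j{j}"
            for d in config.glcm_distances
            for a in config.glcm_angles_deg
            for i in range(L) for j in range(L)]


def assemble_features(color: np.ndarray, wavelet: np.ndarray,
                      glcm: np.ndarray,
                      config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Concatenate the three blocks into the ordered feature vector."""
    if (len(color) != config.n_color or len(wavelet) != config.n_wavelet
            or len(glcm) != config.n_glcm):
        raise ConfigInconsistencyError(
            f"block lengths ({len(color)}, {len(wavelet)}, {len(glcm)}) do "
            f"not match the configuration ({config.n_color}, "
            f"{config.n_wavelet}, {config.n_glcm})")
    names = (color_feature_names() + wavelet_feature_names(config)
             + glcm_feature_names(config))
    return FeatureVector(values=np.concatenate([color, wavelet, glcm]),
                         names=tuple(names))


def extract_features(image: np.ndarray, mask: np.ndarray, rect: RectRegion,
                     config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Full descriptor of one standardized image given its ROI and rectangle."""
    gray = rgb_to_gray(image, config.gray_weights)
    return assemble_features(color_features(image, mask),
                             wavelet_features(image, rect, config),
                             glcm_features(gray, rect, config), config)
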