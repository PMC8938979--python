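"""8-bit grayscale raster handling.

Loading of single-channel TIFF/PNG micrographs, linear LUT contrast
enhancement, automatic (iterative-intermeans / isodata) thresholding and
binarization to a boolean foreground mask.

All measurements downstream are in pixel units; any physical-resolution
metadata embedded in input files is discarded on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("neuridi")

DARK_FOREGROUND = "dark_foreground"
BRIGHT_FOREGROUND = "bright_foreground"

#: fraction of pixels saturated at *each* histogram tail by autoscale()
AUTOSCALE_SATURATION = 0.0035


class ConfigurationError(ValueError):
    """A parameter set violates its documented constraints."""


class DegenerateHistogramError(ValueError):
    """The image contains a single intensity; no threshold separates classes."""


class PairingError(ValueError):
    """A neurite image and its companion (nuclei / mask) disagree in shape."""


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D uint8 grayscale image.

    Accepts uint8 directly; 16-bit integer input is linearly rescaled
    min->0, max->255. Color (3-D) input is rejected: the method is defined
    on single-channel 8-bit micrographs.
    """
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ConfigurationError(
            f"expected a single-channel 2-D image, got shape {arr.shape}; "
            "convert RGB/multi-channel images to one grayscale channel first"
        )
    if arr.size == 0:
        raise ConfigurationError("image has zero size")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16 or (
        np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) > 255
    ):
        lo, hi = int(arr.min()), int(arr.max())
        if hi == lo:
            return np.zeros(arr.shape, dtype=np.uint8)
        scaled = (arr.astype(np.float64) - lo) * (255.0 / (hi - lo))
        return np.floor(scaled + 0.5).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0:
            raise ConfigurationError("negative intensities are not valid for 8-bit images")
        return arr.astype(np.uint8)
    raise ConfigurationError(f"unsupported image dtype {arr.dtype}")


def load_image(path: str | Path) -> np.ndarray:
    """Read a single-page grayscale TIFF or PNG as a 2-D uint8 array.

    Physical-scale metadata is ignored: all downstream measurements are in
    pixel units.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        # reject color rather than silently flattening channels
        if not (arr[..., :3] == arr[..., :1]).all():
            raise ConfigurationError(
                f"{path}: color image; the pipeline expects single-channel "
                "grayscale micrographs"
            )
        arr = arr[..., 0]
    return as_gray_image(arr)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a 2-D uint8 image (PNG or TIFF chosen by extension)."""
    iio.imwrite(Path(path), np.ascontiguousarray(img))


# ---------------------------------------------------------------------------
# Contrast enhancement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastLUT:
    """Linear lookup table mapping the intensity window [lo, hi] onto [0, 255]."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 255):
            raise ConfigurationError(
                f"LUT window must satisfy 0 <= lo < hi <= 255, got ({self.lo}, {self.hi})"
            )


def apply_lut(img: np.ndarray, lut: ContrastLUT) -> np.ndarray:
    """Remap intensities linearly so that lo -> 0 and hi -> 255, clamped.

    Uses round-half-up on the linear map, the usual 8-bit LUT semantics, so
    the mapping is deterministic and monotone nondecreasing.
    """
    img = as_gray_image(img)
    v = img.astype(np.float64)
    out = np.floor(255.0 * (v - lut.lo) / (lut.hi - lut.lo) + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def autoscale(img: np.ndarray, saturation: float = AUTOSCALE_SATURATION) -> np.ndarray:
    """Linear contrast stretch saturating `saturation` of pixels at each tail.

    The default 0.35% per-tail saturation is the conventional automatic
    enhance-contrast behavior for fluorescence micrographs. Degenerate
    windows (lo == hi) return the image unchanged with a warning.
    """
    img = as_gray_image(img)
    lo = int(np.floor(np.percentile(img, 100.0 * saturation)))
    hi = int(np.ceil(np.percentile(img, 100.0 * (1.0 - saturation))))
    if hi <= lo:
        logger.warning("autoscale: degenerate intensity window (lo=%d, hi=%d); image unchanged", lo, hi)
        return img.copy()
    return apply_lut(img, ContrastLUT(max(lo, 0), min(hi, 255)))


# ---------------------------------------------------------------------------
# Automatic thresholding
# ---------------------------------------------------------------------------

def isodata_threshold(img: np.ndarray) -> int:
    """Iterative-intermeans (isodata) threshold of an 8-bit image.

    Starting from the histogram mean, iterate
        t <- floor((mean of intensities <= t + mean of intensities > t) / 2)
    until stable. The returned integer t lies in [0, 254]; pixels <= t form
    the dark class and pixels > t the bright class (ties go dark, so masks
    are bit-reproducible).

    Raises
    ------
    DegenerateHistogramError
        If the image holds a single intensity value.
    """
    img = as_gray_image(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "constant image: no threshold can separate foreground from background"
        )
    csum = np.cumsum(hist)
    cmass = np.cumsum(hist * levels)
    total, mass = csum[-1], cmass[-1]

    t = int(np.floor(mass / total))
    seen: set[int] = set()
    while t not in seen:
        seen.add(t)
        n_low = csum[t]
        if n_low == 0 or n_low == total:  # one side empty: nudge toward the data
            t = int(levels[hist > 0][0]) if n_low == 0 else int(levels[hist > 0][-2])
            continue
        m_low = cmass[t] / n_low
        m_high = (mass - cmass[t]) / (total - n_low)
        t = int(np.floor((m_low + m_high) / 2.0))
    return min(t, 254)


def binarize(img: np.ndarray, mode: str = BRIGHT_FOREGROUND) -> np.ndarray:
    """Threshold an image to a boolean foreground mask.

    ``dark_foreground`` selects pixels <= t (phase-contrast cells are dark);
    ``bright_foreground`` selects pixels > t (fluorescence signal is bright).
    True always means biological signal regardless of display polarity.
    A degenerate (constant) image yields an all-false mask with a warning so
    batch runs keep going.
    """
    img = as_gray_image(img)
    if mode not in (DARK_FOREGROUND, BRIGHT_FOREGROUND):
        raise ConfigurationError(
            f"unknown binarization mode {mode!r}; expected "
            f"{DARK_FOREGROUND!r} or {BRIGHT_FOREGROUND!r}"
        )
    try:
        t = isodata_threshold(img)
    except DegenerateHistogramError:
        logger.warning("binarize: constant image, returning empty foreground mask")
        return np.zeros(img.shape, dtype=bool)
    if mode == DARK_FOREGROUND:
        return img <= t
    return img > t
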