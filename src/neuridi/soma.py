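"""Automated soma removal.

Cell bodies must be excluded from Degeneration Index measurements: a soma is
a large contiguous blob that would distort both the fragment and total-area
terms. The automated route builds an enlarged soma mask from the paired
nuclear-stain (DAPI/Hoechst) image - binarize the nuclei, drop small
non-nuclear artifacts, then grow the nuclear regions with a run of binary
dilations (and a light trailing erosion that fuses fragmented nuclei) until
they cover the whole soma - and subtracts that mask from the neurite image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .particles import remove_small_particles
from .raster import (
    BRIGHT_FOREGROUND,
    ConfigurationError,
    PairingError,
    as_gray_image,
    autoscale,
    binarize,
)

logger = logging.getLogger("neuridi")

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SomaRemovalConfig:
    """Parameters of the nuclear-dilation soma mask.

    n_dilations
        Number of 3x3-square binary dilations applied to the cleaned nuclear
        mask; each adds one pixel per side. 12 suits mesencephalic (LUHMES)
        cultures; 16 removes the larger somas of sympathetic neurons.
    n_erosions
        Trailing erosions (same element). Together with the dilations this
        acts as a morphological closing that merges fragmented nuclei while
        keeping a net expansion of n_dilations - n_erosions pixels.
    nuclear_artifact_max
        Components of the binarized nuclei image at or below this area (px)
        are discarded as non-nuclear debris before dilation.
    """

    n_dilations: int = 12
    n_erosions: int = 2
    nuclear_artifact_max: int = 50

    def __post_init__(self) -> None:
        if not (self.n_dilations >= self.n_erosions >= 0):
            raise ConfigurationError(
                "soma removal requires n_dilations >= n_erosions >= 0, got "
                f"({self.n_dilations}, {self.n_erosions})"
            )
        if self.nuclear_artifact_max < 0:
            raise ConfigurationError("nuclear_artifact_max must be >= 0")


def build_soma_mask(
    nuclei_img: np.ndarray,
    cfg: SomaRemovalConfig = SomaRemovalConfig(),
    *,
    expected_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Binarize a nuclear-stain image and grow it into a soma mask.

    Pipeline: autoscale contrast -> bright-foreground binarization ->
    small-artifact removal -> n_dilations dilations -> n_erosions erosions,
    all with the 3x3 full-square structuring element. Whenever
    n_dilations > n_erosions the result is a superset of the cleaned nuclear
    mask. A blank nuclei image yields an empty mask.
    """
    nuclei_img = as_gray_image(nuclei_img)
    if expected_shape is not None and nuclei_img.shape != tuple(expected_shape):
        raise PairingError(
            f"nuclei image shape {nuclei_img.shape} does not match paired "
            f"neurite image shape {tuple(expected_shape)}"
        )
    mask = binarize(autoscale(nuclei_img), BRIGHT_FOREGROUND)
    mask = remove_small_particles(mask, cfg.nuclear_artifact_max)
    if not mask.any():
        return mask
    if cfg.n_dilations:
        mask = ndi.binary_dilation(mask, structure=_STRUCT8, iterations=cfg.n_dilations)
    if cfg.n_erosions:
        mask = ndi.binary_erosion(mask, structure=_STRUCT8, iterations=cfg.n_erosions)
    return mask


def subtract_mask(target: np.ndarray, soma: np.ndarray, *, background: int = 0) -> np.ndarray:
    """Blank every pixel under the soma mask; leave the rest untouched.

    Works on grayscale images (soma pixels set to `background`, 0 for
    fluorescence and 255 for phase-contrast polarity) and on boolean masks
    (soma pixels set false). Idempotent; the result never has foreground
    inside the soma region.
    """
    soma = np.asarray(soma, dtype=bool)
    target = np.asarray(target)
    if target.shape != soma.shape:
        raise PairingError(
            f"cannot subtract soma mask of shape {soma.shape} from image of shape {target.shape}"
        )
    if target.dtype == bool:
        return target & ~soma
    out = as_gray_image(target).copy()
    out[soma] = np.uint8(background)
    return out
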