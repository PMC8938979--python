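"""Degeneration Index (DI) computation and named method presets.

DI = (summed area of detected neurite fragments) / (total neurite area) on a
binarized, soma-free neurite mask; 0.0 means fully intact, 1.0 fully
fragmented. Fragments are the connected components admitted by a
size-circularity filter; the total area is every foreground pixel that
survived soma subtraction and small-particle removal. A blank field (zero
total area) yields an *undefined* DI, reported as missing rather than 0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .particles import ParticleFilter, label_components, select_fragments
from .raster import (
    BRIGHT_FOREGROUND,
    DARK_FOREGROUND,
    ConfigurationError,
    ContrastLUT,
)
from .soma import SomaRemovalConfig

logger = logging.getLogger("neuridi")

#: half-open rectangle (row0, col0, row1, col1), 0-based
Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class DIResult:
    """One DI measurement with its provenance."""

    fragment_area: int
    total_area: int
    di: float | None  # None when total_area == 0 (undefined, not 0)
    n_fragments: int
    preset_name: str = ""
    source_image: str = ""

    def to_row(self) -> dict:
        """Serialize to one CSV row; undefined DI becomes an empty cell."""
        return {
            "image": self.source_image,
            "preset": self.preset_name,
            "fragment_area_px": self.fragment_area,
            "total_area_px": self.total_area,
            "n_fragments": self.n_fragments,
            "di": "" if self.di is None else f"{self.di:.6f}",
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Complete parameter set for one DI analysis route.

    `soma` set to a SomaRemovalConfig selects automated soma removal from a
    paired nuclei image; `manual_masks` selects user-supplied binary soma
    masks; with neither, images are assumed pre-cleaned of cell bodies.
    """

    binarize_mode: str
    fragment_filter: ParticleFilter
    remover_max: int = 0
    lut: ContrastLUT | None = None
    autoscale: bool = False
    soma: SomaRemovalConfig | None = None
    manual_masks: bool = False
    preset_name: str = "custom"

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Presets are immutable; overriding produces a new named config."""
        kwargs.setdefault("preset_name", f"{self.preset_name}*")
        return replace(self, **kwargs)


_PRESETS = {
    # fully automated fluorescence route: autoscale contrast, automated
    # nuclear-dilation soma removal, 0-4 px remover, 5-10,000 px fragments
    "andi_fluorescence": PipelineConfig(
        binarize_mode=BRIGHT_FOREGROUND,
        fragment_filter=ParticleFilter(5, 10000, 0.2, 1.0),
        remover_max=4,
        lut=None,
        autoscale=True,
        soma=SomaRemovalConfig(n_dilations=12, n_erosions=2, nuclear_artifact_max=50),
        manual_masks=False,
        preset_name="andi_fluorescence",
    ),
    # optimized phase-contrast route: LUT 90-205, 0-9 px remover,
    # 10-10,000 px fragments, manual soma masks
    "phase_optimized": PipelineConfig(
        binarize_mode=DARK_FOREGROUND,
        fragment_filter=ParticleFilter(10, 10000, 0.2, 1.0),
        remover_max=9,
        lut=ContrastLUT(90, 205),
        autoscale=False,
        soma=None,
        manual_masks=True,
        preset_name="phase_optimized",
    ),
    # the widely cited legacy procedure: no contrast enhancement, no
    # remover, 20-10,000 px fragments, manual soma removal
    "traditional_legacy": PipelineConfig(
        binarize_mode=DARK_FOREGROUND,
        fragment_filter=ParticleFilter(20, 10000, 0.2, 1.0),
        remover_max=0,
        lut=None,
        autoscale=False,
        soma=None,
        manual_masks=True,
        preset_name="traditional_legacy",
    ),
}


def preset(name: str) -> PipelineConfig:
    """Return one of the named, immutable analysis presets."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}"
        ) from None


def compute_di(
    neurite_mask: np.ndarray,
    fragment_filter: ParticleFilter,
    roi: Rect | None = None,
    *,
    preset_name: str = "",
    source_image: str = "",
) -> DIResult:
    """Measure the Degeneration Index of a soma-free neurite mask.

    The mask is expected to be post-soma-removal and post-particle-removal.
    With an ROI the mask is clipped to the half-open rectangle first, so
    components straddling the edge are re-measured inside it (this is what
    makes fixed-size-region measurements sensitive to artificial
    fragmentation at the border). total_area counts every foreground pixel;
    fragment_area sums the components admitted by the filter.
    """
    neurite_mask = np.asarray(neurite_mask, dtype=bool)
    if roi is not None:
        r0, c0, r1, c1 = roi
        h, w = neurite_mask.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ConfigurationError(
                f"ROI {roi} does not fit inside mask of shape {neurite_mask.shape}"
            )
        neurite_mask = neurite_mask[r0:r1, c0:c1]
    total_area = int(neurite_mask.sum())
    if total_area == 0:
        logger.warning(
            "compute_di: empty neurite mask%s; DI undefined",
            f" for {source_image}" if source_image else "",
        )
        return DIResult(0, 0, None, 0, preset_name, source_image)
    fragments = select_fragments(label_components(neurite_mask), fragment_filter)
    fragment_area = int(sum(p.area for p in fragments))
    return DIResult(
        fragment_area=fragment_area,
        total_area=total_area,
        di=fragment_area / total_area,
        n_fragments=len(fragments),
        preset_name=preset_name,
        source_image=source_image,
    )


def di_in_roi(
    neurite_mask: np.ndarray,
    fragment_filter: ParticleFilter,
    roi: Rect,
    **kwargs,
) -> DIResult:
    """DI restricted to a rectangular region (e.g. a 150x150 px window).

    Named entry point for artificial-fragmentation studies that compare the
    same region across renderings; identical to compute_di with an ROI.
    """
    return compute_di(neurite_mask, fragment_filter, roi=roi, **kwargs)
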