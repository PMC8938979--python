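"""Directory-level batch automation.

Pairs neurite micrographs with their companion nuclei images (or manual soma
masks) by sorted filename, runs the configured DI pipeline on every pair,
and writes a timestamped results CSV plus one fragment-overlay image per
input. One corrupt image never aborts a batch: failures are logged, the row
is skipped, and the run continues.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import raster
from .di import DIResult, PipelineConfig, compute_di
from .particles import label_components, remove_small_particles, select_fragments
from .raster import BRIGHT_FOREGROUND, ConfigurationError
from .soma import build_soma_mask, subtract_mask

logger = logging.getLogger("neuridi")

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}


class CountMismatchError(ValueError):
    """Paired directories hold different numbers of images."""


@dataclass
class BatchJob:
    """A planned batch run: the ordered image pairs and the configuration."""

    neurite_dir: Path
    out_dir: Path
    config: PipelineConfig
    nuclei_dir: Path | None = None
    mask_dir: Path | None = None
    pairs: list[tuple[Path, Path | None]] = field(default_factory=list)


def _list_images(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def plan_job(
    neurite_dir: str | Path,
    nuclei_dir: str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig,
    *,
    mask_dir: str | Path | None = None,
    strict_names: bool = False,
) -> BatchJob:
    """Enumerate and pair input images; refuse to start on a bad plan.

    Images are paired index-to-index in ascending lexicographic filename
    order (non-image files are ignored). When the companion directory holds
    a different number of images the job refuses to start, naming both
    totals. With `strict_names` the paired files must share a stem.
    """
    neurite_dir = Path(neurite_dir)
    out_dir = Path(out_dir)
    if not neurite_dir.is_dir():
        raise ConfigurationError(f"neurite directory {neurite_dir} does not exist")
    neurites = _list_images(neurite_dir)
    if not neurites:
        raise ConfigurationError(f"no TIFF/PNG images found in {neurite_dir}")

    companion_dir: Path | None = None
    if nuclei_dir is not None:
        companion_dir = Path(nuclei_dir)
    elif mask_dir is not None:
        companion_dir = Path(mask_dir)

    companions: list[Path | None]
    if companion_dir is not None:
        if not companion_dir.is_dir():
            raise ConfigurationError(f"companion directory {companion_dir} does not exist")
        comp = _list_images(companion_dir)
        if len(comp) != len(neurites):
            raise CountMismatchError(
                f"{neurite_dir} holds {len(neurites)} images but "
                f"{companion_dir} holds {len(comp)}; the directories must "
                "contain an equal number of images"
            )
        if strict_names:
            for a, b in zip(neurites, comp):
                if a.stem != b.stem:
                    raise ConfigurationError(
                        f"strict name matching: {a.name} paired with {b.name}"
                    )
        companions = list(comp)
    else:
        companions = [None] * len(neurites)

    job = BatchJob(
        neurite_dir=neurite_dir,
        out_dir=out_dir,
        config=config,
        nuclei_dir=Path(nuclei_dir) if nuclei_dir is not None else None,
        mask_dir=Path(mask_dir) if mask_dir is not None else None,
        pairs=list(zip(neurites, companions)),
    )
    logger.info("planned %d image pair(s):", len(job.pairs))
    for a, b in job.pairs:
        logger.info("  %s  <->  %s", a.name, b.name if b else "(none)")
    return job


def analyze_pair(
    neurite_img: np.ndarray,
    config: PipelineConfig,
    *,
    nuclei_img: np.ndarray | None = None,
    soma_mask: np.ndarray | None = None,
    source_image: str = "",
) -> tuple[DIResult, np.ndarray]:
    """Run the full single-image DI pipeline on in-memory arrays.

    Order of operations: contrast enhancement -> soma-mask construction
    (automated from nuclei, or supplied) -> subtraction from the grayscale
    neurite image -> binarization -> small-particle removal -> DI. Returns
    the DIResult together with the final neurite mask the DI was measured
    on (useful for overlays and audits).
    """
    img = raster.as_gray_image(neurite_img)
    if config.lut is not None:
        img = raster.apply_lut(img, config.lut)
    elif config.autoscale:
        img = raster.autoscale(img)

    if soma_mask is None and config.soma is not None and nuclei_img is not None:
        soma_mask = build_soma_mask(nuclei_img, config.soma, expected_shape=img.shape)
    if soma_mask is not None:
        background = 0 if config.binarize_mode == BRIGHT_FOREGROUND else 255
        img = subtract_mask(img, soma_mask, background=background)

    mask = raster.binarize(img, config.binarize_mode)
    if config.remover_max > 0:
        mask = remove_small_particles(mask, config.remover_max)
    result = compute_di(
        mask,
        config.fragment_filter,
        preset_name=config.preset_name,
        source_image=source_image,
    )
    return result, mask


def render_overlay(mask: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """RGB audit image: black binarized neurites on white, fragments in red.

    The red pixels are exactly the pixels of the fragments counted in the
    DI numerator.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.full(mask.shape + (3,), 255, dtype=np.uint8)
    out[mask] = (0, 0, 0)
    for p in select_fragments(label_components(mask), config.fragment_filter):
        out[p.coords[:, 0], p.coords[:, 1]] = (255, 0, 0)
    return out


def run_job(job: BatchJob) -> pd.DataFrame:
    """Execute a planned batch and write CSV + overlay outputs.

    Writes `results_<timestamp>.csv` (columns: image, preset,
    fragment_area_px, total_area_px, n_fragments, di - empty cell when
    undefined) and `overlay_<image>.png` per input into job.out_dir. Outputs
    are freshly timestamped, never merged with a previous run. Individual
    image failures are logged and skipped. Returns the results table.
    """
    job.out_dir.mkdir(parents=True, exist_ok=True)
    probe = job.out_dir / ".neuridi_write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ConfigurationError(f"output directory {job.out_dir} is not writable: {exc}")

    rows: list[dict] = []
    n_failed = 0
    for i, (neurite_path, companion) in enumerate(job.pairs, start=1):
        logger.info("[%d/%d] analyzing %s", i, len(job.pairs), neurite_path.name)
        try:
            img = raster.load_image(neurite_path)
            nuclei = None
            soma = None
            if companion is not None:
                if job.nuclei_dir is not None:
                    nuclei = raster.load_image(companion)
                else:  # manual binary soma mask
                    soma = raster.load_image(companion) > 0
            result, mask = analyze_pair(
                img,
                job.config,
                nuclei_img=nuclei,
                soma_mask=soma,
                source_image=neurite_path.name,
            )
            overlay = render_overlay(mask, job.config)
            raster.save_image(job.out_dir / f"overlay_{neurite_path.stem}.png", overlay)
            rows.append(result.to_row())
        except Exception:
            n_failed += 1
            logger.exception("failed to analyze %s; continuing with next image", neurite_path.name)

    table = pd.DataFrame(
        rows,
        columns=["image", "preset", "fragment_area_px", "total_area_px", "n_fragments", "di"],
    )
    stamp = time.strftime("%Y%m%d-%H%M%S")
    csv_path = job.out_dir / f"results_{stamp}.csv"
    if csv_path.exists():  # two runs within a second: keep both
        k = 1
        while (job.out_dir / f"results_{stamp}_{k}.csv").exists():
            k += 1
        csv_path = job.out_dir / f"results_{stamp}_{k}.csv"
    table.to_csv(csv_path, index=False)
    logger.info(
        "batch complete: %d analyzed, %d failed/skipped; results in %s",
        len(rows), n_failed, csv_path,
    )
    return table
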