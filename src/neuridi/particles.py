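"""Connected-component particle analysis.

8-connected labeling, per-particle area / perimeter / circularity, the
size-circularity fragment selector, and small-particle removal. This mirrors
the Analyze-Particles / Particle-Remover style of measurement used for
neurite-fragment detection: round blobs (circularity 0.2-1.0) within a pixel
size window count as fragments, elongated intact neurites do not.

Conventions (fixed so results are bit-reproducible):
  * connectivity is 8-connected; diagonal fragments never split
  * area = number of member pixels; interior holes are not counted
  * perimeter = outer-boundary chain code, straight steps weight 1 and
    diagonal steps weight sqrt(2)
  * circularity = 4*pi*area / perimeter**2, capped at 1.0 (discretization
    can push the raw ratio above 1 for tiny particles)
  * size bounds are inclusive on both ends
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .raster import ConfigurationError

_STRUCT8 = np.ones((3, 3), dtype=bool)

# Moore neighborhood, clockwise from north
_DIRS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_W = tuple(1.0 if k % 2 == 0 else math.sqrt(2) for k in range(8))  # straight=1, diagonal=sqrt2
_DIR_INDEX = {d: k for k, d in enumerate(_DIRS)}


@dataclass
class Particle:
    """One 8-connected foreground component with its shape measurements."""

    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    coords: np.ndarray  # (n, 2) member pixel coordinates
    perimeter: float = 0.0
    circularity: float = 0.0


@dataclass(frozen=True)
class ParticleFilter:
    """Inclusive size and circularity window for fragment selection."""

    size_min: int
    size_max: int
    circ_min: float
    circ_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.size_min <= self.size_max):
            raise ConfigurationError(
                f"size window must satisfy 0 <= min <= max, got ({self.size_min}, {self.size_max})"
            )
        if not (0.0 <= self.circ_min <= self.circ_max <= 1.0):
            raise ConfigurationError(
                f"circularity window must lie in [0, 1], got ({self.circ_min}, {self.circ_max})"
            )

    def admits(self, p: Particle) -> bool:
        return (
            self.size_min <= p.area <= self.size_max
            and self.circ_min <= p.circularity <= self.circ_max
        )


def _trace_perimeter(sub: np.ndarray) -> float:
    """Chain-code length of the outer boundary of a single component.

    `sub` is a boolean array padded with at least one background pixel on
    every side and containing exactly one 8-connected component. Moore
    boundary tracing, clockwise; an isolated pixel has chain length 0.
    """
    rows, cols = np.nonzero(sub)
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost (raster order)
    c, b = start, 6  # backtrack begins at the (background) west neighbor
    perim = 0.0
    state0 = None
    limit = 8 * len(rows) + 8
    steps = 0
    while steps <= limit:
        k_found = None
        for i in range(1, 9):
            k = (b + i) % 8
            if sub[c[0] + _DIRS[k][0], c[1] + _DIRS[k][1]]:
                k_found = k
                break
        if k_found is None:
            return 0.0  # isolated pixel
        if state0 is None:
            state0 = (c, k_found)
        elif (c, k_found) == state0:
            break
        perim += _W[k_found]
        prev = (k_found - 1) % 8  # last background neighbor examined
        bg = (c[0] + _DIRS[prev][0], c[1] + _DIRS[prev][1])
        c = (c[0] + _DIRS[k_found][0], c[1] + _DIRS[k_found][1])
        b = _DIR_INDEX[(bg[0] - c[0], bg[1] - c[1])]
        steps += 1
    return perim


def measure_particle(p: Particle) -> Particle:
    """Fill perimeter and circularity of a labeled particle (in place).

    Circularity is 4*pi*area/perimeter^2 capped at 1.0; degenerate boundaries
    (single pixel, chain length 0) report circularity exactly 1.0.
    """
    r0, c0, r1, c1 = p.bbox
    sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    sub[p.coords[:, 0] - r0 + 1, p.coords[:, 1] - c0 + 1] = True
    p.perimeter = _trace_perimeter(sub)
    if p.perimeter <= 0.0:
        p.circularity = 1.0
    else:
        p.circularity = min(1.0, 4.0 * math.pi * p.area / (p.perimeter**2))
    return p


def label_components(mask: np.ndarray) -> list[Particle]:
    """Partition a foreground mask into measured 8-connected particles.

    Labels are assigned 1..n in raster-scan order of each component's first
    pixel. Every foreground pixel belongs to exactly one particle; an empty
    mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    flat = lab.ravel()
    uniq, first = np.unique(flat, return_index=True)
    order = [int(u) for u in uniq[np.argsort(first)] if u != 0]
    slices = ndi.find_objects(lab)
    particles: list[Particle] = []
    for new_label, old in enumerate(order, start=1):
        sl = slices[old - 1]
        local = lab[sl] == old
        coords = np.argwhere(local)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        p = Particle(
            label=new_label,
            area=int(coords.shape[0]),
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            coords=coords,
        )
        particles.append(measure_particle(p))
    return particles


def select_fragments(particles: list[Particle], f: ParticleFilter) -> list[Particle]:
    """Pure filter: particles whose area and circularity fall in the window."""
    return [p for p in particles if f.admits(p)]


def remove_small_particles(mask: np.ndarray, max_size: int) -> np.ndarray:
    """Erase every 8-connected component of area <= max_size.

    The particle-remover step: size window "0-N" erases areas 1..N (area-0
    components do not exist). Retained components are untouched, so output
    foreground is a subset of the input and total area is conserved between
    the survivors and the removed set.
    """
    if max_size < 0:
        raise ConfigurationError(f"max_size must be >= 0, got {max_size}")
    mask = np.asarray(mask, dtype=bool)
    if max_size == 0 or not mask.any():
        return mask.copy()
    lab, n = ndi.label(mask, structure=_STRUCT8)
    areas = np.bincount(lab.ravel(), minlength=n + 1)
    keep = areas > max_size
    keep[0] = False
    return keep[lab]
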