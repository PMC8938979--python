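"""Shared fixtures: independent brute-force oracles and mask builders."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


def flood_fill_components(mask: np.ndarray) -> list[dict]:
    """Brute-force 8-connected labeling by breadth-first flood fill.

    Independent of the package implementation: plain BFS over the boolean
    grid, components discovered in raster-scan order. Returns a list of
    dicts with area, bbox (half-open) and the coordinate set.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            q = deque([(r, c)])
            seen[r, c] = True
            pix = []
            while q:
                pr, pc = q.popleft()
                pix.append((pr, pc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = pr + dr, pc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
            rows = [p[0] for p in pix]
            cols = [p[1] for p in pix]
            comps.append(
                {
                    "area": len(pix),
                    "bbox": (min(rows), min(cols), max(rows) + 1, max(cols) + 1),
                    "pixels": frozenset(pix),
                }
            )
    return comps


@pytest.fixture
def flood_oracle():
    return flood_fill_components


@pytest.fixture
def random_masks():
    """Deterministic stream of small random boolean masks."""

    def make(n: int, shape=(20, 20), density: float = 0.35, seed: int = 0):
        rng = np.random.default_rng(seed)
        return [rng.random(shape) < density for _ in range(n)]

    return make
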