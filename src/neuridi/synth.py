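"""Synthetic micrograph generator with per-pixel ground truth.

Renders paired neurite / nuclear-stain images that emulate a fluorescence
field of cultured neurons: smooth curvilinear intact neurites, beaded
elliptical fragments replacing a controlled fraction of each neurite's
length (the beading morphology of degenerating processes), soma disks at
neurite origins with concentric nuclei rendered only into the nuclei
channel, sub-threshold debris specks, and additive Gaussian noise.

Every structural class is also emitted as a boolean ground-truth mask, so
each pipeline stage (thresholding, particle filtering, soma removal, DI)
can be tested against known truth without any external image set. The
realized fragmentation fraction ``true_f`` is measured from the rendered
masks, not taken from the request, so rasterization drift is exposed
rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .raster import ConfigurationError, save_image


class GenerationError(RuntimeError):
    """The requested scene geometry cannot be realized in the frame."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field.

    Defaults emulate a 20x fluorescence field of a differentiated
    mesencephalic culture captured on a 1280 x 1024 camera (~0.34 um/px):
    soma radius ~20 px (~7 um), nuclei ~16 px, neurites 2-4 px wide and
    several hundred px long. Signal and background are separated by many
    noise standard deviations, the regime in which histogram-based
    automatic thresholding is well defined; the spec enforces a minimum
    separation of 5 x noise_sd.
    """

    width: int = 1280
    height: int = 1024
    n_neurites: int = 16
    fragmentation_fraction: float = 0.0
    n_somas: int = 16
    soma_radius: int = 20
    nucleus_radius: int = 13
    n_debris: int = 40
    debris_max_area: int = 4
    background_level: int = 20
    signal_level: int = 200
    noise_sd: float = 4.0
    stroke_width_range: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fragmentation_fraction <= 1.0):
            raise ConfigurationError("fragmentation_fraction must lie in [0, 1]")
        if abs(self.signal_level - self.background_level) < 5.0 * self.noise_sd:
            raise ConfigurationError(
                "signal and background must differ by at least 5 x noise_sd "
                "so automatic thresholding can separate the classes; use "
                "render_from_truth() for deliberate low-contrast renderings"
            )
        if not (0 <= self.n_somas <= self.n_neurites):
            raise ConfigurationError("n_somas must lie in [0, n_neurites]")
        if self.nucleus_radius >= self.soma_radius + 1 and self.n_somas:
            raise ConfigurationError("nucleus_radius should not exceed soma_radius")
        if min(self.width, self.height) < 64:
            raise ConfigurationError("frame must be at least 64 x 64 px")
        w_lo, w_hi = self.stroke_width_range
        if not (1 <= w_lo <= w_hi <= 8):
            raise ConfigurationError("stroke_width_range must satisfy 1 <= lo <= hi <= 8")
        if self.n_somas and self.n_somas * (2.5 * self.soma_radius) ** 2 > self.width * self.height:
            raise GenerationError(
                f"{self.n_somas} somas of radius {self.soma_radius} do not fit "
                f"a {self.width} x {self.height} frame"
            )


@dataclass
class GroundTruth:
    """Per-class pixel truth for one scene.

    The five masks are pairwise disjoint; the nucleus disk sits inside the
    soma disk, so ``soma_mask`` excludes nucleus pixels and the full cell
    body footprint is ``soma_footprint`` (= soma_mask | nucleus_mask).
    ``true_f`` is fragment area / (fragment area + intact area) of the
    rendered masks.
    """

    intact_mask: np.ndarray
    fragment_mask: np.ndarray
    soma_mask: np.ndarray
    nucleus_mask: np.ndarray
    debris_mask: np.ndarray
    true_f: float

    @property
    def soma_footprint(self) -> np.ndarray:
        return self.soma_mask | self.nucleus_mask

    @property
    def neurite_signal(self) -> np.ndarray:
        """All pixels bright in the neurite channel."""
        return (
            self.intact_mask | self.fragment_mask | self.soma_footprint | self.debris_mask
        )


def _curve_points(
    rng: np.random.Generator,
    h: int,
    w: int,
    start: tuple[float, float],
    length: int,
    obstacles: list[tuple[float, float]] | None = None,
    avoid_radius: float = 0.0,
) -> np.ndarray:
    """Smooth random-walk centerline: unit steps with drifting heading.

    The walk steers gently back toward the interior near the frame border
    and away from obstacle disks (foreign somas), so a neurite is only ever
    severed at its own origin soma.
    """
    r, c = start
    theta = rng.uniform(0.0, 2.0 * math.pi)
    pts = np.empty((length, 2))
    soft = 35.0  # steer smoothly back toward the interior inside this margin
    obstacles = obstacles or []
    for i in range(length):
        pts[i] = (r, c)
        theta += rng.normal(0.0, 0.035)
        if r < soft or r > h - 1 - soft or c < soft or c > w - 1 - soft:
            target = math.atan2(h / 2.0 - r, w / 2.0 - c)
            diff = (target - theta + math.pi) % (2.0 * math.pi) - math.pi
            theta += min(max(diff, -0.09), 0.09)
        for r0, c0 in obstacles:
            if (r - r0) ** 2 + (c - c0) ** 2 < avoid_radius**2:
                away = math.atan2(r - r0, c - c0)
                diff = (away - theta + math.pi) % (2.0 * math.pi) - math.pi
                theta += min(max(diff, -0.3), 0.3)
                break
        r = min(max(r + math.sin(theta), 2.0), h - 3.0)
        c = min(max(c + math.cos(theta), 2.0), w - 3.0)
    return pts


def _stroke(points: np.ndarray, width: int, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    idx = np.round(points).astype(int)
    canvas[idx[:, 0], idx[:, 1]] = True
    if width > 1:
        canvas = ndi.binary_dilation(canvas, structure=np.ones((width, width), bool))
    return canvas


def _dilate1(mask: np.ndarray) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=np.ones((3, 3), bool))


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one paired (neurite, nuclei) scene plus its ground truth.

    The same seed reproduces the scene bit-exactly. Somas are placed at the
    proximal endpoint of the first ``n_somas`` neurites; the fragmented
    fraction of each curve is its distal end, matching the distal-first
    progression of neurite degeneration. Beads are only stamped where they
    touch no other structure, so rendered fragments stay disjoint
    connected components; any skipped bead is reflected in ``true_f``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    shape = (h, w)

    soma_canvas = np.zeros(shape, dtype=bool)
    nucleus_canvas = np.zeros(shape, dtype=bool)
    intact_canvas = np.zeros(shape, dtype=bool)
    fragment_canvas = np.zeros(shape, dtype=bool)
    debris_canvas = np.zeros(shape, dtype=bool)

    # soma centers with mutual separation, then one curve per neurite
    soma_centers: list[tuple[float, float]] = []
    margin = spec.soma_radius + 4
    tries = 0
    while len(soma_centers) < spec.n_somas:
        tries += 1
        if tries > 200 * max(spec.n_somas, 1):
            raise GenerationError("could not place the requested somas in the frame")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all(
            (r - r0) ** 2 + (c - c0) ** 2 >= (2.2 * spec.soma_radius) ** 2
            for r0, c0 in soma_centers
        ):
            soma_centers.append((r, c))
    for r, c in soma_centers:
        rr, cc = draw_disk((r, c), spec.soma_radius, shape=shape)
        soma_canvas[rr, cc] = True
        rr, cc = draw_disk((r, c), spec.nucleus_radius, shape=shape)
        nucleus_canvas[rr, cc] = True

    curves: list[tuple[np.ndarray, int, int]] = []  # (points, stroke width, soma index)
    avoid = float(spec.soma_radius + 10)
    for i in range(spec.n_neurites):
        if i < spec.n_somas:
            start = soma_centers[i]
            obstacles = soma_centers[:i] + soma_centers[i + 1:]
        else:
            start = (rng.uniform(26, h - 26), rng.uniform(26, w - 26))
            obstacles = soma_centers
        length = int(rng.integers(300, 451))
        width_px = int(rng.integers(spec.stroke_width_range[0], spec.stroke_width_range[1] + 1))
        pts = _curve_points(rng, h, w, start, length, obstacles, avoid)
        curves.append((pts, width_px, i if i < spec.n_somas else -1))

    # pass 1: intact strokes (the proximal 1-f of every curve). For partial
    # fragmentation the surviving remnant keeps at least ~90 px of visible
    # length so an intact neurite stub is never short enough to read as a
    # round fragment; the realized fraction is measured into true_f anyway.
    min_remnant = 90
    frag_start: list[int] = []
    f = spec.fragmentation_fraction
    for pts, width_px, soma_idx in curves:
        n = len(pts)
        k = int(round(f * n))
        if 0.0 < f < 1.0:
            hidden = 0
            if soma_idx >= 0:
                r0, c0 = soma_centers[soma_idx]
                hidden = int(
                    np.count_nonzero(
                        (pts[:, 0] - r0) ** 2 + (pts[:, 1] - c0) ** 2
                        < (spec.soma_radius + 3) ** 2
                    )
                )
            k = max(0, min(k, n - hidden - min_remnant))
        frag_start.append(n - k)
        if n - k > 1:
            intact_canvas |= _stroke(pts[: n - k], width_px, shape)

    # pass 2: beads along the distal fragmented arc, never touching anything
    occupied = _dilate1(
        intact_canvas
        | ndi.binary_dilation(soma_canvas, structure=np.ones((3, 3), bool), iterations=6)
    )
    for (pts, _, _), f0 in zip(curves, frag_start):
        n = len(pts)
        i = f0 + 2
        while i < n:
            a = rng.uniform(2.2, 4.2)
            b = rng.uniform(1.6, min(a, 3.2))
            gap = rng.uniform(3.0, 8.0)
            j = min(i + 3, n - 1)
            theta = math.atan2(pts[j][0] - pts[i][0], pts[j][1] - pts[i][1])
            center = pts[min(i + int(a), n - 1)]
            rr, cc = draw_ellipse(
                center[0], center[1], b, a,
                shape=shape, rotation=math.atan2(math.sin(theta), math.cos(theta)),
            )
            if rr.size >= 5 and not occupied[rr, cc].any():
                fragment_canvas[rr, cc] = True
                bead = np.zeros(shape, dtype=bool)
                bead[rr, cc] = True
                occupied |= _dilate1(bead)
            i += int(2 * a + gap)

    # pass 3: debris specks (small 4-connected random blobs)
    for _ in range(spec.n_debris):
        size = int(rng.integers(1, spec.debris_max_area + 1))
        for _attempt in range(25):
            r = int(rng.integers(2, h - 2))
            c = int(rng.integers(2, w - 2))
            pix = {(r, c)}
            while len(pix) < size:
                pr, pc = list(pix)[int(rng.integers(0, len(pix)))]
                dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(rng.integers(0, 4))]
                q = (min(max(pr + dr, 1), h - 2), min(max(pc + dc, 1), w - 2))
                pix.add(q)
            rows = np.fromiter((p[0] for p in pix), dtype=int)
            cols = np.fromiter((p[1] for p in pix), dtype=int)
            grown = np.unique(
                np.stack(
                    [np.clip(rows[:, None] + np.arange(-1, 2), 0, h - 1).repeat(3, axis=1).ravel(),
                     np.tile(np.clip(cols[:, None] + np.arange(-1, 2), 0, w - 1), (1, 3)).ravel()],
                    axis=1,
                ),
                axis=0,
            )
            if not occupied[grown[:, 0], grown[:, 1]].any() and not debris_canvas[grown[:, 0], grown[:, 1]].any():
                debris_canvas[rows, cols] = True
                break

    # disjoint truth masks: soma wins over strokes; nucleus carved out of soma
    intact_mask = intact_canvas & ~soma_canvas
    fragment_mask = fragment_canvas & ~soma_canvas
    soma_mask = soma_canvas & ~nucleus_canvas
    debris_mask = debris_canvas & ~soma_canvas & ~intact_mask & ~fragment_mask

    frag_area = int(fragment_mask.sum())
    intact_area = int(intact_mask.sum())
    true_f = frag_area / (frag_area + intact_area) if frag_area + intact_area else 0.0

    truth = GroundTruth(
        intact_mask=intact_mask,
        fragment_mask=fragment_mask,
        soma_mask=soma_mask,
        nucleus_mask=nucleus_canvas,
        debris_mask=debris_mask,
        true_f=true_f,
    )

    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    neurite_img = _render(
        truth.neurite_signal, spec.background_level, spec.signal_level,
        spec.noise_sd, noise_rng,
    )
    nuclei_img = _render(
        nucleus_canvas, spec.background_level, spec.signal_level,
        spec.noise_sd, noise_rng,
    )
    return neurite_img, nuclei_img, truth


def _render(signal_mask: np.ndarray, background: int, signal: int, noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    img = np.full(signal_mask.shape, float(background))
    img[signal_mask] = float(signal)
    img += rng.normal(0.0, noise_sd, size=signal_mask.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_from_truth(
    truth: GroundTruth,
    *,
    background_level: int,
    signal_level: int,
    noise_sd: float,
    seed: int,
    prominence_variation: float = 0.0,
    soma_signal_level: int | None = None,
) -> np.ndarray:
    """Re-render the neurite channel of a scene at arbitrary contrast.

    Exists for binarization-artifact studies: the same ground-truth
    geometry can be rendered at low contrast (mean signal only a couple of
    noise standard deviations above background) to show how thresholding
    breaks intact neurites into spurious fragments. No separation
    constraint is enforced here, by design.

    ``prominence_variation`` emulates the uneven optical prominence of
    structures in transmitted-light imaging: a smooth random field
    multiplies the signal-background contrast per pixel (clipped to
    [0, 2x]), so some neurite stretches are strongly rendered while others
    sink toward the background, exactly the "low prominence" stretches
    that vanish on binarization. 0 (default) renders uniform contrast, as
    in well-labeled fluorescence.

    ``soma_signal_level`` lets cell bodies render at a different (usually
    stronger) contrast than the thin processes, as optically dense somas do
    in transmitted-light images; it defaults to ``signal_level``.
    """
    rng = np.random.default_rng(seed)
    sig = truth.neurite_signal
    img = np.full(sig.shape, float(background_level))
    contrast = float(signal_level - background_level)
    if prominence_variation > 0.0:
        field = ndi.gaussian_filter(rng.normal(size=sig.shape), 10.0)
        sd = field.std()
        if sd > 0:
            field /= sd
        prom = np.clip(1.0 + prominence_variation * field, 0.0, 2.0)
        img[sig] += contrast * prom[sig]
    else:
        img[sig] += contrast
    if soma_signal_level is not None:
        img[truth.soma_footprint] = float(soma_signal_level)
    img += rng.normal(0.0, noise_sd, size=sig.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_series(
    out_dir: str | Path,
    f_levels: list[float],
    n_seeds: int,
    spec: SceneSpec = SceneSpec(),
    *,
    phase: bool = False,
) -> pd.DataFrame:
    """Write a batch-ready directory pair plus a ground-truth CSV.

    Creates ``<out_dir>/neurites/`` and ``<out_dir>/nuclei/`` with matching
    filenames (so sorted-order pairing aligns) and
    ``<out_dir>/ground_truth.csv`` with columns image, requested_f, true_f,
    soma_px. With ``phase=True`` the neurite images are rendered with dark
    signal on a bright background (simple intensity inversion); the nuclei
    channel stays fluorescent.
    """
    out_dir = Path(out_dir)
    neur_dir = out_dir / "neurites"
    nuc_dir = out_dir / "nuclei"
    neur_dir.mkdir(parents=True, exist_ok=True)
    nuc_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for li, f in enumerate(f_levels):
        if not (0.0 <= f <= 1.0):
            raise ConfigurationError(f"fragmentation level {f} outside [0, 1]")
        for si in range(n_seeds):
            scene_seed = (spec.seed * 1_000_003 + li * 10_007 + si) % (2**31)
            sub = replace(spec, fragmentation_fraction=f, seed=scene_seed)
            neurite_img, nuclei_img, truth = generate_scene(sub)
            if phase:
                neurite_img = (255 - neurite_img).astype(np.uint8)
            name = f"f{int(round(f * 100)):03d}_s{si:02d}.png"
            save_image(neur_dir / name, neurite_img)
            save_image(nuc_dir / name, nuclei_img)
            rows.append(
                {
                    "image": name,
                    "requested_f": f,
                    "true_f": truth.true_f,
                    "soma_px": int(truth.soma_footprint.sum()),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    return table
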