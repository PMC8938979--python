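# Methods

## The measurement model

Neurite degeneration proceeds by beading: a thin, elongated process breaks
into small, nearly round swellings. On a binarized micrograph this is a
shape statistic — the Degeneration Index is the area fraction of the
neurite signal contributed by connected components that are both small
(within a pixel-area window) and round (circularity `4πA/P² ≥ 0.2`),

```
DI = fragment_area / total_area ∈ [0, 1].
```

The statistic presumes (a) pixel units throughout — no physical
calibration is read or used, so the size windows are only meaningful at
the acquisition scale they were chosen for (1280 × 1024 at 20×, or any
format with a comparable pixels-per-neurite scale); (b) cell bodies have
been removed, since a soma is a large compact blob that would inflate the
denominator and, once fragmented nuclei appear, the numerator too; and
(c) debris below the fragment scale has been erased before any area is
summed, because the denominator counts *every* remaining foreground pixel.

An undefined DI (zero total area after cleaning) is reported as missing,
never as 0 or 1: a blank field is an acquisition failure, not a biology
reading, and coding it as an endpoint would bias group means.

## Pipeline order and parameters

Per image: contrast enhancement → soma-mask construction → subtraction
from the grayscale neurite image → binarization → small-particle removal →
particle analysis → DI. Total area is measured after particle removal and
after soma subtraction; the numerator's components are measured on exactly
the same mask.

Parameters that matter (all in pixels unless noted):

* **LUT window (90, 205)** — linear remap of that intensity window to
  0–255 for phase-contrast input; endpoints map exactly to 0 and 255 with
  round-half-up.
* **Autoscale saturation 0.35% per tail** — fluorescence contrast
  enhancement; percentile-based linear stretch.
* **Fragment filter** — (5–10,000, circ 0.2–1.0) fluorescence;
  (10–10,000) phase; (20–10,000) legacy. Bounds inclusive on both ends.
* **Remover max** — 4 (fluorescence) / 9 (phase): components of area
  1..max are erased. "0–N" windows include no area-0 components because
  none exist.
* **Soma removal** — `n_dilations` (default 12; 16 for sympathetic-scale
  somas) then `n_erosions` (default 2) with the full 3×3 square element.
  The dilation count sets the reach: a nucleus of radius r grows to cover
  a soma of radius up to r + (n_dilations − n_erosions) (and further on
  diagonals, since the square element grows in the Chebyshev metric). The
  trailing erosions realize a partial closing that fuses fragmented
  nuclei without giving up net expansion. The exact split between
  dilations and erosions is a design choice here: only the dilation count
  is exposed by the original tool's dialog, so the pair (12, 2) is our
  documented default, both values configurable.
* **nuclear_artifact_max 50** — nuclei at the supported scale are hundreds
  of pixels; 50 separates staining speckle from nuclei.

## Numerical conventions

* **Thresholding** is iterative intermeans on the 256-bin histogram:
  start at the image mean, iterate `t ← ⌊(mean≤t + mean>t)/2⌋` to a fixed
  point; ties (pixels equal to t) always fall in the dark class, so masks
  are bit-reproducible. Constant images raise; the binarizer catches this
  and returns an empty mask with a warning so batches continue.
* **Connectivity** is 8-connected everywhere — diagonal fragment chains
  must not split.
* **Perimeter** is the chain code of the outer boundary (Moore tracing):
  straight steps weigh 1, diagonal steps √2. Interior holes affect
  neither area (member-pixel count) nor perimeter. Circularity is capped
  at 1.0: discretization pushes the raw ratio above 1 for tiny particles,
  and the filter's upper bound must still admit near-circular blobs. A
  single-pixel component (chain length 0) reports circularity 1.0.
  Under nearest-neighbor upscaling, diagonal runs staircase and the chain
  length can grow up to √2 faster than the scale factor, so circularity
  is scale-stable only up to a factor-of-two bound for thin diagonal
  shapes; the test suite encodes exactly that bound.
* **ROI restriction** clips the mask to the half-open rectangle before
  labeling, so components straddling the border are re-measured inside
  it. This mirrors measuring fixed-size "analogous regions" and is the
  mechanism by which border clipping can itself create passing fragments;
  users comparing ROIs should keep the ROI placement fixed across
  conditions.
* **Batch determinism** — the pipeline is seed-free; identical inputs
  produce byte-identical CSV contents. Timestamps appear only in output
  filenames, and a re-run never overwrites or merges a previous run's
  files. Pairing of neurite/nuclei directories is by sorted filename
  index (a strict-name flag enforces matching stems); unequal counts
  refuse to start; a corrupt image is logged and skipped without aborting
  the batch.

## The synthetic scene generator

`generate_scene` renders what the pipeline consumes: smooth random-walk
neurites (length 300–450 px, stroke width 2–4 px) on a 1280 × 1024 (by
default) field; the distal fraction *f* of each curve is replaced by
elliptical beads (≈10–50 px, 3–8 px gaps) standing for the fragment class;
somas (disks, radius 20) sit at the proximal endpoints of the first
`n_somas` curves with concentric nuclei (radius 13) rendered only into the
nuclei channel; debris specks of 1–4 px are scattered clear of other
structures; everything is rendered at signal 200 over background 20 with
additive Gaussian noise (σ = 4) and clipped to 8 bits. Five pairwise
disjoint ground-truth masks are emitted; the realized fragmentation
fraction `true_f` is recomputed from the rendered masks so rasterization
and placement losses are measured, not assumed.

Deliberate design choices in the generator:

* Beads are only stamped where they touch nothing else (1 px clearance,
  6 px around somas), so each rendered fragment is its own component and
  `true_f` stays exactly recoverable; skipped beads simply lower
  `true_f`. Beads follow the original curve path, mimicking beading
  morphology rather than scattering random blobs, and `true_f` is
  area-based because DI is an area ratio.
* For partial fragmentation (0 < f < 1) the surviving intact remnant
  keeps ≥ 90 px of visible length: a shorter stub is genuinely compact
  enough to read as a fragment, which would make the ground truth itself
  ambiguous. The realized fraction is, again, measured into `true_f`.
* Curves steer smoothly away from frame borders and from foreign somas,
  so a neurite is severed only at its own origin; hard wall reflections
  would pile curves into compact tangles that misread as fragments.
* Structure counts and radii keep the nuclei channel within the operating
  regime of histogram thresholding: intermeans needs the bright class to
  carry enough mass to pull the threshold out of the background mode
  (roughly ≥ 1% of pixels at strong contrast). Scenes with very few or
  very small nuclei would binarize their own noise; that is a property of
  the thresholding method, not of this implementation.

What the generator does **not** emulate: point-spread blur, uneven
illumination, Poisson shot noise, out-of-focus debris, touching/beading
ambiguities of real degenerating arbors, or channel crosstalk. Passing the
ground-truth tests therefore shows the measurement machinery is correct
and internally consistent — not that DI on real micrographs is free of the
segmentation ambiguities those effects introduce.

The low-contrast experiment (`render_from_truth`) adds one optical effect
on purpose: a smooth multiplicative *prominence field* on the structure
(and optionally a stronger rendering for the optically dense somas), which
is how transmitted-light images actually fail — stretches of a neurite
sink toward the background and vanish at binarization, shattering intact
processes into spurious fragments, while a uniformly-labeled fluorescence
rendering of the same geometry binarizes cleanly. With mean neurite signal
only two noise standard deviations above background and no prominence
anchor, the intermeans threshold instead sits at the background mode and
the mask becomes percolating speckle — a regime we verified but do not use
as the demonstration, since it measures noise percolation rather than
neurite shattering.

## Validation protocols and problem sizes

The validation experiments (`neuridi.validation`) run on 640 × 512 fields
with 8 neurites/somas (16 for the contrast experiment) — a scaled-down
field that keeps every structure at native pixel scale while shrinking the
frame: (1) DI recovery over f ∈ {0, .25, .5, .75, 1} × 20 seeds; (2)
automated-vs-exact soma removal over 30 scenes of random fragmentation;
(3) low- vs high-contrast ROI DI over 20 intact scenes with a 150 × 150
soma-free window chosen where intact signal is densest.

## Known limitations

* Dense crossings of intact neurites can merge into a single component
  compact enough to pass the 0.2 circularity floor; this occasionally
  inflates DI by a few percent in crowded fields (real or synthetic). The
  same ambiguity affects the manual workflow this package automates.
* The soma mask grows in the Chebyshev metric, so it overshoots the
  Euclidean soma boundary on diagonals by a few pixels; neurite pixels in
  that ring are lost from the denominator.
* Histogram thresholding is global; strongly uneven illumination breaks
  it, and no shading correction is attempted (out of scope).
* Size windows are in pixels; images at other magnifications need
  rescaled windows, which is the user's responsibility.
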