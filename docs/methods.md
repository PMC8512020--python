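# Methods

This note documents the models, parameter choices and numerical decisions
behind `fundusedge`, and what the synthetic phantom suite does and does not
demonstrate about real fundus photographs.

## Detector model

The detector is the classical Canny chain (Gaussian smoothing, Sobel
gradients, non-maximum suppression, double thresholding, hysteresis)
modified for fundus photography: the working plane is the extracted green
channel, CLAHE runs before smoothing, and the final edge map is masked by
an eroded field-of-view mask so the bright circular rim between the retina
and the black camera surround never survives as an edge.

All stages are authored here rather than delegated to an image-processing
library's Canny, because the stage semantics are the point: each stage is
unit-tested against an independent oracle (hand convolution, a brute-force
non-maximum rule, a BFS connectivity oracle, an all-pairs distance oracle).
`scipy.ndimage` supplies only generic primitives — `correlate` for the
convolutions, binary morphology, connected-component labelling inside
hysteresis, and the Euclidean distance transform inside PFOM.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| low threshold | 30 | raw Sobel magnitude | weak/irrelevant split |
| high threshold | 105 | raw Sobel magnitude | strong/weak split |
| Gaussian size | 5 | px (odd) | smoothing support |
| Gaussian σ | 1.4 | px | smoothing scale (same in x and y) |
| CLAHE clip limit | 2.0 | — | histogram slope bound |
| CLAHE tile | 3 × kernel = 15 | px | contextual region side |
| background threshold | 10 | intensity | field-of-view mask split |
| mask erosion radius | 5 | px | rim clearance (square 11×11 element) |
| brush radius | 15 | px | default stroke capture region |
| PFOM α | 1/9 | per px² | displacement penalty |

Thresholds apply to **raw** (unnormalized) Sobel magnitudes, consistent
with 8-bit image-pipeline conventions; magnitude and angle are kept in
floating point, and only the smoothing stage re-quantizes to 8-bit.  The
CLAHE tile side tracks 3× the Gaussian kernel size because the tile must
stay large relative to the noise scale the Gaussian suppresses; the CLI
warns when the coupling is overridden.

The background threshold (strict `>` at 10) and the grayscale weights
(BT.601, 0.299/0.587/0.114, rounding half-up) are implementation defaults:
reasonable standard choices for 8-bit fundus imagery, not measured
constants.  PFOM's α = 1/9 is Pratt's classical value; published PFOM
figures are not comparable across unknown α, which is why the evaluation
layer exposes α explicitly.

### Numerical decisions

- **Convolution borders** are reflect-101 (`mirror`); the outermost 1-pixel
  frame is unconditionally suppressed after NMS, since border gradients are
  reflection artifacts.
- **NMS tie handling**: a pixel survives when its magnitude is ≥ both
  neighbours along the quantized normal.  Strict suppression of ties would
  delete plateau ridges entirely; keeping them preserves ridge connectivity
  and hysteresis then decides their fate.  Each orientation owns a ±22.5°
  sector modulo 180°.
- **Threshold comparisons** are strict: exactly-high is weak, exactly-low is
  irrelevant.
- **Hysteresis** is transitive 8-connected propagation from strong pixels
  (implemented by component labelling, pinned by a brute-force BFS oracle in
  the tests), not a single raster pass: a single pass is order-dependent and
  splits contiguous vessels.
- **CLAHE** redistributes the clipped excess uniformly in one pass (no
  iterative re-clipping) and blends tile mappings bilinearly between tile
  centres, clamping to the nearest tile beyond the outer centres.  The image
  is padded by reflection to a whole number of tiles.  A constant image maps
  to a constant image; with the clip limit disabled each tile's mapping is
  plain histogram equalization (both are test oracles).
- **Degenerate PFOM cases** (unspecified by the usual formula): two empty
  maps score 1, one empty map scores 0.  `nearest_distances` with an empty
  ideal returns an empty array and lets `pfom` handle the case.
- **Sweep caching**: thresholds enter the pipeline only after NMS, so
  `sweep_thresholds` computes the front of the pipeline once per
  preprocessing configuration and re-runs only the thresholding tail per
  (low, high) pair.  A test pins every table entry to a from-scratch
  `detect()` + `pfom()` run, so the caching is an optimisation, not a
  semantic change.  Ties in the argmax break to the lowest low, then the
  lowest high.
- **Ground-truth modes**: vessel ground truth usually comes as filled
  region masks; the sweep scores either against the mask itself (default)
  or against its morphological gradient (3×3 dilation minus erosion), a
  two-pixel band straddling the region boundary.

## Regional sessions

The interactive GUI loop (window, trackbars, mouse events) is replaced by a
scriptable `Session` with a text stroke-log format; the semantics are
identical and headless-testable, and the GUI's single-key vocabulary
(b/g/p/y colours, w erase, m/a modes) survives as the log grammar.  Brush
regions are unions of Euclidean discs swept along Bresenham segments
(default radius 15 px — the capture radius around the cursor is an
implementation choice).  Layers are independent binary maps confined to the
retina mask; the composite resolves overlaps latest-stroke-wins via an
owner map while the underlying layers stay independent.  Full-image
detection results are cached per parameter snapshot, so a stroke at an
already-seen toolbar setting costs one mask intersection.

## The phantom generator

A phantom emulates the gross structure of a fundus photograph: black
surround, bright circular disc (radius 80 px in a 192 px field — roughly
one third of DRIVE linear resolution), and dark curvilinear vessels drawn
as cubic-spline-smoothed random walks with bounded per-step curvature,
growing outward from near the disc centre, optionally with one thinner
branch.  Per-channel additive Gaussian noise (σ = 6) is clipped to 8 bits.

Default scene conditions: six vessels, widths 1–4 px, green-channel
contrasts 12–60 grey levels.  The thin-and-faint emphasis is deliberate:
real vessel trees are dominated by small vessels near the detection limit,
and that is the regime where channel choice, CLAHE and region-local
thresholds matter at all.  Colour composition concentrates structure in the
green channel (red bright and flat, blue low and flat), mirroring real
fundus photographs where vessels absorb green strongly while red is nearly
saturated.  An optional `red_texture_sigma` adds band-limited
choroidal-style texture to the red channel; it defaults to off — the
baseline keeps red flat — and is worth knowing about because PFOM's
max-normalization partially *rewards* extra clutter whenever N_A < N_I, so
enabling it raises grayscale-baseline scores for the wrong reason.

The two-vessel phantom used for region-local threshold experiments fixes
contrasts at 80 and 20 (a 4:1 ratio): the faint vessel's gradient response
overlaps the noise floor, so global thresholds permissive enough to trace
it flood the rest of the disc, while the prominent vessel is clean at high
thresholds.  Contrasts much above ~100 would push vessel pixels toward the
background threshold, where noise makes the field-of-view mask erode them
away — an artifact of the phantom's black-level geometry that real fundus
images do not exhibit.

### What phantom results do and do not show

Phantoms have piecewise-constant intensity, isotropic Gaussian noise, no
optic disc, fovea, lesions, illumination gradients or interlacing
artifacts.  Passing the property suite therefore demonstrates the
*algorithmic* claims — stage correctness, threshold monotonicity, the
existence and direction of the regional-thresholds and preprocessing
benefits — under controlled conditions, not absolute performance on DRIVE /
STARE / CHASE_DB1.  Published per-image PFOM tables additionally depend on
an unstated α, so absolute scores are not reproducible from the method
description alone; the sweep machinery reproduces the protocol (run the
detector over a threshold grid, report the argmax "ideal" pair and score),
and `fundusedge evaluate` runs it end-to-end on real data when images and
ground truth are supplied.

A note on score magnitudes: scored against a two-pixel boundary band, a
perfectly localized one-pixel-per-side edge map has N_A ≈ N_I/2, capping
PFOM near 0.5 through the max-normalization alone.  The detector smoke
floor (≥ 0.5 on a clean thin-vessel phantom) and the phantom sweep scores
around 0.4–0.6 must be read against that ceiling, not against 1.0.

## Problem sizes

Tests and the acceptance script run on 64–192 px phantoms with threshold
grids of 20–30 pairs — sizes chosen so the full suite completes in a few
seconds while keeping every vessel several smoothing kernels wide of the
disc rim.  All randomness flows from explicit integer seeds; every test and
script run is bit-reproducible.
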