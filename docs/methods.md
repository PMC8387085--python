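# Methods

## Scope and model

`canaliq` measures bile-canalicular morphology in 2-D from single
brightfield RGB photomicrographs of DAB-immunostained liver sections.
The underlying model is deliberately simple and fully transparent:

* **Imaging model.** Brightfield absorption follows Beer–Lambert:
  per-channel optical density `OD_c = -log10(I_c / 255)` is a linear
  mix of stain contributions, `OD = C · M`, where the rows of `M` are
  unit OD vectors for hematoxylin, DAB, and an orthogonal residual
  (Ruifrok–Johnston values, overridable). Unmixing is the matrix
  inverse; no per-slide vector estimation is attempted.
* **Positivity model.** A pixel is IHC-positive when (a) its total
  positive stain concentration exceeds a background floor
  (default 0.05 OD) and (b) the DAB share of that total is at least a
  cutoff (default 0.5). Positive pixels are re-rendered from their DAB
  component alone; all others become pure white. The subsequent 8-bit
  image therefore carries *only* DAB absorbance, which is what makes
  the uncalibrated absorbance surrogate `cMGV = 255 − MGV` meaningful
  without further background normalization.
* **Object model.** One canaliculus = one 8-connected component of
  the thresholded mask. Components under `min_pixels` (default 10) are
  treated as staining artefacts. Border-touching components are kept
  (an `exclude_border` flag exists for sensitivity analysis).

## Shape parameters and numerical choices

* **Feret diameter** is the arithmetic mean of the object's
  projections onto the image x and y axes, `F = (X + Y)/2` — the
  construction that defines the branching index here — not the
  conventional rotational max-caliper Feret (available via
  `feret_mode="caliper"`). The projection definition is
  orientation-dependent (a 45°-rotated square changes `F` by √2); this
  is an inherent property of the measure, documented rather than
  "fixed", and it is invariant under 90° rotations.
* **Perimeter** uses the 8-connected boundary chain through pixel
  centres with the Vossepoel–Smeulders corner-corrected weights
  (0.980 per straight step, 1.406 per diagonal step, −0.091 per
  direction change) plus a constant 4 px for the half-pixel band
  between pixel centres and the physical outline. Calibration anchors:
  a digitized disk (r = 40 px) gives `P/F` within 0.3% of π, filled
  squares give 3.85–3.91 against the ideal 4. Raw 1/√2 chain counting
  would overshoot disks by ≈ 5%; crack-edge counting by ≈ 27%. Only
  the outer boundary is traced (interior holes, which essentially do
  not occur in thin tubular masks, do not add perimeter).
* **P/F as a branching index.** A side branch adds roughly twice its
  length to `P` while moving `X`/`Y` at most by its extent in one
  direction, so `P/F` grows with branching at fixed overall extent.
  Note that the comparison shape matters: any *filled* rectilinear
  plus-shape has exactly the perimeter of its bounding box (rectilinear
  convexity), so the index separates branched from unbranched *thin*
  structures, not from arbitrary filled ones. Tests therefore exercise
  comb-vs-rectangle and tube-with-branches vs tube-without.
* **Solidity** divides the pixel count by the area of the convex hull
  of all pixel *corner* points, so axis-aligned rectangles score
  exactly 1 and every concavity strictly lowers the value.
* **MGV/cMGV** are computed on the extracted 8-bit DAB channel (not on
  a grayscale of the original RGB), per the positivity model above.
* **8-bit conversion** is the unweighted channel mean (the ImageJ
  default), with ITU-R 601 luma weights as an option.
* **Thresholding** is an explicit 8-bit cut recorded in every output.
  Default 200: extraction has already forced background to white, so
  any generous cut keeps exactly the reconstructed-DAB pixels. `auto`
  runs Otsu on the sub-255 pixels only, which is the right tool when a
  weak-halo population should be split from strong staining — but note
  that on a *unimodal* foreground it must bisect that mode (any
  variance-maximizing split of one population does), which is why it
  is not the default.

## Local thickness

Thickness at a foreground pixel is the diameter of the largest disk
containing the pixel and lying inside the structure
(Hildebrand–Rüegsegger, 2-D). Implementation: Euclidean distance
transform → candidate radius per pixel → disk painting, all
comparisons on integer squared distances, so the fast path agrees
*exactly* with a brute-force pairwise oracle (verified on 100 random
64×64 masks per run). Conventions: outside the field counts as
background (one-pixel background pad); disk membership is by pixel
centre; reported diameter is `2r − 1` px so a bar of odd width w
measures exactly w along its core (even widths read 1 px low — the
half-pixel ambiguity is unavoidable on a centre-sampled grid).
The field mean is taken over the full unfiltered mask ("whole image");
a flag computes the artefact-filtered variant instead.

## Statistics

Default unit of analysis is the patient (mean of that patient's
fields; empty fields excluded with a warning), because group sizes in
this design are counted in biopsies. Field- and ROI-level units are
available but correlated observations within a patient then violate
the t-test's independence assumption — flagged, not corrected (no
mixed models by design). Descriptives are mean ± sample SD (n−1);
the test is the two-sided pooled-variance Student's t-test (Welch via
flag), no multiple-testing correction by default (Holm available).
Degenerate separation (zero within-group variance, different means)
reports the smallest positive float as p with a warning rather than
p = 0. Type-I calibration at n = 5 vs 7 over 2000 null replicates
lands at ≈ 0.045–0.05 at α = 0.05.

## Synthetic generator

Each synthetic canaliculus is a random-walk axis (3 px steps, Gaussian
turn angles, default spread 25°) with side branches sprouting at
uniformly random positions at 30–90° to the local direction, one third
of the main length, dilated to the tube width. Rendering inverts the
exact extraction basis: DAB OD (default 0.8) on tube pixels,
low-frequency hematoxylin texture (OD 0.25 ± 40%) everywhere, Gaussian
sensor noise (default σ = 3 gray levels), quantized to 8 bits.
Defaults: 256×256 px at 0.1 µm/px, 4 canaliculi, 2 branches,
width 5 ± 1 px (≈ 0.5 µm calibre).

What it emulates: DAB-dominant tubular branching structures over a
counterstained background, with controllable geometry, stain strength,
and noise, plus exact per-structure ground truth. What it does not:
hepatocyte texture, uneven illumination, stain co-localization halos,
section artefacts, or slide-to-slide stain variation. Passing the
recovery tests therefore demonstrates correctness of the measurement
chain under the stated imaging model — not robustness to every failure
mode of real slides (no cross-slide color normalization is included,
by design).

On 8-bit data, extraction is idempotent up to quantization (the
white/DAB classification is stable; reconstructed values can move by
one gray level). On float data it is exactly idempotent, and the
forward-render → extract round-trip recovers per-pixel DAB OD to
< 1e-6 for DAB-dominant pixels.

## Problem sizes

Verification runs use sizes chosen to make every check exact or
statistically stable while remaining quick: 100 random 64×64 masks for
the thickness oracle, 50 seeded replicates per arm for the branching
Monte-Carlo (192×192 fields, single canaliculus, width 5 px, extent
80 px), 5 fields at σ = 5 for mask precision/recall, 2000 replicates
for t-test calibration, and a 2×2-sample × 3-field study at 128×128
for the byte-determinism check.

## Known limitations

* Single 2-D sections; no stereological correction to 3-D network
  properties.
* The projection Feret's orientation dependence (above).
* Stain vectors are fixed, not estimated per slide; strong scanner or
  protocol shifts require passing custom vectors.
* Thickness on even-width structures reads one pixel low.
* The branching index is a proxy; it does not count branch points
  (no skeletonization by design).
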