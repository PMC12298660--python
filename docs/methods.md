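# Methods

This note documents the models, conventions and free parameters behind
`marblesense`, and what its synthetic experiments do and do not show.

## Pipeline model

An input image is processed at a fixed working resolution of 960 × 720 px
(other sizes are bilinearly resized on ingest). Analysis is confined to a
centred elliptical region of interest (ROI) spanning a configurable
fraction of each image dimension; the default *medium* mask (75 %) has
semi-axes 360 × 270 px, with *small* (60 %) and *large* (90 %) variants for
sensitivity studies. The ROI is tiled by square blocks anchored at the
image origin; a block is retained only if every one of its pixels lies
inside the ellipse. Retained blocks are the units of feature extraction
and classification; block predictions are aggregated to an image verdict
by plurality vote with a conservative tie-break (fat-injected > regular >
Wagyu), so an ambiguous image is flagged rather than excused.

### Geometry conventions

Results such as "36 valid blocks at 80 × 80 px, 55 at 64 × 64 px" depend on
rasterization conventions, which are therefore fixed:

* coordinates are 0-based, x rightward, y downward; block windows are
  half-open `[x, x+s) × [y, y+s)`;
* a pixel is inside the ellipse iff its centre `(x+0.5, y+0.5)` satisfies
  the ellipse inequality with inclusive boundary;
* the block grid is anchored at (0, 0) and residual margins are discarded
  (at 64 px, 720 − 11·64 = 16 rows are dropped).

Because the ellipse is convex, a block is fully inside iff its four corner
pixel centres are inside; the test suite verifies this shortcut against a
per-pixel brute force for every block size used (64–84 px in steps of 4).

## Features

### Uniform LBP texture

Each block is converted to grayscale
(`round(0.299 R + 0.587 G + 0.114 B)`) and described by a local binary
pattern histogram. For sampling geometry (P, R), bit *k* of a pixel's code
is set iff the neighbour at angle 2πk/P and radius R is ≥ the centre value;
bit *k* carries weight 2ᵏ. Codes whose circular bit string has at most two
0↔1 transitions are *uniform* — P(P−1)+2 of them (58 for P = 8) — and are
mapped, in ascending code order, to their own bins; all remaining codes
share one pooled bin, giving 59 bins for P = 8 (243 for P = 16).

Numerical conventions:

* **Radius-1 sampling uses the 3 × 3 integer neighbourhood** (offsets are
  the rounded circle points), the classic square-neighbourhood form of the
  operator; sampling is then exact and needs no interpolation. For R = 2
  the true circle points are used with bilinear interpolation (points that
  fall on the grid, e.g. (±R, 0), are snapped and sampled exactly).
* **No padding**: codes are computed only at the (s − 2R)² interior pixels
  of an s × s block, and the histogram is normalized by that count so it
  sums to 1 exactly. Padding alternatives would fabricate intensities at
  block borders.
* The bit-ordering/orientation choice is a pure relabelling: opposite
  orderings permute histogram bins identically for all blocks and leave
  classification unchanged.

The default configuration is LBP(8, 1), the operating point used by the
default pipeline.

### Colour statistics

Per block and per colour space, the population mean and standard deviation
of each channel (six values). All channels are expressed on a 0–255 scale:
RGB natively; HSV via the hexcone model with H (0–360°), S and V (0–100 %)
rescaled linearly; L\*a\*b\* under the D65 white point and sRGB
linearization with L\* scaled by 255/100 and a\*, b\* shifted by +128 and
clipped. Population (divide-by-N) standard deviations are used; with ≥ 4096
pixels per block the sample/population distinction is far below feature
noise, but a single convention keeps tests bit-stable. The original
conversion software's exact white point is unknown; D65/sRGB is this
package's choice and no fidelity to other defaults is claimed.

### Assembly and scaling

A block's feature vector is `[59 LBP bins | 6 stats per colour space]`,
with colour spaces in the fixed order RGB, HSV, LAB — 65 dimensions for
the default LBP+RGB combination, 71 and 77 for the larger combinations.
Features are min–max scaled to [0, 1] with bounds learned **on the
training split only** and frozen for validation/test (no leakage);
out-of-range test values are clipped and constant training dimensions map
to 0 (any constant is uninformative, and this avoids division by zero).

## Classifier

A three-class RBF-kernel SVM, K(xᵢ, xⱼ) = exp(−γ‖xᵢ − xⱼ‖²), realized as
one-vs-one pairwise machines (scikit-learn's SVC provides the dual solver).
Class prediction takes the most pairwise votes; vote ties use the same
conservative priority as image voting. Defaults C = 64, γ = 1; a grid
search over C ∈ {16, 32, 64, 128, 256} × γ ∈ {0.25, 0.5, 1, 2, 4} (the
full dyadic range 2⁻⁸…2⁸ is available) scores validation block CR and
breaks ties toward smaller C, then smaller γ — preferring the smoothest
model among equals. Training uses a fixed tolerance of 1e−3 and a fixed
input ordering, making fits reproducible; class weighting is uniform since
all experimental designs here are class-balanced.

## Metrics

With fat-injected as the positive class:

* **α (misjudgment rate)** — truly non-injected items predicted injected ÷
  all truly non-injected items (Type I error). The denominator never
  includes injected items.
* **recall / detection rate (1 − β)** — detected injected ÷ truly injected.
* **precision** — correct injected calls ÷ all injected calls.
* **CR** — three-class accuracy = trace of the 3 × 3 confusion matrix over
  its total.
* **F1** — harmonic mean of recall and precision, one-vs-rest for the
  injected class only.

All are computed identically at block level and at image level (after
voting). A zero denominator yields NaN plus a `RuntimeWarning` — never a
silent 0 or 100, which would corrupt parameter sweeps. Outputs round to
two decimals; full precision is kept internally.

## Synthetic data generator

The generator emulates the three phenotypes on red lean backgrounds:

| parameter | Wagyu | regular | fat-injected |
|---|---|---|---|
| lean colour mean (R,G,B) | (178, 72, 66) | (160, 70, 64) | (132, 50, 52) |
| fat fraction of ROI | 0.26–0.38 | 0.02–0.07 | 0.22–0.34 |
| fleck/streak count | 150–260 | 8–25 | 16–32 |
| elongation (major/minor) | 1–2.5 | 1–3 | 6–12 |
| connectivity | scattered | scattered | chained (4 segments) |
| orientation jitter | ±90° (isotropic) | ±90° | ±14° about a dominant axis |
| per-fleck area jitter (lognormal σ) | 0.6 | 0.5 | 0.2 |

Lean is rendered as spatially correlated Gaussian colour noise; fat as
anti-aliased near-white ((≈230, 222, 218) ± noise) rotated ellipses —
single flecks for scattered classes, end-to-end chains of four elongated
segments along a jittered dominant orientation for the injected class
(yielding interconnected, directional streaks and far fewer connected
components than Wagyu). Flecks are added until the rendered ROI fat
fraction reaches a target drawn from the class range; layouts that cannot
reach their target raise a `GenerationError`. The binary mask actually
rasterized is returned as ground truth. These parameter values are free
choices of this package satisfying the documented qualitative contrasts
(many-small-scattered vs few-long-connected, darker injected lean); no
quantitative phenotype measurements of real beef were available to fit.

**Perturbations.** The brightness ladder targets ROI gray means
μ + 1.5 k σ for k ∈ {−3…3} with defaults μ = 98.91 and
1.5 σ = 25.97 gray levels (so k = +3 is 176.82); adjustment is a
multiplicative gain iterated a few times to compensate clipping, reaching
the target within ±1 gray level when saturation permits. Labels are
opaque white rounded rectangles with dark text-like strokes covering a
prescribed ROI fraction, placed fully inside the ellipse; reflections are
soft Gaussian near-white blobs. Tilt applies the homography K·R·K⁻¹ of a
camera rotated about an image-plane axis, with nominal focal length
f = 0.9 × image width, resampled bilinearly to the working frame; a 0°
tilt is an exact identity.

**What passing tests show — and don't.** The synthetic classes are
separable by construction (distinct lean colour means plus distinct fat
texture), so near-perfect classification on clean synthetic data verifies
the pipeline's correctness, not real-world accuracy; real beef varies in
illumination, cut surface, wetness and camera processing in ways the
generator does not model (no photorealistic rendering, no attempt to match
real channel histograms quantitatively). Robustness sweeps should be read
the same way: the *trends* (performance non-increasing with tilt angle,
extreme brightness worse than normal) are the claim, not the absolute
rates. In particular, even small tilts degrade the synthetic benchmark
noticeably because the model is trained exclusively on untilted images and
the warp shifts block contents across the fixed grid.

## Experiment sizes

The large-sample protocol uses 200 images per class split 120/40/40 into
train/validation/test — 600 images and 21,600 grid blocks at 80 × 80 —
with robustness sweeps on a 60-image test subset (20 per class) under
small (3°) and large (12°) tilt and the darkest/brightest ladder rungs
(k = ±3). The worked README example uses the smaller 40/20/20-per-class
design. Both run in minutes on one CPU.

## Known limitations

* Synthetic-only validation: no claim of accuracy on real beef images.
* The elliptical ROI is fixed and centred; no meat/background segmentation.
* LBP variants (rotation-invariant riu2, multi-scale fusion) and
  probability calibration are out of scope.
* Image-level concatenated LBP features (55 × 59 per image) are exposed
  only as an export; classification is strictly per-block.
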