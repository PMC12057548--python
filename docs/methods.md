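# Methods

## Image model and pipeline

A crumb photograph is modeled as an 8-bit grayscale raster with a physical
scale in mm/pixel. The default scale is 0.045 mm/px: a 30 mm × 30 mm field
of view at ~667 px across, the resolution at which a single pixel covers
0.002 mm² — the smallest cell area the grain table reports. The analysis
chain is

    histogram → global threshold → binarize (pores = dark class)
    → 3×3 binary median despeckle (one pass)
    → 8-connected component labeling → per-cell measurement
    → min-area filter (default 0.002 mm²) → summary + fractal descriptors

Each stage is exposed separately; `run_pipeline` batches the chain over
images and methods and never aborts on a per-image failure (a blank image,
for instance, records a `NoSeparation` error in its row).

## Thresholding criteria

All five criteria operate on the 256-bin histogram only. Conventions that
the criteria themselves leave open are fixed as follows:

* the below class is `g ≤ T`; a valid `T` always lies in
  `[lowest occupied bin, highest occupied bin)`, so both classes are
  non-empty;
* ties in any objective break toward the lowest qualifying `T`
  (determinism);
* entropies use natural logarithms — any fixed base gives the same argmax;
* Huang's fuzzy-membership constant `C` is the occupied intensity range, so
  padding empty bins cannot change the result;
* IsoData starts from the rounded global mean and iterates
  `T ← round((μ_below + μ_above)/2)` to a fixed point, clamped to the valid
  range;
* Intermodes smooths with a 3-point running mean (edges replicated) until
  exactly two local maxima remain (plateaus count once, at their left
  edge), up to 10,000 passes before raising `NotBimodal`. A histogram with
  exactly two occupied levels is treated as already bimodal — its occupied
  levels are the modes — since smoothing can never separate adjacent
  spikes;
* Kapur candidates that leave either class with zero probability are
  skipped.

These are implementations of the five classical criteria from their
original formulations; Otsu is additionally pinned to an independent
brute-force variance-maximization oracle in the tests.

## Particle analysis

Despeckling is a single pass of the 3×3 binary median with replicate
padding — the standard despeckle convention; it removes isolated pixels and
clusters smaller than ~5 px while preserving solid regions. Connectivity is
8 by default (diagonal contact joins pores); 4-connectivity is available
via a flag, and a dedicated test guards the convention. Border-touching
particles are retained: real crumb fields contain pores far larger than
could avoid the crop border.

**Perimeter.** The perimeter of a particle is the length of its crack
boundary — the pixel edges exposed to background — which is exact for
axis-aligned rectangles (a 4×4 px square at 1 mm/px has perimeter 16 mm; an
L-tromino 8 mm; digital squares satisfy `P² = 16A` exactly). At junctions
where two pixels of the same particle touch only diagonally, the four unit
cracks meeting at the shared corner are replaced by two √2 diagonal
segments, giving 8-connected particles a single well-defined boundary
length. The estimator is deterministic and positive for every non-empty
particle.

## Fractal descriptors

`DFp = 2·log₁₀(P/4)/log₁₀(A)` with `P` in mm and `A` in mm². The formula is
not unit-invariant, so the millimetre convention is frozen. Any square of
side ≠ 1 mm gives exactly 1. Cells with `|log₁₀ A| < 10⁻⁶` sit on the
singularity at `A = 1 mm²` and are reported as undefined and excluded from
means. A known limitation follows: cells with areas *near* (but not at)
1 mm² produce arbitrarily large `|DFp|`, so the mean DFp of a population
whose sizes straddle 1 mm² is dominated by the near-unit cells. This is a
property of the perimeter–area form itself, not of the estimator.

`DFt` is the least-squares slope of `log₁₀ N` against `log₁₀(1/r)` over
multiple scales, with the two-point ratio recoverable as a special case.
Two variants are provided because the defining ratio does not fix one:
`size_distribution` (default) counts cells with area ≥ r over the grid of
observed cell areas; `box_counting` counts occupied boxes at dyadic box
edges (in mm). Box counting gives exactly 2 for a full filled field,
1.9–2.0 for filled rectangles and ~1 for one-pixel lines. Fewer than two
usable scales (e.g. all cells the same size) raises `InsufficientScales`.

## Synthetic crumb images

The generator emulates what the thresholding chain actually faces: a
bimodal gray-level distribution with dark pores (default mean 80) in a
bright matrix (default 170, i.e. 90 gray levels of contrast), i.i.d.
Gaussian gray noise (default σ = 10; the validation studies use σ = 5),
optional Gaussian blur and salt-and-pepper speckle. Pores are rasterized
disks (center-in-circle test) with lognormal radii, median 0.45 mm
(σ_log = 0.4), 400 disks per 30 mm field — chosen so total pore area is
~260–300 mm² of the 900 mm² field and per-image cell counts are a few
hundred, the regime reported for starch-based gluten-free cakes.
Overlapping disks merge; ground truth counts 8-connected components of the
final mask, i.e. what particle analysis could at best observe.

Two resolution rules keep the ground truth observable: radii are floored at
3 px (a smaller pore is below the imaging resolution, and a 3×3 median
erases 2-px disks outright), and a disk that would leave a wall thinner
than 3 px to an earlier pore is redrawn — sub-pixel walls cannot be
represented in the raster and would otherwise be bridged by the despeckle,
silently merging pores the ground truth counts as separate. Within these
rules the mask is captured *before* any noise, and identical seeds give
bit-identical output.

What the generator does **not** emulate: irregular (non-disk) pore shapes,
anisotropy, illumination gradients, JPEG artifacts, and the partial-volume
gray levels of real pore walls. Recovery results on synthetic images
therefore demonstrate correctness of the chain, not field performance on
real photographs.

**Observed behavior of the five criteria on clean synthetic images**
(contrast 90, σ = 5, no blur/speckle): Huang, IsoData, Otsu and Intermodes
place `T` in the empty gap between the modes; the binarized mask is then
bit-identical to the ground truth and recovery is exact. Kapur's
maximum-entropy criterion instead places `T` about 2σ inside the matrix
mode — splitting the dominant mode raises the entropy sum regardless of σ —
so ~3–4% of matrix pixels fall below `T`; the despeckle removes nearly all
of them, but a few-per-image survive as 1–3 px specks above the 0.002 mm²
cutoff, leaving MaxEntropy's count high by a small margin (~2%) where the
other four are exact. Under heavy degradation (blur σ = 2 px + 5%
salt-and-pepper, the stress condition used in validation), the
Huang/IsoData/Otsu family retains markedly higher count and area recovery
than MaxEntropy/Intermodes.

## Synthetic digestion profiles

Glucose release follows first-order kinetics,
`G(t) = FG + C∞·(1 − e^(−kt))`, sampled on a 30-min grid to 180 min plus
the 20- and 120-min Englyst draws. Defaults (FG = 0.65, C∞ = 55 g/100 g,
k = 0.07 min⁻¹) give fractions in the range reported for starch-based
gluten-free cakes (RAG ≈ 42, SDS ≈ 9–12 g/100 g). Measurement noise is
additive Gaussian, then clipped to `[FG, TG]` and made monotone by a
running maximum (glucose release cannot reverse). The ground-truth
fractions returned alongside are computed from the noise-free curve by the
same formulas the analysis applies, so the noise-free round trip is an
exact identity.

## Quality calculators

* `TS = (TG − FG)·0.9`: the total-starch expression is parenthesized per
  the Englyst convention. Profiles are validated against
  `0 ≤ FG ≤ G20 ≤ G120 ≤ TG`, and the violated inequality is named in the
  error. Published fraction tables can be screened with
  `implied_free_glucose(RAG, RDS) = RAG − RDS/0.9`: a negative value flags
  an internally inconsistent row (the bundled potato row is one such case;
  the validator flags it rather than silencing it).
* `HI` integrates both curves trapezoidally over the same 0–180 min
  interval; the reference curve is always caller-supplied — no reference
  food is silently assumed.
* The browning index uses the coefficients (1.79, 0.31, 0.17); the common
  literature variant (1.75, 0.31, 0.172) is selectable through keyword
  arguments. Bundled BI values recompute to within ~0.2 of the published
  ones from their 1-dp CIELAB inputs.
* ΔE is plain Euclidean distance in CIELAB; when processing a multi-sample
  table the rice-starch sample is the conventional reference.
* Reported values are never rounded internally; display rounding (2 dp for
  ΔE and rates, 1 dp for percentages) is applied only at the reporting
  edge.

## Problem sizes and determinism

Validation runs use 667×667 px images (the full 30 mm field), three seeds
per condition, 100 random histograms for the Otsu oracle and 1,000 random
profiles for the fraction identity; the whole suite completes in a few
seconds. All synthetic data is generated from explicit integer seeds;
equal seeds give bit-identical images, masks and profiles.
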