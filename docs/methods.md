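# Methods

## Model and scope

The framework assumes degradation by convolution with a Gaussian kernel.
Under that assumption blur equalization is exactly invariant up to two
discretization errors: the stop threshold Θ is overshot by at most one step
kernel, and the image grid itself is discrete.  Averaging and median filters
violate the assumption; the harness therefore evaluates them separately, and
the tests only require that equalization still *helps* there, not that it is
invariant.  The pipeline only ever adds blur — there is no deconvolution or
sharpening path, so a target below an image's current blur level leaves the
image unchanged.

Intensities are real-valued on the 0–255 scale throughout; quantization to
8 bits happens only when writing files.  Repeated rounding between
equalization iterations would otherwise break the Gaussian semigroup
property that the whole construction relies on.

## Numerical conventions

* **Padding.** All convolutions, median filters and derivative operators use
  symmetric (mirror) boundary padding.  Constant padding would create a dark
  frame that the edge-based blur measures would read as strong sharp edges.
* **Kernel truncation.** Simulated Gaussian blur uses a side length of
  2·ceil(3σ)+1, renormalized (< 0.3 % truncated mass).  The equalization
  step kernel is the 3×3, σ = 1 truncation; its effective per-step variance
  is ≈ 0.46, so an equalization run of n steps corresponds to an added blur
  of roughly σ ≈ √(0.46·n).
* **Quantiles.** Decile thresholds use the inclusive linear-interpolation
  convention (numpy's default), fixed so thresholds reproduce bit-for-bit.
* **Tie rules.** LBP sets a bit when neighbor ≥ center; LPQ sets a bit when
  a coefficient component ≥ 0.  Both choices make constant images
  well-defined fixed points.  LBP bilinear interpolation is evaluated in
  incremental form (a + t·(b − a)) and the LPQ/ECM kernels are mean-removed,
  so constant inputs and global gray-level shifts behave exactly in floating
  point.
* **Blur-measure orientation.** All measures are oriented so larger =
  blurrier, keeping the stop test B(I) ≥ Θ literal.  Contrast shrinks with
  blur, so `measure_contrast` returns the *negated* mean squared neighbor
  difference and its thresholds live in the negated space.  The contrast is
  normalized by the neighbor-pair count so datasets with mixed image sizes
  compare on one scale.
* **Degenerate inputs.** A constant (or edge-free) image has no defined edge
  width or relative variation; the measures raise `DegenerateImageError`
  with a flag noting the image may be treated as maximally blurred.  Batch
  APIs collect such failures instead of dropping images and report tallies;
  equalization caps at `max_iter = 64` (non-convergence is flagged, not
  fatal, since a near-constant image can never reach a high Θ).

## Interpretation choices in the descriptors and measures

Several building blocks are under-determined by their usual one-line
descriptions; the choices here are explicit and testable:

* **Edge detection for the edge-width measure**: horizontal Sobel derivative;
  edge pixels are those above 10 % of the image's maximum response (a
  sharpness-independent relative cutoff).  The per-row extremum search walks
  to the nearest strict local extremum; plateaus collapse to the endpoint
  closest to the edge pixel.
* **Low-pass for the variation-comparison measure**: a 3×3 averaging filter;
  horizontal and vertical directions are scored separately and combined by
  the maximum.  Directions with zero original variation are skipped.
* **ELBP**: uniform LBP (radius 1) computed on the Sobel gradient-magnitude
  image.
* **MFS**: density measures are local intensity sum, gradient-magnitude sum
  and |Laplacian| sum over discs of radii 1–4; the log–log slope is taken
  against *effective* radii √(area/π) of the discrete discs, which removes
  the small-radius bias (a constant image gets dimension exactly 2 under the
  intensity measure).  Dimensions are histogrammed into 26 bins over [0, 4].
* **ECM**: eight first-derivative-of-Gaussian filters (σ = 1) at kπ/8;
  "maximum response" is read as the global maximum magnitude over the image;
  displacement (1, 1) in (row, col).
* **LPQ**: window 15, frequencies {(a,0),(0,a),(a,a),(a,−a)} with a = 1/15,
  separable correlation, no decorrelation/whitening stage — the histogram is
  built directly from the sign codes.
* **LBP** is implemented in-package (vectorized bilinear sampling) rather
  than through an external library so the sampling geometry, tie rule and
  uniform-bin ordering are pinned down and verified against a per-pixel
  brute-force oracle in the tests.

## Synthetic benchmark

The generator emulates the structure of a single-scale texture benchmark:
K classes × N patches, one directory per class, a clean training database
"A" and an independently drawn evaluation database "B" that alone receives
simulated degradations.  Each class is white noise shaped in the Fourier
domain by a Gabor-like envelope (class orientation and center frequency,
optional second harmonic) plus a 6 % broadband noise floor, normalized to
mean 127 and std 40 × class contrast, clipped to [0, 255].  Patches are
drawn from independent child generators keyed by (seed, class, index), so
datasets are bit-reproducible and patch order is irrelevant.

The default recipe (8 classes, orientations kπ/8, frequencies 0.04–0.32
cycles/pixel, contrasts 0.19–1.4) deliberately spans smooth, low-contrast
surfaces through coarse, high-contrast ones, the way physical texture
collections mix out-of-focus-looking fabrics with sharp granular materials.
That spread matters: the decile thresholds are taken over *sharp* images, so
the equalization mechanism only has dynamic range if intrinsically
"blurry-looking" classes anchor the upper deciles.  The generator was
accepted against its fitness contract — a linear classifier on MRLBP
features must reach ≥ 0.9 on a clean half/half split — before the default
recipe and seed (7) were frozen; the test suite runs entirely on that frozen
configuration.

What the generator does **not** emulate: natural-texture phase structure
(its classes are Gaussian random fields), illumination or scale variation,
sensor noise correlated with intensity, and the 28-class breadth of a full
benchmark.  Passing tests therefore demonstrate the mechanics and the
qualitative trade-offs of equalization, not accuracy levels transferable to
any particular real collection — at this desk scale the clean 8-class
problem is easy (baselines saturate at 1.0), which compresses some effects
the full-scale experiments show more gradually.

## Experimental protocol

Degradations are applied to the evaluation set only.  Thresholds are the
deciles of the blur scores of the *undegraded* evaluation set (reproduction
mode); a switch derives them from the training set instead for deployments
where clean evaluation images do not exist.  For each grid cell, training
and degraded evaluation sets are both equalized at Θ, features are
standardized by training-set mean/scale, and a linear SVM (C = 1,
one-vs-rest, fixed seed) is fitted; baseline cells skip equalization.
Blur-prediction error tables compare ordered pairs (X at σ, Y at σ + 0.5)
within or across classes; pairs are exhaustive up to 10⁴ per base level,
subsampled with a seeded generator above that, and score ties count half —
a constant scorer scores exactly the 0.5 guessing anchor.  Non-converged or
degenerate images are never dropped; they pass through unmodified and are
tallied per cell.

Problem sizes in the test suite and acceptance script (8 × 20 + 20 patches
of 128², two-level Gaussian grids, four non-Gaussian levels) are the
package's desk-scale defaults, chosen to keep a full run in minutes while
preserving the train-A/eval-B structure.

## Known limitations

* Equalization can only match blur levels it can *reach*: if Θ is below the
  score of a strongly degraded image, that image passes through unequalized
  and invariance degrades — visible in the grid as lower accuracy at small
  Θ indices.
* The measures estimate perceptual blur, not the Gaussian σ; the
  `ideal_equalize` oracle (true-σ equalization via the semigroup) bounds
  what a perfect measure could achieve, and is only available on synthetic
  data where σ is known by construction.
* Median filtering is not a convolution; for large median kernels (> 5×5)
  equalization recovers less, consistent with the model mismatch.
* The iteration adds blur in quanta of one step kernel; with the default
  σ = 1 step the residual blur mismatch after equalization can be up to
  ~0.46 in σ² (a larger step is faster but coarser — both are exposed as
  parameters).
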