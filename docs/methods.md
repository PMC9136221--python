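# Methods

## Contour extraction and canonical frame

Input masks are binary images with one 8-connected foreground region
(multi-fascicle masks are split by connected-component labeling first).
The ordered pixel boundary is extracted by Moore-neighbor tracing with
Jacob's stopping criterion — deterministic, ordered output, each
boundary pixel visited once on simply-shaped regions. Image coordinates
(row, col) map to math coordinates (x, y) = (col, −row): flipping the
row axis makes "counterclockwise" mean positive signed area, matching
the complex-plane convention; pixel centers sit at integer coordinates.

The canonical frame subtracts the foreground-pixel centroid of the
*region* (not the mean of boundary points, which over-weights densely
sampled stretches), forces counterclockwise orientation, and rotates the
point order so the contour starts at the point with minimal |atan2(y, x)|
— the intersection with the positive real axis. Ties go to the smaller
index in the oriented sequence. Canonicalization is idempotent.

## Elliptic Fourier model

For a closed polygonal contour with increments (Δx_p, Δy_p), chord
lengths Δt_p = √(Δx_p² + Δy_p²) and cumulative parameter t_p (t_N = T,
the perimeter; the closing step from the last point back to the first is
included), the order-k coefficients are the classical closed-form
projections, e.g.

    a_k = T / (2 k² π²) · Σ_p (Δx_p / Δt_p) · (cos(2πk t_p / T) − cos(2πk t_{p−1} / T))

and likewise b_k (sines), c_k, d_k (y-increments). The constants a0, c0
are the parametric means of x(t), y(t), accumulated per segment with the
ξ/δ correction terms (ξ_1 = δ_1 = 0) plus the first point's coordinates;
for a centroid-centered contour they are ≈ 0. Reconstruction evaluates
the truncated series at uniform normalized parameter τ ∈ [0, 1), with T
folded into the angular argument — the representation is therefore
independent of the contour's absolute perimeter, which is what makes
parameters comparable across fascicles of different sizes.

**Reparameterization caveat.** Fitting is a Fourier projection *under
the contour's own arc-length parameterization*. The reconstruction of a
truncated model is traversed at uniform τ, which is proportional to arc
length only when the curve has constant speed (circles). Refitting a
reconstruction therefore re-expands the same geometric shape under a
slightly different parameterization: coefficients are reproduced exactly
for circles (measured ≲ 1e-6 relative) but shift, for general shapes, by
roughly three times the harmonic-to-fundamental amplitude ratio (a pure
2:1 ellipse with a1 = 20 refits to a1 ≈ 18.3). Shape-level agreement is
unaffected — round trips are validated by Dice/H_E, coefficient-level
round trips only on constant-speed curves. Any pipeline comparing raw
coefficients should fit all contours from their original point sets, not
from reconstructions.

## Closed cubic B-spline model

The comparison model samples m control points from the contour at equal
index intervals (round(jN/m); equal arc-length spacing is available via
a flag) and closes the control polygon periodically. One published
description of this construction appends two wrap control points; a
cubic needs degree-many (three) appended points for a continuous seam,
so three are used — the curve is then C² everywhere, including at
u = 0/1 (seam gap measured < 1e-9 px). Basis functions follow the
Cox–de Boor recursion with 0/0 := 0 over a uniform (repetition-1) knot
vector whose valid span is scaled to [0, 1]; evaluation at u = 1 takes
the left limit. Evaluation agrees with an independent de Boor
implementation (scipy's BSpline) to 1e-10.

With m = 21 the model carries 42 free coordinates before closure.
Counts of "more than 63/64 parameters" have appeared for this
construction; the basis of that count is unclear and this package
reports its own (2m plus the dependent wrap points).

## Metrics

* **Dice** is computed on pixel masks at the original resolution.
  Reconstructions are rasterized by an even–odd scanline fill evaluated
  at pixel centers, half-open in both axes (a center exactly on a left
  edge is inside, on a right edge outside), so boundary ties are counted
  once and the filled area is unbiased.
* **Hausdorff H** is *directed*, reconstruction → original (max over
  reconstructed points of the nearest-original distance), exactly as the
  evaluation index is defined; a symmetric variant exists behind a flag
  but is never the default.
* **H_E = H/N·100** uses N = the *original* contour's point count. Since
  traced contours have roughly one point per boundary pixel, N is a
  perimeter proxy and H_E is a scale-free boundary error.
* Dataset-level aggregation uses arithmetic means of per-contour Dice,
  H and H_E. (Whether a published per-order H row is a mean or a max
  over contours is ambiguous; the mean is implemented.)
* `evaluate()` samples the model at max(10N, 720) points and, by
  default, rasterizes original and reconstruction on a shared grid built
  around the contour — legitimate because all three metrics are
  translation-invariant; passing a mask uses that grid instead.

## Order selection

`evaluate_orders` fits every contour at orders 1..K and averages the
metrics; `select_order` returns the smallest order with mean Dice ≥ 95%
and mean H_E ≤ 5% (both enforced conjunctively; defaults 95 and 5). No
qualifying order is a regular result carrying the best row, not an
exception. Hausdorff distance is reported but never used for selection:
H is not monotone in the order, so it cannot rank model complexity.

## Parameter statistics

Candidate families: normal, logistic, t location-scale (scipy MLE) and
Gaussian mixtures (scikit-learn EM, full covariances, 3 restarts, fixed
seed, components reported sorted by mean so output is deterministic).
Model choice minimizes BIC = k·ln n − 2·logL, which penalizes the
mixture's extra parameters; with nested families on Gaussian data the
penalty breaks the tie toward the normal. The t density is the
location-scale transform of the Student t with ν degrees of freedom;
ν̂ → ∞ recovers the normal.

The published piecewise forms for the fundamental amplitudes assign one
Gaussian component per support interval with hard boundaries and no
weights. `pdf_piecewise_mixture` evaluates that form verbatim (with the
exponent sign taken negative — a positive sign diverges, and the printed
prefactors 1/5, 1/6.68, 1/3.86 match 1/(σ√(2π)) with the printed
denominators equal to 2σ²); it is documented as not integrating to 1 in
general. Proper fitting and simulation use standard weighted mixtures.

## Synthetic generator

Defaults encode the published population laws in pixel units:

| parameter | law | values |
|---|---|---|
| a1 | 3-component Gaussian mixture | (14.11, 5), (36.51, 6.68), (58.15, 3.86) |
| d1 | 4-component Gaussian mixture | (14.4, 4.44), (29.99, 1.77), (41.57, 4.41), (59.15, 3.75) |
| b3 | normal | N(0.03, 0.46²) |
| b1, c1, remaining harmonics | t location-scale | per-parameter (μ, σ, ν) table |
| a0, c0 | fixed 0 | centered frame |

The mixtures are sampled with equal weights (the published component
tables carry none) and truncated to x > 0, since a1, d1 act as the
fascicle's caliber. Contours are reconstructed at 400 points, screened
for simplicity (shapely segment-intersection test; heavy-tailed t draws
occasionally fold the curve) and minimum area (50 px), and rasterized on
a grid padded 10% beyond the bounding box plus a half-pixel offset that
keeps symmetric shapes off exact lattice alignments, where boundary ties
bias pixel counts. Rejected draws are resampled; the observed rejection
rate at the default laws is ≈ 0–2%, and generation aborts with
diagnostics above 90%.

What the generator emulates: the marginal distributions of the order-4
parameters and hence realistic calibers, ellipticities and boundary
detail. What it does not: the joint dependence structure (parameters are
drawn independently — real fascicles correlate, e.g., a1 with d1),
MicroCT noise and segmentation artifacts, slice-to-slice continuity, and
splitting/merging topology. Passing end-to-end bounds on synthetic data
therefore demonstrates the modeling pipeline's fidelity, not
segmentation robustness on real images.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen to
keep Monte-Carlo error well inside the stated tolerances: 100k samples
for normal-law recovery (SE of σ̂ ≈ 0.001 ≪ 0.01), 50k for the t law
(SE of μ̂ ≈ 0.02 ≪ 0.15) and the mixtures, and 50 synthetic bundles for
the end-to-end experiment (mean Dice ≈ 98.5%, worst H_E ≈ 1%, stable to
±0.3 across seeds). All randomness flows from numpy Generators seeded
explicitly; the acceptance script spawns independent child seeds from
the single command-line seed. Degenerate inputs (empty masks, N < 3
contours, duplicate consecutive points, zero-scale samples, degenerate
EM components, out-of-domain spline parameters) raise informative
errors rather than propagating NaNs.

## Known limitations

* Coefficient-level round trips are exact only for constant-speed
  curves (see the reparameterization caveat above).
* Moore tracing assumes one 8-connected region; 1-pixel-wide necks can
  be traversed twice (each traversal direction), which is correct for
  the trace but inflates N slightly.
* H_E's normalization by point count assumes ≈ 1 point per boundary
  pixel; densely resampled contours would need N replaced by perimeter.
* The generator's independence assumption makes extreme aspect ratios
  (large a1 with small d1) more common than in real fascicle
  populations.
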