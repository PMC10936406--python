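# Methods

This note documents the models, conventions, numerical choices and
limitations behind `semstack`. Empirical statements here are limited to
what the test suite and `scripts/acceptance.py` themselves compute.

## Coordinates and data model

Points are `(x, y)` with `x` the column (SEM fast-scan direction) and `y`
the row (slow-scan), origin top-left, 0-based; arrays are indexed
`(z, y, x)` with `z` the acquisition (milling) order. All images are held
as float64 internally; integer files are cast without rescaling so that
fitting and subtraction have signed headroom. Pixel size is isotropic
in-plane, in nanometres, with precedence: explicit argument > file
metadata > error — physical resolutions are never guessed. Multipage TIFF
is the baseline container; MRC2014 is supported through a minimal
single-volume reader/writer (modes int8/int16/float32/uint16, voxel size
from the cell dimensions).

## Constrained alignment

The model maps a landmark on slice `k+1` into slice `k`'s frame as
`r' = A·r + b`. The `TransformSpec` flags select which entries of `A` are
free; everything else is held at identity, so the returned matrix contains
the disabled entries bit-exactly. Supported families:

- any subset of `{translate, shear_x, shear_y, stretch_x, stretch_y,
  scale_uniform}` — the residual is linear in the free parameters, solved
  by exact least squares (`lstsq`; rank-deficiency raises);
- `{translate, rotate}` and `{translate, rotate, scale_uniform}` — the
  closed-form Procrustes/Umeyama solution (SVD of the centered
  cross-covariance, determinant-corrected to exclude reflections);
- `affine` — full six-parameter least squares, needing ≥3 non-collinear
  points.

Mixing `rotate` with shear/stretch is rejected: no closed form preserves
the constraint contract there, and the physical acquisition models never
need it.

Landmarks come from scikit-image's SIFT with nearest-neighbour descriptor
matching, cross-checking, and a Lowe ratio of 0.75; detector settings are
recorded in the result for reproducibility. Outlier filtering is either a
component-wise percentile band on the displacement vectors (default q = 5;
a match is kept when both its x and y displacement lie inside the
inclusive [q, 100−q] percentile interval) or RANSAC under the constrained
family (default tolerance 2 px, 1000 iterations, minimal sample
`max(3, ceil(n_params/2))`, explicit seed, final refit on the consensus
set). Percentile filtering is the fast option; RANSAC is preferred when
matches are scarce or the misalignment is large.

Alignment is sequential from slice 0: the correcting transform for each
consecutive pair is fitted, cumulative transforms to slice 0 are composed
as exact matrix products, and each slice is resampled exactly once with
the cumulative map (bilinear interpolation, out-of-bounds filled with the
slice median so borders do not skew later statistics). A pair with too
few matches reuses the previous pairwise transform (identity if none) and
is flagged in the result rather than raising — a partially aligned stack
with diagnostics is more useful than an aborted run.

## Charge-artifact suppression

Charging produces dark regions elongated along the fast-scan axis that
extend asymmetrically past the charging feature. The filter assumes a
segmentation of the charging centers is provided (it is deliberately not
computed here; thresholding is unreliable and ML segmentation is an
upstream concern) and that rows a few lines away, after correction,
approximate the clean signal.

Per row containing labeled segments: the background is the per-column
mean of the up-to-`n_lines_average` (default 5) previously corrected rows
of the current pass, excluding masked pixels column-wise; a column masked
in every contributing row falls back to the mean of the valid background
values. The difference between the row and this background, with masked
columns invalid, is fitted on each side of each segment with the
three-parameter shifted logistic sigmoid
`f(x) = a/(1 + exp(±(x−b)/c))` (sign chosen so the curve saturates to `a`
at the segment and decays to 0 away from it; left and right sides fitted
independently because real tails are asymmetric). Gaussian or exponential
tail shapes are deliberately not offered: they lack the saturation
behaviour and converge poorly on flat or feature-contaminated windows.

Numerical details: Levenberg–Marquardt on (amplitude, center, log-width)
with deterministic initial values from the segment geometry — amplitude
from the mean of the 5 valid pixels nearest the boundary, center at the
boundary, width `max(2, segment_length/4)`; the exponent is clamped at
±500 to avoid overflow; a fit is discarded (no subtraction, counted in the
per-image log) when the solver fails, the window has fewer than 4 valid
pixels, or the fitted amplitude exceeds five times the largest observed
difference (a plateau extrapolated far beyond the data is a failure mode
of windows whose midpoint falls at the edge, not a measurement). Fitting
windows are bounded by neighbouring segments so tails never leak across
centers. Fitted curves are subtracted from unmasked pixels only.

The down pass (top-to-bottom) and up pass (bottom-to-top) each run
sequentially on their own copy, each skipping its seed row; the output is
their arithmetic mean — symmetric, deterministic, and testable (`both`
output equals the average of the `down` and `up` outputs identically). An
empty mask is a bitwise no-op. The whole filter has no random state: two
runs are bitwise identical.

`background_std_report` measures the standard deviation of unmasked
intensities within a Chebyshev radius (default 50 px) of any labeled
pixel, before and after; flattening the tails should reduce it.

## FRC resolution estimation

`compute_frc` applies a separable 2D Hann taper (edge-leakage control;
standard FRC practice), takes the DFTs, and for each integer radial ring
(width 1 bin, radii rounded to the nearest integer, DC excluded) computes
`Re{Σ F1·conj(F2)} / sqrt(Σ|F1|²·Σ|F2|²)`. Using the real part rather
than the magnitude preserves sign: identical images give exactly +1,
negated images −1. Frequencies are normalized by the outermost ring
(`min(h, w)//2`), so `f = 1` is a 2-pixel period and
`resolution_px = 2/f_crossing`. The crossing is the first ring below the
threshold (default 1/7, stored at full precision), linearly interpolated
between the bracketing rings; a curve that never drops below threshold is
flagged `at-limit` (resolution 2 px), one already below at the first ring
`unresolved`.

The one-image FRC splits the (even-cropped, square-cropped) image into the
four pixel-parity sub-images and averages the FRC of the two diagonal
pairs (even-even vs odd-odd, even-odd vs odd-even) — both diagonals are
used to reduce variance, and the pairing is deterministic. Sub-images are
treated as contiguous grids at the original pixel pitch; together with the
noise decorrelation between parities this makes the one-image resolution
systematically finer than the two-image gold standard, which is precisely
the bias the calibration absorbs. The calibration family is a
two-parameter power law `d_2img = α·d_1img^β` fitted in log–log space —
with calibration datasets of only a few pixel sizes a two-parameter
monotone family is as much as the data can support. The model records its
fitted domain and flags applications outside it, plus a monotonicity
warning if the input points are not increasing.

Local resolution maps use non-overlapping tiles anchored at the top-left;
partial edge tiles are dropped and tiles more than 50% masked are excluded
(featureless or artifact regions would otherwise skew the distribution).
`compare_tile_sizes` reports per-size distribution statistics, the spread
of the medians, and the Kruskal–Wallis H-test across the per-tile samples
(null hypothesis: equal group medians).

## Synthetic data

Every generator takes an explicit seed, uses one private NumPy generator
(no global state), is bitwise reproducible, and returns a
`GroundTruthRecord` of all applied parameters; tests read ground truth
from the record only.

- `make_textured_image`: multi-scale smoothed random impulses
  (σ = 2/5/11 px) plus additive Gaussian noise (default σ = 0.02 of an
  ~[0,1] range) — enough local contrast that SIFT finds hundreds of
  keypoints on 512², standing in for cellular SEM texture.
- `make_misaligned_stack`: a textured base warped per slice by a known
  cumulative transform from a stated family; consecutive slices also get a
  2% smooth intensity perturbation so they are similar-but-not-identical
  like true serial sections.
- `make_charging_image`: flat background (default 100 intensity units)
  with dark filled ellipses (the labeled centers) and per-row additive
  tails of the exact sigmoid form anchored at the ellipse boundary, with
  asymmetric left/right amplitudes, plus optional Gaussian noise. The test
  fixture emulating a lipid-droplet charging geometry uses one elongated
  center (45×12 px), tails of amplitude −30/−18 and width 6/12 px, and
  noise σ = 0.5 — a regime where the artifact dominates the noise near the
  center, as it does in data worth correcting.
- `make_bandlimited_pair`: white noise hard-low-passed at a known
  normalized cutoff, emitted as two realizations with independent additive
  noise at a stated SNR (default 10), so the two-image FRC crossing has a
  known ground truth.

What these do **not** emulate: Poisson–Gaussian SEM noise, curtaining
streaks, bright or mixed-polarity charging, focus gradients, or
non-stationary texture. Passing tests therefore demonstrate algorithmic
correctness against known ground truth, not performance envelopes on real
instruments — on real data the charging-center segmentation quality and
the instrument calibration dominate.

## Problem sizes

The test suite and acceptance script run end-to-end pipelines at sizes
where the statistics are already stable: 512² images for SIFT/shear
recovery, 6-slice 256² stacks for full alignment, a 256×384 charging
slice, and a 1024² band-limited image tiled at 128/256/512 for the
tile-size comparison (64 + 16 + 4 tiles). These complete in seconds on a
single CPU while exercising the identical code paths a full-size stack
would use.

## Known limitations

- Percentile match filtering acts component-wise on displacements; other
  reasonable definitions (magnitude, match score) would keep slightly
  different sets.
- The two-pass combination in the charge filter is a simple average;
  running the passes sequentially in place is a plausible alternative that
  was not adopted because averaging is symmetric and easier to verify.
- One-image FRC ignores the √2 diagonal spacing of checkerboard
  sub-sampling by design; consequently uncalibrated values are only
  comparable to each other, not across methods, until calibrated.
- MRC support covers single-volume files only (no extended-header
  semantics, no 4D stacks).
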