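# Methods

`microimage` is a compact, self-contained image-processing suite: a small
set of classic algorithms (edge detection, binary features, robust
homography estimation, Hough transforms, region measurement) plus three
end-to-end pipelines that exercise them, all running on synthetic imagery
produced by the package's own generators.  This note records the models,
the numerical choices, and what the synthetic fixtures do and do not show.

## The value-range contract

Every image is a numpy array under one of two contracts: `uint8` samples
in {0..255} or floating-point samples in [0, 1], with the channel axis
last.  All operations validate input and produce output under the same
contract, so pipelines compose without range bookkeeping.  `to_float`
divides by 255; `to_ubyte` multiplies by 255 and rounds half away from
zero, which makes the round trip the identity on all 256 levels and makes
0.5 → 128 deterministic across platforms.  Signed float images ([−1, 1])
are deliberately not produced anywhere; the only out-of-range value is the
−1 background sentinel written by `warp` during mosaicking, and it is
consumed by `add_alpha` (alpha = 0 exactly where a sample equals the
sentinel) before any further arithmetic.

Classic parameter values quoted for 8-bit imagery keep their meaning under
the float contract by dividing by 255: the coin pipeline's offset −15 and
Canny thresholds 10/80 become −15/255, 10/255 and 80/255.

`rgb2gray` uses the ITU-R BT.601 luma weights (0.2125, 0.7154, 0.0721).
Any fixed convex weights would satisfy the package's own guarantees
(achromatic invariance, range preservation); tests therefore do not pin
the third decimal.

## Filtering and edge detection

All filters use reflect (symmetric) boundaries, which conserve the mean
and avoid spurious edge responses at the frame.

* **Gaussian**: separable, kernel truncated at 4σ.
* **Sobel** (public op): the 3×3 kernel pair scaled by 1/4 per axis, so a
  unit step yields a bounded, implementation-independent response.
* **Median**: uint8 only, exact median of the (2r+1)² window.  Rank
  filtering on floats is excluded so every output value is an exact input
  sample.
* **Difference of Gaussians**: `gaussian(low σ) − gaussian(high σ)`,
  the standard band-pass used for blob/defect detection.
* **Adaptive threshold**: the local threshold is the Gaussian-weighted
  window mean with σ = (block_size − 1)/6, truncated at 3σ so the kernel
  support equals the stated block size, minus `offset`.

**Canny** follows the classic chain: Gaussian smoothing at σ, Sobel
gradients, non-maximum suppression with linear interpolation of the two
neighbors along the gradient direction, then double-threshold hysteresis
keeping weak pixels only when 8-connected to a strong pixel.  One
deliberate numerical choice: the gradient inside Canny is computed with
the *unnormalized* (classical) Sobel kernels rather than the 1/4-scaled
public ones.  With the normalized kernels, a threshold of 80/255 could
never fire on [0, 1] imagery (a full-contrast step smoothed at σ = 3 peaks
near 0.27), whereas under the classical kernels the historical 8-bit
thresholds, divided by 255, straddle the response of moderate-contrast
steps — which is precisely the regime the coin pipeline's printed defaults
assume.  NMS ties (exactly equal interpolated neighbors) are kept, so a
perfectly symmetric step can produce a 2-px ridge; on smoothed realistic
data edges are 1 px wide.

## Features and matching

* **peak_local_max**: strict maxima of the (2d+1)² window (border-clipped),
  processed in decreasing intensity with ties broken by (row, col), greedily
  suppressing candidates closer than d (Euclidean) to an accepted peak.
  This is pinned exactly by an exhaustive brute-force oracle in the tests.
* **FAST-9**: a pixel is a corner when ≥ 9 contiguous pixels of its
  16-pixel radius-3 circle are all brighter than I(p)+t or all darker than
  I(p)−t.  No machine-learned decision tree; corners are ranked by the
  Harris response (k = 0.04, structure tensor of the σ=1-smoothed image).
* **Oriented multi-scale keypoints**: FAST corners on an image pyramid
  (8 levels, downscale 1.2), strongest `n_keypoints` kept across levels,
  positions reported at level 0.  Orientation is the intensity-centroid
  angle atan2(m01, m10) over the circular 31-px patch.
* **Binary descriptor**: 256 pairwise intensity comparisons on the
  σ=2-smoothed level image.  The sampling pattern is drawn once from an
  isotropic Gaussian (σ = 31/5), clipped to ±13 px, from a fixed seed
  compiled into the package; the pattern is rotated by the keypoint angle
  discretized to 12° bins.  Keypoints keep a 20-px margin: a clipped
  sample can sit 13·√2 ≈ 18.4 px out after rotation.  Descriptor equality
  with other implementations is a non-goal; only self-consistent matching
  quality is guaranteed (and tested: a 90°-rotated view matches with
  median Hamming distance far below the 128-bit random expectation).
* **Matching**: brute-force Hamming nearest neighbor; cross-checking keeps
  mutually-nearest pairs, yielding a partial one-to-one mapping, with
  distance ties resolved to the lowest index.

## Transforms, warping, Hough

Transforms are 3×3 homogeneous matrices acting on (x, y) = (col, row)
points — the literature's convention, dual to (row, col) image indexing;
the flip happens only at the warp/keypoint boundary.  `compose(a, b)`
means "a then b".  Estimation uses the closed-form similarity fit
(Procrustes with uniform scale), least squares for affine, and the
Hartley-normalized DLT for homographies; exact correspondences are
reproduced to better than 1e−8, and configurations with fewer than 8
independent constraints (e.g. 3 collinear points in a minimal sample)
raise a degeneracy error rather than returning an arbitrary member of the
solution family.

`warp` takes the *inverse* mapping (output → input coordinates) and
samples bilinearly; anything whose 2×2 support leaves the input becomes
`cval` exactly, so an integer translation is a bit-exact shift with a
clean fill band.  `rescale` pre-smooths with σ = (1/f − 1)/2 when
downscaling and edge-pads by two pixels before the warp so that output
pixels created by the ceil-rounded shape interpolate the clamped border
value instead of the fill value.

`hough_line` votes on a unit-spaced ρ grid spanning ± the image diagonal
over 180 angles in [−π/2, π/2).  Peak detection extends the accumulator
across the θ seam (θ+π is the same line with ρ negated) before
local-maximum filtering; without this, near-vertical lines alias into
half-peaks at the opposite end of the θ axis.  `hough_circle` votes along
the package's own rasterized circle of each candidate radius; because the
rasterizer's offset set is symmetric under negation, every perimeter pixel
of a drawn circle votes for the exact center, which is why recovery on
rasterized input is exact.  Per-radius maxima are ranked across radii by
votes/(2πR) to remove the large-radius bias.

## Measurement

Connected components use two-pass union-find in row-major scan order with
labels renumbered by first encounter — a deterministic labeling that an
independent BFS flood-fill oracle reproduces exactly (tested exhaustively
on all 512 3×3 images and on random 64×64 images, both connectivities).
Region properties: half-open bbox, centroid, raw and central moments to
order 3, eccentricity √(1 − λmin/λmax) of the second-moment ellipse
(degenerate 1-px-wide regions yield 1.0, single pixels 0), and perimeter
as the Freeman chain-code length of the Moore-traced outer boundary
(axial steps 1, diagonal √2; a 1-px-wide bar is traversed out and back).
A single-pixel region has no boundary steps and perimeter 0.

`profile_line` samples at unit spacing from source to destination, both
inclusive (a trailing fractional step contributes the endpoint), with
bilinear interpolation and nearest-neighbor extension beyond the frame;
odd `linewidth` averages that many parallel unit-spaced offsets.

RANSAC draws `min_samples` distinct correspondences per trial, counts
inliers by Euclidean reprojection residual ≤ threshold, keeps the model
with most inliers (ties → smaller total inlier residual), and re-estimates
on the winning trial's inliers; the reported mask is evaluated under the
refined model.  The trial count is fixed (default 1000) rather than
adaptive, for deterministic runtime; degenerate subsets are skipped
without consuming the budget, up to a 5× draw cap.

## Pipelines

* **Coins**: 255-bin histogram (edges 0..255 on the 8-bit rendering),
  adaptive threshold (block 95, offset −15/255), peak_local_max
  (min_distance 20), Canny (σ=3, 10/255, 80/255), 8-connected labeling of
  the edge map, per-region boxes.  Defaults are the classic printed
  parameters rescaled to the float contract.
* **Panorama**: grayscale → rescale (default 0.25) → ORB (1000 keypoints,
  FAST threshold 0.05) → cross-checked matching → RANSAC homography
  (min_samples 4, residual threshold 2) → corner-extent computation →
  warps with cval −1 → alpha-averaged mosaic.  Background sentinels are
  zeroed before summation so single-coverage pixels stay in [0, 1].
  Blending stops at the plain alpha average; multi-resolution spline
  blending is out of scope.  Failure contract: a registration error is
  raised (naming the stage) when keypoints/matches are too few or when the
  consensus covers less than 25 % of the matches or fewer than 10
  correspondences — coincidental consensus on non-overlapping views
  measures around 5 %, genuine registrations in our regime above 90 %.
* **Crack tracking**: Canny on the first frame, circular Hough over a
  radius range (default 10..half the short side), concentric sampling
  circle at `annulus_fraction` (default 0.75 — exposed because the
  fraction is an experimental choice, not a derived quantity) of the drop
  radius, pixels ordered by angle; one diagram row per frame.

## Synthetic fixtures and their limits

The generators are pure functions of (parameters, seed) and double as the
package's study conditions:

* **Coin scenes**: background 0.2, disk peak 0.8 with a 0.1 radial
  shading, additive Gaussian noise σ = 0.03 (≤ 0.05 keeps 3σ contrast at
  the centers).  The 0.5+ rim contrast is chosen so the printed 8-bit
  pipeline parameters, rescaled to float, operate in their intended
  regime.
* **Textured pairs**: one Gaussian-smoothed noise texture (σ = 1.5,
  range-normalized to [0.05, 0.95]) rendered as an identity crop and
  through the true homography from a single larger canvas, so the second
  view has valid content everywhere and the truth transform (view-2 → 
  view-1 coordinates) matches the stitching model's direction.  A
  requested minimum overlap fraction is verified on a coordinate grid.
* **Crack stacks**: a hard-edged bright drop (0.85 on 0.2), 1-px dark
  radial cracks at evenly spaced angles with a seeded offset, growing
  linearly inward after per-crack appearance frames spread over the first
  half of the stack; frames are smoothed at σ = 0.7 and lightly
  noised (σ = 0.01).  By construction no crack reaches the 0.75 R
  sampling circle in frame 0 and all cross it in the final frame.

These fixtures exercise exactly the mechanisms the pipelines rely on —
contrast steps, texture corners, rasterized circles — but are far cleaner
than photographs: no illumination fields, no occlusion, no sensor noise
correlation, no lens distortion.  Passing tests therefore demonstrate
algorithmic correctness and parameter semantics, not robustness to
real-world imaging conditions.

## Problem sizes

The shipped test and acceptance runs use desk-scale inputs chosen as
representative rather than stressful: 256² coin scenes, 200² pair views
stitched at working scale 1.0, 10-frame 128² crack stacks, 64² oracle
images (50 for labeling, 100 for peak suppression), 200 exact estimation
sets per transform kind, and 100 seeded RANSAC scenes of 70 inliers + 30
outliers at 300 trials each.

## Known limitations

* Single-channel warping only; color pipelines convert to gray first.
* No adaptive RANSAC stopping; no approximate nearest-neighbor matching.
* The PNM dialect is the only guaranteed on-disk format (PNG via imageio
  when present); 16-bit images are rejected by design.
* Labeling and hysteresis run a Python union-find over ON pixels —
  exact and deterministic, but not suited to multi-megapixel edge maps.
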