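# microimage

A compact, self-contained image-processing library for scientific image
analysis, built around the classic building blocks that measurement
pipelines are assembled from:

* a strict **value-range contract** (uint8 ∈ {0..255}, float ∈ [0, 1])
  with converters, grayscale and alpha utilities;
* **filters**: Gaussian, Sobel, exact uint8 median, difference of
  Gaussians, Gaussian-weighted **adaptive thresholding**, and a full
  **Canny** edge detector (smoothing → gradients → non-maximum
  suppression → hysteresis);
* **features**: local-maximum detection, FAST-9 corners with Harris
  ranking, oriented multi-scale keypoints with 256-bit binary
  descriptors, brute-force Hamming matching with cross-checking;
* **transforms**: similarity/affine/projective estimation (closed-form,
  least-squares, Hartley-normalized DLT), inverse-mapping bilinear
  **warp**, anti-aliased rescaling, straight-line and circular **Hough
  transforms**;
* **measurement**: connected-component labeling, region properties
  (area, bbox, centroid, moments, eccentricity, chain-code perimeter),
  line profiles, and generic **RANSAC**;
* three end-to-end **pipelines** — coin measurement, feature-based
  panorama stitching, and drying-drop crack tracking via a space-time
  diagram — plus seeded synthetic generators that produce their inputs
  together with ground truth.

Everything runs on imagery the package generates itself; PGM/PPM (binary
PNM) files are read and written bit-exactly without external
dependencies.

## The core models

**Canny edges.**  With G<sub>σ</sub> the Gaussian kernel and
(g<sub>x</sub>, g<sub>y</sub>) the Sobel gradients of G<sub>σ</sub> ∗ I,
a pixel is an edge candidate if its magnitude m = √(g<sub>x</sub>² +
g<sub>y</sub>²) is maximal along the gradient direction (sub-pixel
interpolated); candidates with m ≥ t<sub>high</sub> seed edges and
candidates with m ≥ t<sub>low</sub> survive only when 8-connected to a
seed.

**Homography estimation.**  A projective transform H maps homogeneous
points x′ ∼ H x.  Given matched keypoints, RANSAC repeatedly fits H to
4-point subsets (normalized DLT), counts inliers with reprojection
residual ‖x′ − Hx‖ ≤ t, and re-estimates on the best consensus.  The
mosaic warps both views into a shared frame by the *inverse* mapping and
alpha-averages overlapping pixels.

**Hough transforms.**  Each ON pixel votes for all parameters consistent
with it: lines accumulate over (θ, ρ) with ρ = x cos θ + y sin θ; circles
accumulate center votes along the rasterized circle of each candidate
radius, ranked by votes/(2πR).

See `docs/methods.md` for the full account of conventions, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from microimage import coins_pipeline, make_coins_scene

image, truth = make_coins_scene(n_disks=12, seed=0)   # 256x256 float scene
report = coins_pipeline(image)                        # classic defaults

print(report.n_regions)
# 12
hits = sum(
    any(b[0] <= r < b[2] and b[1] <= c < b[3] for b in report.bboxes)
    for r, c in truth.centers
)
print(hits)
# 12
```

The pipeline thresholds the scene against the local Gaussian-weighted
mean, finds intensity peaks, traces each disk's rim with Canny, labels the
closed contours 8-connectedly, and reports one bounding box per disk:
all 12 generated disks are found, and every true center falls inside
exactly one box.  The same pipeline is available from the shell:

```sh
microimage synth --kind coins --seed 0 --out scene/
microimage coins scene/coins.pgm --report report.json
# 12 regions -> report.json
```

(`microimage panorama` and `microimage cracks` wrap the other two
pipelines the same way.)  Short narrative scripts for each capability
live in `examples/`.

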