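"""Three end-to-end applications built from the library primitives.

* :func:`coins_pipeline` — segment and measure bright disks ("coins"):
  histogram, adaptive threshold, local maxima, Canny edges, labeling,
  per-region bounding boxes.
* :func:`stitch_pair` — feature-based panorama registration: ORB keypoints,
  cross-checked Hamming matching, RANSAC homography, corner-extent
  computation, inverse-mapping warps and alpha-averaged mosaic.
* :func:`crack_spacetime` — drying-drop crack tracking: circular Hough
  detection of the drop, a concentric sampling circle, and a space-time
  diagram with one row per frame.

Classic 8-bit parameter values (95-px block, offset -15, Canny thresholds
10/80) keep their meaning here: the pipelines run under the [0, 1] float
contract, so those defaults appear divided by 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import add_alpha, rgb2gray, to_float, to_ubyte
from .errors import DetectionError, ParameterError, RegistrationError
from .features import OrbParams, match_descriptors, orb_detect_and_extract, peak_local_max
from .filters import canny, threshold_adaptive
from .measure import label, ransac, regionprops
from .synth import draw_circle_perimeter
from .transform import (
    GeometricTransform,
    compose,
    hough_circle,
    rescale,
    translation_transform,
    warp,
)

__all__ = [
    "CoinReport",
    "PanoramaResult",
    "SpaceTimeDiagram",
    "coins_pipeline",
    "stitch_pair",
    "render_mosaic",
    "crack_spacetime",
]


@dataclass
class CoinReport:
    """Output of the coin-measurement pipeline."""

    n_regions: int
    bboxes: list  # half-open (min_row, min_col, max_row, max_col)
    peak_coords: np.ndarray  # (N, 2) local-maximum positions
    histogram: np.ndarray  # 255 bin counts over u8 edges 0..255
    threshold_mask: np.ndarray | None = None


def coins_pipeline(
    image,
    block_size: int = 95,
    offset: float = -15.0 / 255.0,
    min_distance: int = 20,
    sigma: float = 3.0,
    low_threshold: float = 10.0 / 255.0,
    high_threshold: float = 80.0 / 255.0,
) -> CoinReport:
    """Measure bright disks: threshold, peaks, edges, labels, boxes.

    Stages run in order: 255-bin histogram of the 8-bit rendering of the
    image; adaptive threshold (Gaussian-weighted local mean); local maxima
    separated by `min_distance`; Canny edges; 8-connected labeling of the
    edge map; per-region half-open bounding boxes.  The defaults are the
    classic printed parameters rescaled to the float contract.
    """
    work = to_float(image)
    if work.ndim == 3:
        work = rgb2gray(image)
    counts, _ = np.histogram(to_ubyte(work), bins=np.arange(256))
    mask = threshold_adaptive(work, block_size=block_size, offset=offset)
    peaks = peak_local_max(work, min_distance=min_distance)
    edges = canny(
        work, sigma=sigma, low_threshold=low_threshold, high_threshold=high_threshold
    )
    lm = label(edges, connectivity=2)
    props = regionprops(lm)
    return CoinReport(
        n_regions=lm.n_labels,
        bboxes=[p.bbox for p in props],
        peak_coords=peaks,
        histogram=counts,
        threshold_mask=mask,
    )


@dataclass
class PanoramaResult:
    """Output of the two-image registration-and-stitch pipeline.

    `model` maps (x, y) points of the *second* image into the first
    image's frame, at the working (rescaled) resolution.  `mosaic` is a
    rows x cols x 4 array (replicated gray + alpha) alpha-averaged over the
    contributing images; `offset` is the translation that shifts both
    warped images into the positive quadrant of `output_shape`.
    """

    model: GeometricTransform
    inlier_count: int
    mosaic: np.ndarray
    offset: GeometricTransform
    output_shape: tuple
    n_matches: int = 0
    scale: float = 1.0


def render_mosaic(image0, image1, model: GeometricTransform,
                  offset: GeometricTransform = None, output_shape=None):
    """Warp `image1` onto `image0`'s frame under `model` and alpha-average.

    Returns ``(mosaic, offset, output_shape)``.  The output extent is the
    bounding box of image0's corners and image1's corners mapped through
    `model`; both images are warped with fill value -1, given alpha
    channels (alpha 0 exactly on the -1 background), summed, and divided
    by the per-pixel image count.  Passing `offset` and `output_shape`
    explicitly renders into a caller-chosen frame instead (useful to
    compare mosaics built from different models pixel-for-pixel).
    """
    image0 = np.asarray(image0, dtype=np.float64)
    image1 = np.asarray(image1, dtype=np.float64)
    if (offset is None) != (output_shape is None):
        raise ParameterError("offset and output_shape must be given together")
    if offset is None:
        r1, c1 = image1.shape
        r0, c0 = image0.shape
        corners1 = np.array([[0, 0], [0, r1], [c1, 0], [c1, r1]], dtype=np.float64)
        corners0 = np.array([[0, 0], [0, r0], [c0, 0], [c0, r0]], dtype=np.float64)
        warped_corners = model(corners1)
        all_corners = np.vstack([warped_corners, corners0])
        corner_min = all_corners.min(axis=0)
        corner_max = all_corners.max(axis=0)
        output_shape = tuple(
            int(v) for v in np.ceil((corner_max - corner_min))[::-1]
        )  # (rows, cols)
        offset = translation_transform(*(-corner_min))

    warped0 = warp(image0, offset.inverse, output_shape=output_shape, cval=-1.0)
    warped1 = warp(
        image1, compose(model, offset).inverse, output_shape=output_shape, cval=-1.0
    )
    a0 = add_alpha(warped0)
    a1 = add_alpha(warped1)
    # zero the -1 background sentinel so it does not bias the average
    a0[..., :3] *= a0[..., 3:]
    a1[..., :3] *= a1[..., 3:]
    merged = a0 + a1
    alpha = merged[..., 3]
    mosaic = merged / np.maximum(alpha, 1.0)[..., None]
    return mosaic, offset, output_shape


def stitch_pair(
    image0,
    image1,
    scale: float = 0.25,
    n_keypoints: int = 1000,
    fast_threshold: float = 0.05,
    min_samples: int = 4,
    residual_threshold: float = 2.0,
    max_trials: int = 1000,
    seed: int = 0,
    min_inliers: int = 10,
    min_inlier_fraction: float = 0.25,
) -> PanoramaResult:
    """Register two overlapping views and build an alpha-averaged mosaic.

    Both images are converted to grayscale if needed and rescaled by
    `scale` (downscaling speeds up feature detection); ORB keypoints are
    detected and described on both, matched brute-force with
    cross-checking, and a projective model mapping image-1 coordinates
    into image 0 is estimated by RANSAC.  The mosaic is assembled at the
    working resolution by :func:`render_mosaic`.

    Raises :class:`RegistrationError`, naming the failing stage, when too
    few matches or too few consensus inliers are found — overlap-free
    inputs fail loudly rather than producing a garbage mosaic.
    """
    imgs = []
    for img in (image0, image1):
        img = np.asarray(img)
        if img.ndim == 3:
            img = rgb2gray(img)
        else:
            img = to_float(img)
        imgs.append(rescale(img, scale) if scale != 1.0 else img)
    work0, work1 = imgs

    params = OrbParams(n_keypoints=n_keypoints, fast_threshold=fast_threshold)
    kp0, desc0 = orb_detect_and_extract(work0, params)
    kp1, desc1 = orb_detect_and_extract(work1, params)
    if len(kp0) < min_samples or len(kp1) < min_samples:
        raise RegistrationError(
            f"feature detection: too few keypoints ({len(kp0)}, {len(kp1)})"
        )
    matches = match_descriptors(desc0, desc1, cross_check=True)
    if len(matches) < min_samples:
        raise RegistrationError(f"matching: only {len(matches)} cross-checked matches")

    # keypoints are (row, col); transforms act on (x, y) = (col, row)
    src = kp1.positions[matches.pairs[:, 1]][:, ::-1]
    dst = kp0.positions[matches.pairs[:, 0]][:, ::-1]
    try:
        result = ransac(
            src,
            dst,
            model_kind="projective",
            min_samples=min_samples,
            residual_threshold=residual_threshold,
            max_trials=max_trials,
            seed=seed,
        )
    except Exception as exc:
        raise RegistrationError(f"ransac: {exc}") from exc
    inlier_count = int(result.inlier_mask.sum())
    required = max(min_inliers, int(np.ceil(min_inlier_fraction * len(matches))))
    if inlier_count < required:
        raise RegistrationError(
            f"ransac: consensus too small ({inlier_count} of {len(matches)} "
            f"matches; need >= {required}) — views likely do not overlap"
        )

    mosaic, offset, output_shape = render_mosaic(work0, work1, result.model)
    return PanoramaResult(
        model=result.model,
        inlier_count=inlier_count,
        mosaic=mosaic,
        offset=offset,
        output_shape=output_shape,
        n_matches=len(matches),
        scale=scale,
    )


@dataclass
class SpaceTimeDiagram:
    """Space-time reduction of an image stack.

    ``matrix[i, j]`` is the intensity of frame ``i`` sampled on the
    concentric analysis circle at angular position ``angles[j]`` (sorted
    ascending); `drop` is the detected ``(row, col, radius)``.
    """

    matrix: np.ndarray
    angles: np.ndarray
    drop: tuple
    sample_coords: tuple = field(default=None, repr=False)


def crack_spacetime(
    stack,
    annulus_fraction: float = 0.75,
    radii_range=None,
    sigma: float = 2.0,
    low_threshold: float = 0.1,
    high_threshold: float = 0.5,
    min_peak_fraction: float = 0.25,
) -> SpaceTimeDiagram:
    """Reduce a drying-drop stack to an angle-vs-time intensity diagram.

    The drop contact line is detected once, on the first frame, by Canny
    edges followed by a circular Hough transform over `radii_range`
    (default: 10 px up to half the short image side).  A concentric
    sampling circle of radius ``annulus_fraction x drop radius`` is
    rasterized, its pixels ordered by angle, and every frame is sampled on
    those pixels to form one row of the diagram.

    Raises :class:`DetectionError` when no circle accumulates at least
    `min_peak_fraction` of its perimeter in votes.
    """
    if not 0 < annulus_fraction < 1:
        raise ParameterError("annulus_fraction must be in (0, 1)")
    frames = [np.asarray(f, dtype=np.float64) for f in stack]
    if not frames:
        raise ParameterError("stack is empty")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ParameterError("all frames must have the same shape")

    edges = canny(
        frames[0], sigma=sigma, low_threshold=low_threshold, high_threshold=high_threshold
    )
    if radii_range is None:
        radii_range = np.arange(10, min(shape) // 2)
    radii_range = np.atleast_1d(np.asarray(radii_range, dtype=np.intp))
    result = hough_circle(edges, radii_range)
    if not result.peaks:
        raise DetectionError("hough_circle found no accumulator peaks")
    count, row, col, radius = result.peaks[0]
    if count < min_peak_fraction * 2.0 * np.pi * radius:
        raise DetectionError(
            f"best circle peak ({count} votes at radius {radius}) is below "
            f"{min_peak_fraction:.0%} of its circumference"
        )

    sample_radius = max(1, int(round(annulus_fraction * radius)))
    rr, cc = draw_circle_perimeter(row, col, sample_radius)
    inb = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    rr, cc = rr[inb], cc[inb]
    angles = np.arctan2(rr - row, cc - col)
    order = np.argsort(angles, kind="stable")
    rr, cc, angles = rr[order], cc[order], angles[order]

    matrix = np.stack([frame[rr, cc] for frame in frames])
    return SpaceTimeDiagram(
        matrix=matrix,
        angles=angles,
        drop=(int(row), int(col), int(radius)),
        sample_coords=(rr, cc),
    )
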