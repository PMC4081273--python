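"""Linear and rank filtering, edge detection, and local thresholding.

All filters use reflect (symmetric) boundary handling.  Thresholds are
interpreted in the image's native intensity units: the classic parameters
quoted for 8-bit imagery (e.g. Canny 10/80) become 10/255 and 80/255 once
the image is converted to the [0, 1] float contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._ccl import label_components
from .errors import ContractViolationError, ParameterError, ShapeError

__all__ = [
    "CannyParams",
    "AdaptiveThresholdParams",
    "gaussian_filter",
    "sobel",
    "median_filter",
    "difference_of_gaussians",
    "canny",
    "threshold_adaptive",
]

# public Sobel kernels: 1/4 per-axis normalization bounds the unit-step
# response; row kernel responds to d/drow
_SOBEL_ROW = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.float64) / 4.0
_SOBEL_COL = _SOBEL_ROW.T
# unnormalized (classical) kernels used inside Canny so that the standard
# printed thresholds straddle realistic step responses on [0, 1] imagery
_SOBEL_ROW_RAW = _SOBEL_ROW * 4.0
_SOBEL_COL_RAW = _SOBEL_COL * 4.0


@dataclass
class CannyParams:
    """Canny parameters: smoothing scale and hysteresis thresholds.

    `low_threshold` / `high_threshold` are gradient-magnitude thresholds in
    the image's native intensity units per pixel; ``0 < low <= high`` and
    ``sigma > 0`` are required.
    """

    sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("canny sigma must be > 0")
        if not 0 < self.low_threshold <= self.high_threshold:
            raise ParameterError("need 0 < low_threshold <= high_threshold")


@dataclass
class AdaptiveThresholdParams:
    """Local-threshold parameters: odd window width and intensity offset."""

    block_size: int = 95
    offset: float = 0.0

    def __post_init__(self):
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ParameterError("block_size must be odd and >= 3")


def _as_float_2d(image, name):
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError(f"{name} expects a single-channel (2-D) image")
    return image


def gaussian_filter(image, sigma: float) -> np.ndarray:
    """Separable Gaussian convolution (kernel truncated at 4 sigma,
    reflect boundary).  ``sigma == 0`` returns the input unchanged."""
    image = np.asarray(image, dtype=np.float64)
    if sigma < 0:
        raise ParameterError("gaussian sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    return ndi.gaussian_filter(image, sigma, mode="reflect", truncate=4.0)


def sobel(image) -> np.ndarray:
    """Gradient magnitude from the 3x3 Sobel pair (1/4-normalized).

    The response is invariant to adding a constant and zero on constant
    images; a unit step yields a bounded, implementation-independent
    response.
    """
    image = _as_float_2d(image, "sobel")
    gr = ndi.correlate(image, _SOBEL_ROW, mode="reflect")
    gc = ndi.correlate(image, _SOBEL_COL, mode="reflect")
    return np.hypot(gr, gc)


def median_filter(image, radius: int) -> np.ndarray:
    """Exact median over the (2r+1)^2 neighborhood of a uint8 image.

    Rank filtering is uint8-only so every median is an exact sample value;
    reflect boundary.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ContractViolationError("median_filter operates on uint8 images only")
    if image.ndim != 2:
        raise ShapeError("median_filter expects a single-channel (2-D) image")
    radius = int(radius)
    if radius < 1:
        raise ParameterError("median radius must be >= 1")
    padded = np.pad(image, radius, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (2 * radius + 1, 2 * radius + 1)
    )
    return np.median(windows, axis=(-2, -1)).astype(np.uint8)


def difference_of_gaussians(image, low_sigma: float, high_sigma: float) -> np.ndarray:
    """Band-pass filter: gaussian(low_sigma) - gaussian(high_sigma)."""
    if not 0 < low_sigma < high_sigma:
        raise ParameterError("need 0 < low_sigma < high_sigma")
    image = np.asarray(image, dtype=np.float64)
    return gaussian_filter(image, low_sigma) - gaussian_filter(image, high_sigma)


def _nms(mag: np.ndarray, gr: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Non-maximum suppression with sub-pixel interpolation of the two
    gradient-direction neighbors (quantized to the nearer axis)."""
    p = np.pad(mag, 1, mode="constant")
    east = p[1:-1, 2:]
    west = p[1:-1, :-2]
    north = p[:-2, 1:-1]
    south = p[2:, 1:-1]
    ne = p[:-2, 2:]
    nw = p[:-2, :-2]
    se = p[2:, 2:]
    sw = p[2:, :-2]

    ax = np.abs(gc)
    ay = np.abs(gr)
    horiz = ax >= ay
    denom = np.where(horiz, np.maximum(ax, 1e-30), np.maximum(ay, 1e-30))
    wgt = np.where(horiz, ay, ax) / denom

    sx = gc >= 0  # gradient points toward increasing column
    sy = gr >= 0  # ... toward increasing row
    base_h = np.where(sx, east, west)
    diag_h = np.where(sx, np.where(sy, se, ne), np.where(sy, sw, nw))
    base_v = np.where(sy, south, north)
    diag_v = np.where(sy, np.where(sx, se, sw), np.where(sx, ne, nw))
    fwd = np.where(horiz, (1 - wgt) * base_h + wgt * diag_h,
                   (1 - wgt) * base_v + wgt * diag_v)

    base_hb = np.where(sx, west, east)
    diag_hb = np.where(sx, np.where(sy, nw, sw), np.where(sy, ne, se))
    base_vb = np.where(sy, north, south)
    diag_vb = np.where(sy, np.where(sx, nw, ne), np.where(sx, sw, se))
    bwd = np.where(horiz, (1 - wgt) * base_hb + wgt * diag_hb,
                   (1 - wgt) * base_vb + wgt * diag_vb)

    keep = (mag >= fwd) & (mag >= bwd) & (mag > 0)
    keep[0, :] = keep[-1, :] = False
    keep[:, 0] = keep[:, -1] = False
    return keep


def canny(image, params: CannyParams | None = None, *, sigma: float = None,
          low_threshold: float = None, high_threshold: float = None) -> np.ndarray:
    """Canny edge detector: smooth, Sobel gradients, non-maximum
    suppression, double-threshold hysteresis.

    Pixels with gradient magnitude >= `high_threshold` seed edges; pixels
    >= `low_threshold` are kept only when 8-connected to a seed.  Gradients
    are computed with the classical (unnormalized) Sobel kernels, so the
    standard 8-bit thresholds, divided by 255, straddle the response of
    moderate-contrast steps under the float contract.  Output edges are at
    most one pixel wide across the gradient direction.
    """
    if params is None:
        params = CannyParams(
            sigma=1.0 if sigma is None else sigma,
            low_threshold=0.1 if low_threshold is None else low_threshold,
            high_threshold=0.2 if high_threshold is None else high_threshold,
        )
    image = _as_float_2d(image, "canny")
    smoothed = gaussian_filter(image, params.sigma)
    gr = ndi.correlate(smoothed, _SOBEL_ROW_RAW, mode="reflect")
    gc = ndi.correlate(smoothed, _SOBEL_COL_RAW, mode="reflect")
    mag = np.hypot(gr, gc)

    ridges = _nms(mag, gr, gc)
    weak = ridges & (mag >= params.low_threshold)
    strong = ridges & (mag >= params.high_threshold)
    if not strong.any():
        return np.zeros_like(weak)
    labels, n = label_components(weak, connectivity=2)
    keep_ids = np.unique(labels[strong])
    mask = np.zeros(n + 1, dtype=bool)
    mask[keep_ids] = True
    return mask[labels]


def threshold_adaptive(image, params: AdaptiveThresholdParams | None = None, *,
                       block_size: int = None, offset: float = None) -> np.ndarray:
    """Local thresholding against the Gaussian-weighted neighborhood mean.

    The threshold at pixel p is the Gaussian-weighted mean over the
    block_size window (sigma = (block_size - 1) / 6, kernel truncated at
    3 sigma so its support matches the window) minus `offset`; output is
    ``image > threshold``.
    """
    if params is None:
        params = AdaptiveThresholdParams(
            block_size=95 if block_size is None else block_size,
            offset=0.0 if offset is None else offset,
        )
    image = _as_float_2d(image, "threshold_adaptive")
    sigma = (params.block_size - 1) / 6.0
    local_mean = ndi.gaussian_filter(image, sigma, mode="reflect", truncate=3.0)
    return image > (local_mean - params.offset)
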