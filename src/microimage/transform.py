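"""Planar geometric transforms, inverse-mapping warps, and Hough transforms.

Coordinate conventions
----------------------
Images are indexed ``(row, col)``, 0-based.  Transforms act on points in
``(x, y) = (col, row)`` order, the convention used throughout the
photogrammetry literature; conversion between the two happens only at the
warp and keypoint boundaries.

A transform is a 3x3 homogeneous matrix of one of three kinds, ordered by
generality::

    similarity (scale + rotation + translation)
      < affine (last row (0, 0, 1))
        < projective (full homography with perspective division)

``compose(a, b)`` applies ``a`` first, then ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    DegenerateGeometryError,
    ParameterError,
    ShapeError,
    SingularTransformError,
)

__all__ = [
    "GeometricTransform",
    "identity_transform",
    "similarity_transform",
    "affine_transform",
    "projective_transform",
    "translation_transform",
    "compose",
    "estimate_transform",
    "warp",
    "rescale",
    "hough_line",
    "hough_circle",
    "HoughLineResult",
    "HoughCircleResult",
]

_KIND_ORDER = {"similarity": 0, "affine": 1, "projective": 2}
_MIN_SAMPLES = {"similarity": 2, "affine": 3, "projective": 4}


class GeometricTransform:
    """A 3x3 homogeneous planar transform acting on (x, y) points.

    Parameters
    ----------
    matrix : (3, 3) array
        Homogeneous matrix; must be invertible.
    kind : {'similarity', 'affine', 'projective'}
        Declared class of the transform.  Similarity and affine matrices
        must have last row (0, 0, 1); a similarity's upper-left 2x2 block
        must equal ``s * R`` with ``R`` a proper rotation and ``s > 0``.
    """

    def __init__(self, matrix, kind: str = "projective"):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (3, 3):
            raise ShapeError("transform matrix must be 3x3")
        if kind not in _KIND_ORDER:
            raise ParameterError(f"unknown transform kind {kind!r}")
        if abs(np.linalg.det(matrix)) < 1e-12:
            raise SingularTransformError("transform matrix is singular")
        if kind in ("similarity", "affine"):
            if not np.allclose(matrix[2], [0.0, 0.0, 1.0], atol=1e-9):
                raise ParameterError(f"{kind} transform must have last row (0, 0, 1)")
        if kind == "similarity":
            a = matrix[:2, :2]
            det = np.linalg.det(a)
            if det <= 0:
                raise ParameterError("similarity must have positive determinant")
            s = np.sqrt(det)
            r = a / s
            if not np.allclose(r @ r.T, np.eye(2), atol=1e-6):
                raise ParameterError("similarity block is not scale x rotation")
        self.matrix = matrix
        self.kind = kind

    def apply(self, points) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points through the transform.

        Raises :class:`SingularTransformError` if any point maps to the
        line at infinity (homogeneous w ~ 0).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        ones = np.ones((pts.shape[0], 1))
        hom = np.hstack([pts, ones]) @ self.matrix.T
        w = hom[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise SingularTransformError("point maps to the line at infinity")
        return hom[:, :2] / w[:, None]

    __call__ = apply

    @property
    def inverse(self) -> "GeometricTransform":
        """The inverse transform (same kind)."""
        return GeometricTransform(np.linalg.inv(self.matrix), self.kind)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeometricTransform(kind={self.kind!r},\n{self.matrix})"


def identity_transform(kind: str = "similarity") -> GeometricTransform:
    return GeometricTransform(np.eye(3), kind)


def similarity_transform(
    scale: float = 1.0, rotation: float = 0.0, translation=(0.0, 0.0)
) -> GeometricTransform:
    """Similarity from scale, rotation (radians, ccw in (x, y)), translation."""
    if scale <= 0:
        raise ParameterError("similarity scale must be positive")
    c, s = np.cos(rotation), np.sin(rotation)
    tx, ty = translation
    m = np.array(
        [[scale * c, -scale * s, tx], [scale * s, scale * c, ty], [0.0, 0.0, 1.0]]
    )
    return GeometricTransform(m, "similarity")


def translation_transform(tx: float, ty: float) -> GeometricTransform:
    return similarity_transform(translation=(tx, ty))


def affine_transform(matrix) -> GeometricTransform:
    return GeometricTransform(matrix, "affine")


def projective_transform(matrix) -> GeometricTransform:
    return GeometricTransform(matrix, "projective")


def compose(a: GeometricTransform, b: GeometricTransform) -> GeometricTransform:
    """The transform "apply `a`, then `b`".

    The kind of the composition is the least restrictive of the two
    operands' kinds (similarity < affine < projective).
    """
    kind = max(a.kind, b.kind, key=_KIND_ORDER.get)
    return GeometricTransform(b.matrix @ a.matrix, kind)


# ---------------------------------------------------------------------------
# estimation


def _estimate_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    # closed-form least-squares fit of s, R, t (Umeyama / Procrustes)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    var_src = (sc**2).sum() / len(src)
    if var_src < 1e-20:
        raise DegenerateGeometryError("source points are coincident")
    cov = dc.T @ sc / len(src)
    u, d, vt = np.linalg.svd(cov)
    sgn = np.eye(2)
    if np.linalg.det(u @ vt) < 0:
        sgn[1, 1] = -1.0
    rot = u @ sgn @ vt
    scale = np.trace(np.diag(d) @ sgn) / var_src
    if scale <= 0:
        raise DegenerateGeometryError("degenerate similarity (non-positive scale)")
    t = mu_d - scale * rot @ mu_s
    m = np.eye(3)
    m[:2, :2] = scale * rot
    m[:2, 2] = t
    return m


def _estimate_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError("source points are collinear")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    m = np.eye(3)
    m[:2, :] = sol.T
    return m


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    rms = np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean())
    if rms < 1e-20:
        raise DegenerateGeometryError("points are coincident")
    s = np.sqrt(2.0) / rms
    return np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )


def _estimate_projective(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    # normalized direct linear transform
    t_src = _hartley_normalization(src)
    t_dst = _hartley_normalization(dst)
    s = (np.hstack([src, np.ones((len(src), 1))]) @ t_src.T)[:, :2]
    d = (np.hstack([dst, np.ones((len(dst), 1))]) @ t_dst.T)[:, :2]
    n = len(s)
    a = np.zeros((2 * n, 9))
    a[0::2, 0:2] = s
    a[0::2, 2] = 1.0
    a[0::2, 6:8] = -s * d[:, 0:1]
    a[0::2, 8] = -d[:, 0]
    a[1::2, 3:5] = s
    a[1::2, 5] = 1.0
    a[1::2, 6:8] = -s * d[:, 1:2]
    a[1::2, 8] = -d[:, 1]
    _, sv, vt = np.linalg.svd(a)
    # a homography has 8 dof: fewer than 8 independent constraints means a
    # degenerate configuration (e.g. 3 collinear points among a minimal 4)
    if (sv > 1e-8 * sv[0]).sum() < 8:
        raise DegenerateGeometryError("degenerate (collinear) point configuration")
    h = vt[-1].reshape(3, 3)
    m = np.linalg.inv(t_dst) @ h @ t_src
    if abs(m[2, 2]) < 1e-12:
        raise DegenerateGeometryError("estimated homography has m33 ~ 0")
    m /= m[2, 2]
    if abs(np.linalg.det(m)) < 1e-12:
        raise DegenerateGeometryError("estimated homography is singular")
    return m


def estimate_transform(kind: str, src, dst) -> GeometricTransform:
    """Least-squares transform fit from (x, y) correspondences.

    Minimal counts: similarity 2, affine 3, projective 4.  Exact
    correspondences are reproduced to ~1e-8; the projective fit uses the
    Hartley-normalized DLT, the similarity fit the closed-form
    rotation/scale/translation solution.

    Raises :class:`DegenerateGeometryError` for collinear/coincident
    configurations and :class:`ParameterError` for too few points.
    """
    if kind not in _KIND_ORDER:
        raise ParameterError(f"unknown transform kind {kind!r}")
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ShapeError("src and dst must be matching (N, 2) arrays")
    if len(src) < _MIN_SAMPLES[kind]:
        raise ParameterError(
            f"{kind} estimation needs >= {_MIN_SAMPLES[kind]} correspondences"
        )
    if kind == "similarity":
        m = _estimate_similarity(src, dst)
    elif kind == "affine":
        m = _estimate_affine(src, dst)
    else:
        m = _estimate_projective(src, dst)
    return GeometricTransform(m, kind)


# ---------------------------------------------------------------------------
# warping


def warp(image, inverse_map, output_shape=None, cval: float = 0.0) -> np.ndarray:
    """Inverse-mapping warp with bilinear interpolation.

    For every output pixel, the input is sampled at
    ``inverse_map((x, y))`` — i.e. `inverse_map` maps *output* coordinates
    to *input* coordinates.  Samples whose 2x2 interpolation support falls
    outside the input are set to `cval`.

    Parameters
    ----------
    image : 2-D float array
    inverse_map : GeometricTransform or (3, 3) array
    output_shape : (rows, cols), optional
        Defaults to the input shape.
    cval : float
        Fill value for out-of-bounds samples (the panorama pipeline uses
        -1 so background pixels can be distinguished afterwards).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("warp expects a single-channel (2-D) image")
    if isinstance(inverse_map, GeometricTransform):
        matrix = inverse_map.matrix
    else:
        matrix = np.asarray(inverse_map, dtype=np.float64)
        if abs(np.linalg.det(matrix)) < 1e-12:
            raise SingularTransformError("inverse map matrix is singular")
    if output_shape is None:
        output_shape = image.shape
    out_h, out_w = int(output_shape[0]), int(output_shape[1])

    cols, rows = np.meshgrid(np.arange(out_w), np.arange(out_h))
    hom = np.stack(
        [cols.ravel(), rows.ravel(), np.ones(out_h * out_w)], axis=0
    )
    mapped = matrix @ hom
    w = mapped[2]
    finite = np.abs(w) > 1e-12
    sx = np.where(finite, mapped[0] / np.where(finite, w, 1.0), -1.0)
    sy = np.where(finite, mapped[1] / np.where(finite, w, 1.0), -1.0)

    in_h, in_w = image.shape
    valid = finite & (sx >= 0) & (sx <= in_w - 1) & (sy >= 0) & (sy <= in_h - 1)
    x0 = np.clip(np.floor(sx).astype(np.intp), 0, in_w - 1)
    y0 = np.clip(np.floor(sy).astype(np.intp), 0, in_h - 1)
    x1 = np.minimum(x0 + 1, in_w - 1)
    y1 = np.minimum(y0 + 1, in_h - 1)
    fx = sx - x0
    fy = sy - y0
    top = image[y0, x0] * (1.0 - fx) + image[y0, x1] * fx
    bot = image[y1, x0] * (1.0 - fx) + image[y1, x1] * fx
    values = top * (1.0 - fy) + bot * fy
    out = np.where(valid, values, float(cval))
    return out.reshape(out_h, out_w)


def rescale(image, factor: float) -> np.ndarray:
    """Resize by `factor` (output shape ``ceil(shape * factor)``).

    Downscaling applies an anti-alias Gaussian pre-smoothing with
    ``sigma = (1/factor - 1) / 2`` before the inverse-mapping warp;
    ``factor == 1`` returns an identical copy.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("rescale expects a single-channel (2-D) image")
    if factor <= 0:
        raise ParameterError("rescale factor must be positive")
    if factor == 1.0:
        return image.copy()
    if factor < 1.0:
        sigma = (1.0 / factor - 1.0) / 2.0
        image = ndi.gaussian_filter(image, sigma, mode="reflect", truncate=4.0)
    out_shape = (
        int(np.ceil(image.shape[0] * factor)),
        int(np.ceil(image.shape[1] * factor)),
    )
    # edge-pad so output pixels mapping just past the last input sample
    # (ceil rounding) interpolate the clamped border value, not cval
    padded = np.pad(image, 2, mode="edge")
    inverse = compose(similarity_transform(scale=1.0 / factor),
                      translation_transform(2.0, 2.0))
    return warp(padded, inverse, output_shape=out_shape, cval=0.0)


# ---------------------------------------------------------------------------
# Hough transforms


@dataclass
class HoughLineResult:
    """Straight-line Hough accumulator over (theta, rho) and its peaks.

    ``accumulator[i, j]`` counts votes for the line
    ``x cos(thetas[i]) + y sin(thetas[i]) = rhos[j]``; peaks are
    ``(count, theta, rho)`` tuples sorted by decreasing count.
    """

    accumulator: np.ndarray
    thetas: np.ndarray
    rhos: np.ndarray
    peaks: list = field(default_factory=list)


@dataclass
class HoughCircleResult:
    """Circular Hough accumulators (one center grid per candidate radius).

    Peaks are ``(count, row, col, radius)`` tuples ranked globally by count
    normalized by circle circumference (removing the large-radius bias).
    """

    accumulators: np.ndarray
    radii: np.ndarray
    peaks: list = field(default_factory=list)


def _local_peaks(acc: np.ndarray, threshold: float, min_distance: int = 5):
    """Indices of accumulator cells that are local maxima >= threshold."""
    size = 2 * min_distance + 1
    footprint_max = ndi.maximum_filter(acc, size=size, mode="constant", cval=0)
    mask = (acc >= threshold) & (acc == footprint_max) & (acc > 0)
    coords = np.argwhere(mask)
    order = np.argsort(acc[mask])[::-1]
    coords = coords[order]
    kept = []
    for rc in coords:
        if all(np.abs(rc - np.asarray(k)).max() > min_distance for k in kept):
            kept.append(tuple(rc))
    return kept


def hough_line(binary, thetas=None, peak_threshold_rel: float = 0.5) -> HoughLineResult:
    """Straight-line Hough transform of a binary image.

    Each ON pixel (r, c) votes, for every angle theta, at
    ``rho = c cos(theta) + r sin(theta)`` rounded to a unit-spaced rho grid
    spanning +/- the image diagonal.  The default theta grid is 180 evenly
    spaced angles in [-pi/2, pi/2).
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 2:
        raise ShapeError("hough_line expects a 2-D binary image")
    if thetas is None:
        thetas = np.linspace(-np.pi / 2, np.pi / 2, 180, endpoint=False)
    thetas = np.asarray(thetas, dtype=np.float64)
    h, w = binary.shape
    diag = int(np.ceil(np.hypot(h - 1, w - 1)))
    rhos = np.arange(-diag, diag + 1)
    acc = np.zeros((len(thetas), len(rhos)), dtype=np.int64)
    rr, cc = np.nonzero(binary)
    if len(rr):
        for i, th in enumerate(thetas):
            idx = np.round(cc * np.cos(th) + rr * np.sin(th)).astype(np.intp) + diag
            acc[i] = np.bincount(idx, minlength=len(rhos))
    result = HoughLineResult(acc, thetas, rhos)
    if acc.max() > 0:
        thr = peak_threshold_rel * acc.max()
        # the (theta, rho) plane wraps: theta + pi is the same line with rho
        # negated, so extend the accumulator across the theta seam before
        # local-maximum detection to suppress aliased half-peaks
        md = 4
        ext = np.concatenate([acc[-md:, ::-1], acc, acc[:md, ::-1]], axis=0)
        footprint_max = ndi.maximum_filter(
            ext, size=2 * md + 1, mode="constant", cval=0
        )[md:-md]
        mask = (acc >= thr) & (acc == footprint_max)
        coords = np.argwhere(mask)
        coords = coords[np.argsort(acc[mask])[::-1]]
        kept = []
        for rc in coords:
            if all(np.abs(rc - np.asarray(k)).max() > md for k in kept):
                kept.append(tuple(rc))
        for ti, ri in kept:
            result.peaks.append((int(acc[ti, ri]), float(thetas[ti]), float(rhos[ri])))
    return result


def hough_circle(binary, radii) -> HoughCircleResult:
    """Circular Hough transform: center-candidate voting per radius.

    Every ON pixel votes along the rasterized circle of each candidate
    radius centered on itself; true circle centers accumulate one vote per
    perimeter pixel.  Per-radius maxima are ranked across radii by
    count / (2 pi R).
    """
    from .synth import draw_circle_perimeter  # local import avoids a cycle

    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 2:
        raise ShapeError("hough_circle expects a 2-D binary image")
    radii = np.atleast_1d(np.asarray(radii, dtype=np.intp))
    if radii.min() < 1:
        raise ParameterError("radii must be >= 1")
    h, w = binary.shape
    rr, cc = np.nonzero(binary)
    accs = np.zeros((len(radii), h, w), dtype=np.int64)
    candidates = []
    for i, radius in enumerate(radii):
        dr, dc = draw_circle_perimeter(0, 0, int(radius))
        vr = rr[:, None] + dr[None, :]
        vc = cc[:, None] + dc[None, :]
        ok = (vr >= 0) & (vr < h) & (vc >= 0) & (vc < w)
        np.add.at(accs[i], (vr[ok], vc[ok]), 1)
        if accs[i].max() > 0:
            pr, pc = np.unravel_index(np.argmax(accs[i]), (h, w))
            count = int(accs[i, pr, pc])
            norm = count / (2.0 * np.pi * radius)
            candidates.append((norm, count, int(pr), int(pc), int(radius)))
    candidates.sort(key=lambda t: (-t[0], t[4]))
    peaks = [(count, r, c, radius) for _, count, r, c, radius in candidates]
    return HoughCircleResult(accs, radii, peaks)
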