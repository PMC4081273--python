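"""Local-maximum detection, ORB keypoints/descriptors, and binary matching.

The feature chain implements the classic panorama front end: FAST-9 corner
detection ranked by Harris response, an image pyramid for modest scale
invariance, orientation by the intensity-centroid moment of the 31x31
patch, and a 256-bit BRIEF-style descriptor whose sampling pattern is
rotated with the keypoint ("rBRIEF").  Descriptors are matched brute-force
by Hamming distance with optional mutual cross-checking.

Cross-implementation descriptor equality is explicitly not a goal; the
pattern table is generated once from a fixed, documented seed, and only
self-consistent matching quality is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError, ShapeError
from .filters import gaussian_filter
from .transform import rescale

__all__ = [
    "KeypointSet",
    "DescriptorSet",
    "MatchSet",
    "OrbParams",
    "peak_local_max",
    "detect_fast",
    "harris_response",
    "orb_detect_and_extract",
    "match_descriptors",
]

# 16-pixel Bresenham circle of radius 3 around a candidate corner,
# clockwise from due north (in (drow, dcol) offsets)
_FAST_CIRCLE = np.array(
    [
        (-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
        (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1),
    ],
    dtype=np.intp,
)
_FAST_N = 9  # segment-test arc length ("FAST-9")

_PATCH_RADIUS = 15  # 31x31 orientation patch
_PATTERN_CLIP = 13  # BRIEF samples clipped to +/-13 px per component
_DESCRIPTOR_MARGIN = 20  # covers a clipped sample rotated by any angle
_N_BITS = 256
_PATTERN_SEED = 74530  # fixed: the pattern table is a build constant
_N_ORIENTATION_BINS = 30  # 12-degree orientation discretization


def _brief_pattern() -> np.ndarray:
    """The fixed 256-pair sampling pattern, (256, 2, 2) as (pair, point, (x, y)).

    Pairs are drawn once from an isotropic Gaussian with sigma = 31/5 and
    clipped to +/-13 px, mirroring the classic descriptor's test geometry.
    """
    rng = np.random.default_rng(_PATTERN_SEED)
    pts = rng.normal(0.0, 31.0 / 5.0, size=(_N_BITS, 2, 2))
    return np.clip(np.round(pts), -_PATTERN_CLIP, _PATTERN_CLIP).astype(np.int64)


_PATTERN = _brief_pattern()
_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.uint8)


@dataclass
class KeypointSet:
    """Detected corners: (row, col) positions with scores, orientations
    (radians) and pyramid scale factors, all level-0 coordinates."""

    positions: np.ndarray  # (N, 2) float, (row, col)
    scores: np.ndarray  # (N,) Harris corner response
    orientations: np.ndarray  # (N,) radians
    scales: np.ndarray  # (N,) pyramid-level downscale factor

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DescriptorSet:
    """One 256-bit binary descriptor per keypoint (bool array, N x 256)."""

    bits: np.ndarray

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class MatchSet:
    """Index pairs between two descriptor sets with Hamming distances."""

    pairs: np.ndarray  # (M, 2) int: (index in set 1, index in set 2)
    distances: np.ndarray  # (M,) int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class OrbParams:
    """ORB parameters: target keypoint count, FAST contrast threshold (in
    float intensity units), pyramid depth and per-level downscale."""

    n_keypoints: int = 1000
    fast_threshold: float = 0.05
    n_scales: int = 8
    downscale: float = 1.2

    def __post_init__(self):
        if self.n_keypoints < 1:
            raise ParameterError("n_keypoints must be >= 1")
        if not 0 < self.fast_threshold < 1:
            raise ParameterError("fast_threshold must be in (0, 1)")
        if self.downscale <= 1:
            raise ParameterError("downscale must be > 1")
        if self.n_scales < 1:
            raise ParameterError("n_scales must be >= 1")


def peak_local_max(image, min_distance: int = 1) -> np.ndarray:
    """Coordinates of local maxima, greedily separated by `min_distance`.

    Candidates are strict maxima of their (2 min_distance + 1)^2
    neighborhood (clipped at the image border).  They are then processed in
    decreasing intensity — ties broken by (row, col) order — and any
    candidate closer than `min_distance` (Euclidean) to an already accepted
    peak is suppressed.  Returns an (N, 2) array of (row, col) indices.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("peak_local_max expects a 2-D image")
    min_distance = int(min_distance)
    if min_distance < 1:
        raise ParameterError("min_distance must be >= 1")
    size = 2 * min_distance + 1
    footprint = np.ones((size, size), dtype=bool)
    footprint[min_distance, min_distance] = False
    neigh_max = ndi.maximum_filter(
        image, footprint=footprint, mode="constant", cval=-np.inf
    )
    candidates = np.argwhere(image > neigh_max)
    if len(candidates) == 0:
        return np.empty((0, 2), dtype=np.intp)
    values = image[candidates[:, 0], candidates[:, 1]]
    order = np.lexsort((candidates[:, 1], candidates[:, 0], -values))
    candidates = candidates[order]
    accepted: list[np.ndarray] = []
    for cand in candidates:
        if all(np.hypot(*(cand - a)) >= min_distance for a in accepted):
            accepted.append(cand)
    return np.asarray(accepted, dtype=np.intp)


def harris_response(image, k: float = 0.04, sigma: float = 1.0) -> np.ndarray:
    """Harris corner response det(M) - k trace(M)^2 of the structure tensor
    of the sigma-smoothed image."""
    image = np.asarray(image, dtype=np.float64)
    smoothed = gaussian_filter(image, 1.0)
    gr = ndi.sobel(smoothed, axis=0, mode="reflect") / 4.0
    gc = ndi.sobel(smoothed, axis=1, mode="reflect") / 4.0
    axx = gaussian_filter(gc * gc, sigma)
    ayy = gaussian_filter(gr * gr, sigma)
    axy = gaussian_filter(gc * gr, sigma)
    return axx * ayy - axy**2 - k * (axx + ayy) ** 2


def detect_fast(image, threshold: float = 0.05) -> KeypointSet:
    """FAST-9 segment-test corners, scored by the Harris response.

    Pixel p is a corner when at least 9 contiguous pixels on its 16-pixel
    radius-3 circle are all brighter than I(p) + threshold or all darker
    than I(p) - threshold.  A 3-pixel border is excluded.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("detect_fast expects a single-channel (2-D) image")
    h, w = image.shape
    if h < 7 or w < 7:
        return KeypointSet(
            np.empty((0, 2)), np.empty(0), np.empty(0), np.empty(0)
        )
    padded = np.pad(image, 3, mode="edge")
    ring = np.stack(
        [padded[3 + dr : 3 + dr + h, 3 + dc : 3 + dc + w] for dr, dc in _FAST_CIRCLE]
    )
    brighter = ring > image[None] + threshold
    darker = ring < image[None] - threshold

    def has_arc(mask: np.ndarray) -> np.ndarray:
        tiled = np.concatenate([mask, mask[: _FAST_N - 1]], axis=0).astype(np.int8)
        csum = np.cumsum(tiled, axis=0, dtype=np.int16)
        csum = np.concatenate([np.zeros((1, h, w), np.int16), csum], axis=0)
        windows = csum[_FAST_N :] - csum[:-_FAST_N]
        return (windows == _FAST_N).any(axis=0)

    corners = has_arc(brighter) | has_arc(darker)
    corners[:3, :] = corners[-3:, :] = False
    corners[:, :3] = corners[:, -3:] = False
    positions = np.argwhere(corners)
    scores = harris_response(image)[corners]
    theta = _orientations(image, positions)
    return KeypointSet(
        positions.astype(np.float64),
        scores,
        theta,
        np.ones(len(positions)),
    )


# circular patch mask and moment coordinate grids for orientation
_PR = _PATCH_RADIUS
_pyy, _pxx = np.mgrid[-_PR : _PR + 1, -_PR : _PR + 1]
_PATCH_MASK = (_pyy**2 + _pxx**2) <= _PR**2


def _orientations(image: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Intensity-centroid orientation theta = atan2(m01, m10) over the
    circular 31 px patch; keypoints too close to the border get theta from
    the clipped patch."""
    h, w = image.shape
    padded = np.pad(image, _PR, mode="edge")
    theta = np.zeros(len(positions))
    for i, (r, c) in enumerate(np.asarray(positions, dtype=np.intp)):
        patch = padded[r : r + 2 * _PR + 1, c : c + 2 * _PR + 1]
        m10 = float((_pxx * patch)[_PATCH_MASK].sum())
        m01 = float((_pyy * patch)[_PATCH_MASK].sum())
        theta[i] = np.arctan2(m01, m10)
    return theta


def _describe(image: np.ndarray, positions: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """256 rotated pairwise intensity comparisons on the smoothed image."""
    smoothed = gaussian_filter(image, 2.0)
    bits = np.zeros((len(positions), _N_BITS), dtype=bool)
    bin_width = 2.0 * np.pi / _N_ORIENTATION_BINS
    for i, ((r, c), theta) in enumerate(zip(positions.astype(np.intp), thetas)):
        phi = np.round(theta / bin_width) * bin_width
        cos_p, sin_p = np.cos(phi), np.sin(phi)
        x = _PATTERN[..., 0]
        y = _PATTERN[..., 1]
        xr = np.round(cos_p * x - sin_p * y).astype(np.intp)
        yr = np.round(sin_p * x + cos_p * y).astype(np.intp)
        a = smoothed[r + yr[:, 0], c + xr[:, 0]]
        b = smoothed[r + yr[:, 1], c + xr[:, 1]]
        bits[i] = a < b
    return bits


def orb_detect_and_extract(image, params: OrbParams | None = None) -> tuple[KeypointSet, DescriptorSet]:
    """Detect oriented multi-scale FAST corners and extract 256-bit
    binary descriptors.

    FAST-9 corners are found at each pyramid level (`downscale` steps),
    ranked by Harris score across levels, and the strongest `n_keypoints`
    kept; positions are reported in level-0 coordinates.  Each keypoint's
    orientation is the intensity-centroid angle of its 31x31 patch, and its
    descriptor compares 256 fixed point pairs rotated by that angle
    (discretized to 12-degree bins).
    """
    params = params or OrbParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("orb_detect_and_extract expects a 2-D image")
    min_side = 2 * _DESCRIPTOR_MARGIN + 1
    if min(image.shape) < min_side:
        raise ShapeError(
            f"image too small for a {2 * _PATCH_RADIUS + 1}-px descriptor patch"
        )

    entries = []  # (score, level, r, c, theta, factor)
    for level in range(params.n_scales):
        factor = params.downscale**level
        if level == 0:
            level_img = image
        else:
            level_img = rescale(image, 1.0 / factor)
            if min(level_img.shape) < min_side:
                break
        kp = detect_fast(level_img, params.fast_threshold)
        if len(kp) == 0:
            continue
        pos = kp.positions.astype(np.intp)
        inb = (
            (pos[:, 0] >= _DESCRIPTOR_MARGIN)
            & (pos[:, 0] < level_img.shape[0] - _DESCRIPTOR_MARGIN)
            & (pos[:, 1] >= _DESCRIPTOR_MARGIN)
            & (pos[:, 1] < level_img.shape[1] - _DESCRIPTOR_MARGIN)
        )
        for (r, c), s, t in zip(pos[inb], kp.scores[inb], kp.orientations[inb]):
            entries.append((float(s), level, int(r), int(c), float(t), factor, level_img))

    entries.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
    entries = entries[: params.n_keypoints]

    if not entries:
        return (
            KeypointSet(np.empty((0, 2)), np.empty(0), np.empty(0), np.empty(0)),
            DescriptorSet(np.zeros((0, _N_BITS), dtype=bool)),
        )

    positions0 = np.array([(r * f, c * f) for _, _, r, c, _, f, _ in entries])
    scores = np.array([e[0] for e in entries])
    thetas = np.array([e[4] for e in entries])
    scales = np.array([e[5] for e in entries])

    bits = np.zeros((len(entries), _N_BITS), dtype=bool)
    by_level: dict[int, list[int]] = {}
    for i, e in enumerate(entries):
        by_level.setdefault(e[1], []).append(i)
    for level, idxs in by_level.items():
        level_img = entries[idxs[0]][6]
        pos = np.array([(entries[i][2], entries[i][3]) for i in idxs])
        th = np.array([entries[i][4] for i in idxs])
        bits[idxs] = _describe(level_img, pos, th)

    return KeypointSet(positions0, scores, thetas, scales), DescriptorSet(bits)


def _hamming_matrix(bits1: np.ndarray, bits2: np.ndarray) -> np.ndarray:
    p1 = np.packbits(bits1, axis=1)
    p2 = np.packbits(bits2, axis=1)
    return _POPCOUNT[p1[:, None, :] ^ p2[None, :, :]].sum(axis=-1, dtype=np.int32)


def match_descriptors(d1: DescriptorSet, d2: DescriptorSet, cross_check: bool = True) -> MatchSet:
    """Brute-force nearest-neighbor matching by Hamming distance.

    With `cross_check`, a pair (i, j) is kept only when j is i's nearest
    neighbor in set 2 *and* i is j's nearest in set 1, so the result is a
    partial one-to-one mapping.  Distance ties resolve to the lowest index
    (argmin convention).  Either set being empty yields an empty MatchSet.
    """
    b1 = np.asarray(d1.bits, dtype=bool)
    b2 = np.asarray(d2.bits, dtype=bool)
    if len(b1) == 0 or len(b2) == 0:
        return MatchSet(np.empty((0, 2), dtype=np.intp), np.empty(0, dtype=np.int32))
    dist = _hamming_matrix(b1, b2)
    nn12 = dist.argmin(axis=1)
    if cross_check:
        nn21 = dist.argmin(axis=0)
        idx1 = np.arange(len(b1))
        keep = nn21[nn12] == idx1
        pairs = np.stack([idx1[keep], nn12[keep]], axis=1)
    else:
        pairs = np.stack([np.arange(len(b1)), nn12], axis=1)
    distances = dist[pairs[:, 0], pairs[:, 1]]
    return MatchSet(pairs.astype(np.intp), distances)
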