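"""Connected components, region measurement, line profiles, and RANSAC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._ccl import label_components
from .errors import EstimationError, ParameterError, ShapeError
from .transform import GeometricTransform, estimate_transform

__all__ = [
    "LabelMap",
    "RegionProps",
    "RansacResult",
    "label",
    "regionprops",
    "profile_line",
    "ransac",
]


@dataclass
class LabelMap:
    """Integer component map: 0 is background, labels run 1..n_labels."""

    labels: np.ndarray
    n_labels: int


@dataclass
class RegionProps:
    """Measurements of one labeled region.

    bbox is half-open: ``(min_row, min_col, max_row, max_col)`` with the
    max indices exclusive, so ``max_col - min_col`` is the width.  Moments
    are 4x4 arrays indexed ``[p, q]`` for sum(row^p col^q), raw about the
    origin and central about the centroid; eccentricity comes from the
    second-central-moment inertia ellipse, ``sqrt(1 - lmin/lmax)``.
    Perimeter is the Freeman chain-code length of the 8-connected outer
    boundary (axial steps 1, diagonal steps sqrt(2)).
    """

    label: int
    area: int
    bbox: tuple
    centroid: tuple
    eccentricity: float
    perimeter: float
    moments: np.ndarray
    moments_central: np.ndarray
    mean_intensity: float | None = None


def label(binary, connectivity: int = 2) -> LabelMap:
    """Label connected components of a binary image.

    ``connectivity=1`` is the 4-neighborhood, ``connectivity=2`` (default,
    the right choice for linking Canny edge chains) the 8-neighborhood.
    Components are numbered 1..n in row-major first-encounter order.
    """
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ShapeError("label expects a 2-D binary image")
    labels, n = label_components(binary.astype(bool), connectivity)
    return LabelMap(labels, n)


# clockwise Moore neighborhood starting due north: (dr, dc) and step weight
_MOORE = [
    ((-1, 0), 1.0), ((-1, 1), np.sqrt(2)), ((0, 1), 1.0), ((1, 1), np.sqrt(2)),
    ((1, 0), 1.0), ((1, -1), np.sqrt(2)), ((0, -1), 1.0), ((-1, -1), np.sqrt(2)),
]


def _chain_perimeter(mask: np.ndarray) -> float:
    """Freeman chain-code perimeter via Moore boundary tracing.

    Single-pixel regions have no boundary steps and perimeter 0.
    """
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    if len(rows) == 1:
        return 0.0
    start = (int(rows[0]), int(cols[0]))  # topmost-leftmost pixel
    # entered "from the west": begin the clockwise scan at the W neighbor
    perimeter = 0.0
    cur = start
    scan_from = 6  # index of W in the clockwise Moore order
    first_move = None
    while True:
        nxt = None
        for k in range(8):
            idx = (scan_from + 1 + k) % 8
            (dr, dc), weight = _MOORE[idx]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                nxt = cand
                move = idx
                step = weight
                break
        if nxt is None:  # isolated pixel cluster degenerated (cannot happen >1 px)
            return 0.0
        perimeter += step
        # next scan starts from the backtrack direction: the neighbor we
        # came from, i.e. the reverse of the move rotated one past
        scan_from = (move + 4) % 8
        if first_move is None:
            first_move = move
            first_after_start = nxt
        elif cur == start and nxt == first_after_start and move == first_move:
            # closed the contour and repeated the initial step
            return perimeter - step
        cur = nxt


def regionprops(labels, intensity=None) -> list[RegionProps]:
    """Per-region measurements, one record per label in ascending order.

    Parameters
    ----------
    labels : LabelMap or int array
    intensity : 2-D array, optional
        When given, each record also carries the region's mean intensity.
    """
    if isinstance(labels, LabelMap):
        lab, n = labels.labels, labels.n_labels
    else:
        lab = np.asarray(labels)
        n = int(lab.max()) if lab.size else 0
    if intensity is not None:
        intensity = np.asarray(intensity, dtype=np.float64)
        if intensity.shape != lab.shape:
            raise ShapeError("intensity image must match the label map shape")

    out = []
    for lbl in range(1, n + 1):
        mask = lab == lbl
        rows, cols = np.nonzero(mask)
        if len(rows) == 0:
            continue
        area = len(rows)
        bbox = (
            int(rows.min()),
            int(cols.min()),
            int(rows.max()) + 1,
            int(cols.max()) + 1,
        )
        raw = np.zeros((4, 4))
        rf = rows.astype(np.float64)
        cf = cols.astype(np.float64)
        for p in range(4):
            for q in range(4):
                if p + q <= 3:
                    raw[p, q] = (rf**p * cf**q).sum()
        cr = raw[1, 0] / raw[0, 0]
        cc = raw[0, 1] / raw[0, 0]
        central = np.zeros((4, 4))
        dr = rf - cr
        dc = cf - cc
        for p in range(4):
            for q in range(4):
                if p + q <= 3:
                    central[p, q] = (dr**p * dc**q).sum()
        inertia = (
            np.array([[central[2, 0], central[1, 1]], [central[1, 1], central[0, 2]]])
            / area
        )
        evals = np.linalg.eigvalsh(inertia)
        lmin, lmax = float(evals[0]), float(evals[1])
        ecc = 0.0 if lmax <= 0 else float(np.sqrt(1.0 - max(lmin, 0.0) / lmax))
        sub = mask[bbox[0] : bbox[2], bbox[1] : bbox[3]]
        out.append(
            RegionProps(
                label=lbl,
                area=area,
                bbox=bbox,
                centroid=(cr, cc),
                eccentricity=ecc,
                perimeter=_chain_perimeter(sub),
                moments=raw,
                moments_central=central,
                mean_intensity=(
                    float(intensity[mask].mean()) if intensity is not None else None
                ),
            )
        )
    return out


def profile_line(image, src, dst, linewidth: int = 1) -> np.ndarray:
    """Intensity profile along the segment from `src` to `dst` (row, col).

    Samples are taken at unit spacing from `src` to `dst`, both endpoints
    included (a trailing partial step contributes the endpoint sample).
    Values are bilinearly interpolated; for ``linewidth > 1`` (odd) the
    profile is averaged over `linewidth` parallel unit-spaced offsets
    perpendicular to the line.  A zero-length line yields one sample.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("profile_line expects a 2-D image")
    linewidth = int(linewidth)
    if linewidth < 1 or linewidth % 2 == 0:
        raise ParameterError("linewidth must be odd and >= 1")
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    d = dst - src
    length = float(np.hypot(*d))
    if length < 1e-12:
        ts = np.array([0.0])
        u = np.zeros(2)
    else:
        n_whole = int(np.floor(length + 1e-9))
        ts = np.arange(n_whole + 1, dtype=np.float64)
        if length - n_whole > 1e-9:
            ts = np.append(ts, length)
        u = d / length
    perp = np.array([-u[1], u[0]])
    half = (linewidth - 1) // 2
    profiles = []
    for k in range(-half, half + 1):
        pts = src[None, :] + ts[:, None] * u[None, :] + k * perp[None, :]
        profiles.append(
            ndi.map_coordinates(image, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
        )
    return np.mean(profiles, axis=0)


@dataclass
class RansacResult:
    """Best consensus model with its boolean inlier mask."""

    model: GeometricTransform
    inlier_mask: np.ndarray
    n_trials_run: int


def _residuals(model: GeometricTransform, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    try:
        proj = model(src)
    except Exception:
        return np.full(len(src), np.inf)
    return np.hypot(*(proj - dst).T)


def ransac(
    src,
    dst,
    model_kind: str = "projective",
    min_samples: int = 4,
    residual_threshold: float = 2.0,
    max_trials: int = 1000,
    seed: int | None = None,
) -> RansacResult:
    """Subset-consensus robust transform estimation.

    Repeats `max_trials` times: draw `min_samples` distinct correspondences
    uniformly at random, fit a transform, and count inliers whose Euclidean
    reprojection residual is <= `residual_threshold`.  The model with the
    most inliers wins (ties broken by lower total inlier residual) and is
    re-estimated on all of its inliers; the returned mask is evaluated
    under that final model.  Degenerate subsets are skipped without
    consuming the trial budget, up to a cap of 5x `max_trials` draws.

    Raises :class:`EstimationError` when there are fewer correspondences
    than `min_samples` or no non-degenerate subset is found.
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    n = len(src)
    if n < min_samples:
        raise EstimationError(
            f"need at least {min_samples} correspondences, got {n}"
        )
    rng = np.random.default_rng(seed)
    best = None  # (n_inliers, -total_residual, mask, model)
    trials = 0
    attempts = 0
    while trials < max_trials and attempts < 5 * max_trials:
        attempts += 1
        idx = rng.choice(n, size=min_samples, replace=False)
        try:
            model = estimate_transform(model_kind, src[idx], dst[idx])
        except Exception:
            continue  # degenerate subset: does not consume a trial
        trials += 1
        res = _residuals(model, src, dst)
        mask = res <= residual_threshold
        count = int(mask.sum())
        score = (count, -float(res[mask].sum()))
        if best is None or score > best[0]:
            best = (score, mask, model)
    if best is None:
        raise EstimationError("no non-degenerate minimal subset found")
    _, mask, model = best
    if mask.sum() >= min_samples:
        try:
            refined = estimate_transform(model_kind, src[mask], dst[mask])
            final_res = _residuals(refined, src, dst)
            model = refined
            mask = final_res <= residual_threshold
        except Exception:
            pass  # keep the best trial model if refinement degenerates
    return RansacResult(model, mask, trials)
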