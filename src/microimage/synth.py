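"""Rasterization primitives and synthetic scene generators.

The drawing functions return pixel coordinate lists rather than painting in
place (compose them with :func:`paint`).  The scene generators produce the
three study fixtures the pipelines run on — disks on a noisy background
("coins"), a textured scene viewed under a known projective transform
(panorama pair), and a drying-drop stack with radial cracks growing inward
over time — each together with its ground truth, and each a pure function
of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import CapacityError, ParameterError, SingularTransformError
from .transform import (
    GeometricTransform,
    compose,
    identity_transform,
    translation_transform,
    warp,
)

__all__ = [
    "SceneTruth",
    "draw_line",
    "draw_circle_perimeter",
    "paint",
    "make_coins_scene",
    "make_textured_pair",
    "make_crack_stack",
]


@dataclass
class SceneTruth:
    """Ground truth attached to a generated scene.

    Only the fields relevant to the scene kind are populated: disk scenes
    fill `centers`/`radii`; pair scenes fill `transform` (mapping view-2
    (x, y) coordinates into view 1); crack stacks fill `centers`/`radii`
    (the drop) plus `crack_angles` (radians, measured as
    atan2(row - r0, col - c0)) and `crack_frames` (first frame on which
    each crack is visible).
    """

    centers: list = field(default_factory=list)
    radii: list = field(default_factory=list)
    transform: GeometricTransform | None = None
    crack_angles: list | None = None
    crack_frames: list | None = None


# ---------------------------------------------------------------------------
# rasterization


def draw_line(r0: int, c0: int, r1: int, c1: int):
    """8-connected Bresenham digital line from (r0, c0) to (r1, c1).

    Both endpoints are included; the pixel count is ``max(|dr|, |dc|) + 1``.
    Returns (rows, cols) integer arrays.
    """
    r0, c0, r1, c1 = int(r0), int(c0), int(r1), int(c1)
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    rr, cc = [], []
    r, c = r0, c0
    while True:
        rr.append(r)
        cc.append(c)
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return np.asarray(rr, dtype=np.intp), np.asarray(cc, dtype=np.intp)


def draw_circle_perimeter(r: int, c: int, radius: int):
    """Integer-midpoint (Bresenham) circle of `radius` centered at (r, c).

    Emits the 8 dihedral reflections of each octant step, deduplicated; the
    result is an 8-connected closed digital curve whose pixels all lie
    within the standard half-pixel rasterization band of the true circle.
    Returns (rows, cols) arrays.
    """
    radius = int(radius)
    if radius < 1:
        raise ParameterError("circle radius must be >= 1")
    pts = set()
    x, y, d = 0, radius, 3 - 2 * radius
    while x <= y:
        for dr, dc in (
            (y, x), (y, -x), (-y, x), (-y, -x),
            (x, y), (x, -y), (-x, y), (-x, -y),
        ):
            pts.add((r + dr, c + dc))
        if d < 0:
            d += 4 * x + 6
        else:
            d += 4 * (x - y) + 10
            y -= 1
        x += 1
    arr = np.asarray(sorted(pts), dtype=np.intp)
    return arr[:, 0], arr[:, 1]


def paint(image: np.ndarray, coords, value: float, clip: bool = True) -> np.ndarray:
    """Set listed (rows, cols) pixels of `image` to `value` (in place).

    With ``clip=True`` coordinates outside the image are silently dropped;
    otherwise out-of-bounds coordinates raise ``IndexError``.
    """
    rr, cc = (np.asarray(a, dtype=np.intp) for a in coords)
    if clip:
        ok = (rr >= 0) & (rr < image.shape[0]) & (cc >= 0) & (cc < image.shape[1])
        rr, cc = rr[ok], cc[ok]
    image[rr, cc] = value
    return image


# ---------------------------------------------------------------------------
# scene generators

_BACKGROUND = 0.2
_DISK_PEAK = 0.8
_DISK_SHADING = 0.1  # radial falloff from disk center to rim


def make_coins_scene(
    n_disks: int = 12,
    shape=(256, 256),
    noise_sigma: float = 0.03,
    seed: int = 0,
    radius_range=(12, 20),
):
    """Bright shaded disks on a dark noisy background, with ground truth.

    The contrast regime (background 0.2, disk peak 0.8, radial shading 0.1,
    noise sigma <= 0.05) is fixed so the printed coin-measurement pipeline
    parameters, rescaled to the float contract, succeed on the fixture.
    Identical seeds yield bit-identical images.

    Returns ``(image, truth)`` with truth listing (row, col) centers and
    radii.  Raises :class:`CapacityError` when the requested disks cannot
    be placed without overlap within the retry budget.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = int(shape[0]), int(shape[1])
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    budget = 500 * max(n_disks, 1)
    while len(centers) < n_disks:
        if tries >= budget:
            raise CapacityError(
                f"could not place {n_disks} non-overlapping disks in {shape}"
            )
        tries += 1
        radius = rng.uniform(*radius_range)
        margin = radius + 4
        if 2 * margin >= min(h, w):
            continue
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all(
            np.hypot(r - rc, c - cc) >= radius + rad + 6
            for (rc, cc), rad in zip(centers, radii)
        ):
            centers.append((r, c))
            radii.append(radius)

    image = np.full((h, w), _BACKGROUND)
    yy, xx = np.mgrid[0:h, 0:w]
    for (r, c), radius in zip(centers, radii):
        dist = np.hypot(yy - r, xx - c)
        inside = dist <= radius
        shaded = _DISK_PEAK - _DISK_SHADING * (dist / radius) ** 2
        image[inside] = shaded[inside]
    image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return image, SceneTruth(centers=centers, radii=radii)


def make_textured_pair(
    shape=(200, 200),
    transform: GeometricTransform | None = None,
    overlap_fraction: float = 0.5,
    seed: int = 0,
    texture_sigma: float = 1.5,
):
    """Two views of one smoothed random texture related by a known transform.

    A single texture canvas large enough for both viewports is generated;
    view 1 is the identity crop, view 2 samples the canvas through
    `transform` (which maps view-2 (x, y) coordinates into view-1
    coordinates), so view 2 has valid scene content everywhere and the two
    views share at least `overlap_fraction` of their area.

    Returns ``(image1, image2, truth)`` with ``truth.transform`` the true
    view-2 -> view-1 map.
    """
    t = transform if transform is not None else identity_transform()
    if abs(np.linalg.det(t.matrix)) < 1e-12:
        raise SingularTransformError("pair transform is singular")
    h, w = int(shape[0]), int(shape[1])

    corners2 = np.array(
        [[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=np.float64
    )
    mapped = t(corners2)
    xmin = int(np.floor(min(0.0, mapped[:, 0].min()))) - 2
    ymin = int(np.floor(min(0.0, mapped[:, 1].min()))) - 2
    xmax = int(np.ceil(max(w - 1.0, mapped[:, 0].max()))) + 2
    ymax = int(np.ceil(max(h - 1.0, mapped[:, 1].max()))) + 2
    big_h, big_w = ymax - ymin + 1, xmax - xmin + 1
    if big_h > 6 * h or big_w > 6 * w:
        raise ParameterError("transform moves the second view too far off-scene")

    rng = np.random.default_rng(seed)
    texture = ndi.gaussian_filter(
        rng.standard_normal((big_h, big_w)), texture_sigma, mode="reflect"
    )
    lo, hi = texture.min(), texture.max()
    texture = 0.05 + 0.9 * (texture - lo) / (hi - lo)

    image1 = texture[-ymin : -ymin + h, -xmin : -xmin + w].copy()
    shifted = compose(t, translation_transform(-xmin, -ymin))
    image2 = warp(texture, shifted, output_shape=(h, w), cval=0.0)

    # measure actual shared-scene fraction on a coarse grid of view-2 pixels
    gc, gr = np.meshgrid(np.arange(0, w, 2), np.arange(0, h, 2))
    pts = np.stack([gc.ravel(), gr.ravel()], axis=1).astype(np.float64)
    m1 = t(pts)
    inside = (
        (m1[:, 0] >= 0) & (m1[:, 0] <= w - 1) & (m1[:, 1] >= 0) & (m1[:, 1] <= h - 1)
    )
    if inside.mean() < overlap_fraction:
        raise ParameterError(
            f"views share only {inside.mean():.2f} of the scene "
            f"(requested >= {overlap_fraction})"
        )
    return image1, image2, SceneTruth(transform=t)


def make_crack_stack(
    n_frames: int = 10,
    drop_center=(64, 64),
    drop_radius: int = 48,
    n_cracks: int = 6,
    seed: int = 0,
    noise_sigma: float = 0.01,
):
    """Frames of a bright drying drop with dark radial cracks growing inward.

    Cracks start at the drop rim at fixed, well-separated angular positions
    (even spacing plus a seeded global offset) and grow toward the center
    frame by frame after their individual appearance frames; by the final
    frame every crack crosses the standard sampling annulus.  Frames are
    lightly smoothed so the rim is a clean edge for circle detection.

    Returns ``(frames, truth)``: a list of float images plus truth with the
    drop center/radius, crack angles and appearance frames.
    """
    if n_cracks < 1:
        raise ParameterError("n_cracks must be >= 1")
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    r0, c0 = float(drop_center[0]), float(drop_center[1])
    radius = float(drop_radius)
    margin = 8
    if r0 - radius < margin or c0 - radius < margin:
        raise ParameterError("drop must fit in the frame with an 8 px margin")
    h = int(np.ceil(r0 + radius + margin))
    w = int(np.ceil(c0 + radius + margin))

    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 2.0 * np.pi / n_cracks)
    angles = [(offset + 2.0 * np.pi * k / n_cracks) % (2.0 * np.pi) for k in range(n_cracks)]
    # appearance frames spread over the first half of the stack
    appear = [int(np.floor(k * (n_frames // 2) / n_cracks)) for k in range(n_cracks)]

    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - r0, xx - c0)
    base = np.where(dist <= radius, 0.85, _BACKGROUND)

    frames = []
    for i in range(n_frames):
        frame = base.copy()
        for phi, t_k in zip(angles, appear):
            if i < t_k:
                continue
            progress = (i - t_k + 1) / (n_frames - t_k)
            inner = radius * (1.0 - 0.92 * progress)
            rr0 = int(round(r0 + radius * np.sin(phi)))
            cc0 = int(round(c0 + radius * np.cos(phi)))
            rr1 = int(round(r0 + inner * np.sin(phi)))
            cc1 = int(round(c0 + inner * np.cos(phi)))
            paint(frame, draw_line(rr0, cc0, rr1, cc1), 0.05)
        frame = ndi.gaussian_filter(frame, 0.7, mode="reflect")
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        frames.append(np.clip(frame, 0.0, 1.0))

    truth = SceneTruth(
        centers=[(r0, c0)],
        radii=[radius],
        crack_angles=angles,
        crack_frames=appear,
    )
    return frames, truth
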