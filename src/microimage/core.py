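"""Value-range ("dtype") contract and colour/alpha conversions.

Images throughout the package are plain :class:`numpy.ndarray` objects with
the channel axis, when present, last.  Two sample kinds are supported and
their legal ranges are fixed:

===========  =========================
sample kind  legal range
===========  =========================
``uint8``    integers in {0, ..., 255}
``float``    reals in [0, 1]
===========  =========================

Every operation validates its input against this contract and produces
output that satisfies it, so arbitrarily long processing chains can be built
without tracking ranges by hand ("anything in, anything out").  The only
value that ever escapes [0, 1] is the background sentinel used by the
warping step of the panorama pipeline (conventionally -1); it is consumed by
:func:`add_alpha` before any further arithmetic.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractViolationError, ShapeError

__all__ = [
    "LUMA_WEIGHTS",
    "to_float",
    "to_ubyte",
    "rgb2gray",
    "gray2rgb",
    "add_alpha",
    "validate",
]

#: Luma weights used by :func:`rgb2gray` (ITU-R BT.601 primaries as adopted
#: by the classic scientific-Python imaging stack).  They sum to 1 so that
#: achromatic pixels are preserved exactly.
LUMA_WEIGHTS = (0.2125, 0.7154, 0.0721)


def _is_float(image: np.ndarray) -> bool:
    return np.issubdtype(image.dtype, np.floating)


def validate(image: np.ndarray) -> np.ndarray:
    """Check `image` against the value-range contract and return it.

    Raises
    ------
    ContractViolationError
        If samples lie outside the legal range for their dtype, or the
        dtype is neither uint8 nor floating point.
    ShapeError
        If the array is not 2-D or 2-D-with-channels.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ShapeError(f"expected a 2-D image, got ndim={image.ndim}")
    if image.ndim == 3 and image.shape[-1] not in (1, 3, 4):
        raise ShapeError(
            f"channel axis must have 1, 3 or 4 channels, got {image.shape[-1]}"
        )
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ShapeError("image must have at least one row and one column")
    if image.dtype == np.uint8:
        return image
    if _is_float(image):
        if image.size and (not np.isfinite(image).all()):
            raise ContractViolationError("float image contains non-finite samples")
        lo, hi = float(image.min()), float(image.max())
        if lo < 0.0 or hi > 1.0:
            raise ContractViolationError(
                f"float samples must lie in [0, 1]; found range [{lo}, {hi}]"
            )
        return image
    raise ContractViolationError(
        f"unsupported sample dtype {image.dtype}; use uint8 or float"
    )


def to_float(image: np.ndarray) -> np.ndarray:
    """Convert to the float contract: uint8 value ``v`` maps to ``v / 255``.

    Float input is validated and returned unchanged.  The mapping is
    monotone and bijective on the 256 uint8 levels.
    """
    image = validate(image)
    if _is_float(image):
        return image
    return image.astype(np.float64) / 255.0


def to_ubyte(image: np.ndarray) -> np.ndarray:
    """Convert to the uint8 contract: float ``v`` maps to ``round(v * 255)``.

    Rounding is half-away-from-zero (so 0.5 -> 128 deterministically on
    every platform).  uint8 input is returned unchanged.
    """
    image = validate(image)
    if image.dtype == np.uint8:
        return image
    # values are guaranteed non-negative, so floor(v*255 + 0.5) rounds
    # half away from zero
    return np.floor(image * 255.0 + 0.5).astype(np.uint8)


def rgb2gray(image: np.ndarray) -> np.ndarray:
    """Luma-weighted conversion of a 3-channel image to single-channel float.

    gray = 0.2125 R + 0.7154 G + 0.0721 B; output lies in [0, 1] whenever
    the input satisfies its contract.
    """
    image = validate(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ShapeError("rgb2gray expects an image with exactly 3 channels")
    fimg = to_float(image)
    return fimg @ np.asarray(LUMA_WEIGHTS)


def gray2rgb(image: np.ndarray) -> np.ndarray:
    """Replicate a single-channel image into 3 identical channels."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ShapeError("gray2rgb expects a single-channel (2-D) image")
    return np.dstack([image, image, image])


def add_alpha(image: np.ndarray, background: float = -1.0) -> np.ndarray:
    """Attach an alpha layer: 1 where a sample differs from `background`.

    The single-channel input is replicated into RGB and an alpha channel is
    appended, yielding a rows x cols x 4 float array.  Pixels exactly equal
    to `background` get alpha 0 (the convention used to mark out-of-frame
    samples produced by warping with a sentinel fill value).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError("add_alpha expects a single-channel (2-D) image")
    alpha = (image != background).astype(np.float64)
    return np.dstack([image, image, image, alpha])
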