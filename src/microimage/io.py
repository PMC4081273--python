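"""Raster image reading/writing and lazily-loaded file collections.

The mandatory on-disk dialect is binary PNM: P5 (PGM, single channel) and
P6 (PPM, three channels) with maxval <= 255, read and written bit-exactly
by this module without third-party help.  PNG reading is optional and
delegated to :mod:`imageio` when that package is available.
"""

from __future__ import annotations

import glob as _glob
import re
from pathlib import Path

import numpy as np

from .core import to_ubyte, validate
from .errors import FormatError, ShapeError

__all__ = ["read_image", "write_image", "open_collection", "ImageCollection"]

_WHITESPACE = b" \t\n\r\x0b\x0c"


def _parse_pnm_header(data: bytes):
    """Parse a P5/P6 header; return (magic, width, height, maxval, offset).

    `offset` is the index of the first raster byte.  Comments (``#`` to end
    of line) are permitted between tokens, as the format allows.
    """
    if data[:2] not in (b"P5", b"P6"):
        raise FormatError(f"not a binary PNM file (magic {data[:2]!r})", offset=0)
    magic = data[:2].decode()
    pos = 2
    tokens = []
    while len(tokens) < 3:
        # skip whitespace and comments
        while pos < len(data):
            if data[pos : pos + 1] in _WHITESPACE:
                pos += 1
            elif data[pos : pos + 1] == b"#":
                nl = data.find(b"\n", pos)
                pos = len(data) if nl == -1 else nl + 1
            else:
                break
        if pos >= len(data):
            raise FormatError("truncated PNM header", offset=pos)
        m = re.match(rb"[0-9]+", data[pos:])
        if m is None:
            raise FormatError(
                f"expected integer in PNM header, got {data[pos:pos + 1]!r}",
                offset=pos,
            )
        tokens.append(int(m.group()))
        pos += m.end()
    if pos >= len(data) or data[pos : pos + 1] not in _WHITESPACE:
        raise FormatError("missing whitespace after PNM maxval", offset=pos)
    pos += 1  # exactly one whitespace byte separates header and raster
    width, height, maxval = tokens
    if width < 1 or height < 1:
        raise FormatError(f"invalid PNM dimensions {width}x{height}", offset=2)
    if maxval > 255:
        raise FormatError(
            f"PNM maxval {maxval} exceeds 255; 16-bit images are not supported",
            offset=2,
        )
    if maxval < 1:
        raise FormatError(f"invalid PNM maxval {maxval}", offset=2)
    return magic, width, height, maxval, pos


def read_image(path) -> np.ndarray:
    """Read a raster image as a uint8 array.

    PGM (P5) yields a 2-D array, PPM (P6) a rows x cols x 3 array.  Other
    formats (e.g. PNG) are delegated to imageio when installed.

    Raises
    ------
    OSError
        If the file does not exist or cannot be read.
    FormatError
        On a malformed PNM header or truncated raster, with the byte
        offset of the defect.
    """
    data = Path(path).read_bytes()
    if data[:1] == b"P" and data[1:2].isdigit() and data[:2] not in (b"P5", b"P6"):
        raise FormatError(
            f"unsupported PNM variant {data[:2]!r}; only binary P5/P6", offset=0
        )
    if data[:2] in (b"P5", b"P6"):
        magic, width, height, maxval, offset = _parse_pnm_header(data)
        channels = 1 if magic == "P5" else 3
        n = width * height * channels
        raster = data[offset : offset + n]
        if len(raster) < n:
            raise FormatError(
                f"PNM raster truncated: expected {n} bytes, found {len(raster)}",
                offset=len(data),
            )
        arr = np.frombuffer(raster, dtype=np.uint8)
        if magic == "P5":
            return arr.reshape(height, width).copy()
        return arr.reshape(height, width, 3).copy()
    try:
        import imageio.v3 as iio
    except ImportError as exc:  # pragma: no cover - imageio is optional
        raise FormatError(
            "unrecognized image format and imageio is not installed", offset=0
        ) from exc
    arr = np.asarray(iio.imread(path))
    if arr.dtype != np.uint8:
        raise FormatError(f"only 8-bit images are supported, got {arr.dtype}")
    if arr.ndim == 3 and arr.shape[-1] not in (1, 3):
        raise FormatError(f"unsupported channel count {arr.shape[-1]}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write a uint8 image as binary PNM (P5 for 1 channel, P6 for 3).

    Float images satisfying the [0, 1] contract are converted through
    :func:`~microimage.core.to_ubyte` first.  The written file round-trips
    bit-exactly through :func:`read_image`.
    """
    image = to_ubyte(validate(image))
    if image.ndim == 3 and image.shape[-1] == 1:
        image = image[..., 0]
    if image.ndim == 2:
        magic = b"P5"
    elif image.ndim == 3 and image.shape[-1] == 3:
        magic = b"P6"
    else:
        raise ShapeError("write_image supports 1- or 3-channel images only")
    height, width = image.shape[:2]
    header = magic + f"\n{width} {height}\n255\n".encode()
    Path(path).write_bytes(header + np.ascontiguousarray(image).tobytes())


class ImageCollection:
    """An ordered, lazily-loaded collection of image files.

    Files matching `pattern` are resolved eagerly and sorted
    lexicographically so the ordering is reproducible regardless of
    filesystem enumeration order, but no file is *read* until its index is
    accessed; each file is read at most once and cached thereafter.

    Parameters
    ----------
    pattern : str
        Glob pattern, e.g. ``'stack/*.pgm'``.
    load_func : callable, optional
        Loader applied to each path on first access (default
        :func:`read_image`).  Injectable for testing and for custom formats.
    """

    def __init__(self, pattern: str, load_func=read_image):
        self.pattern = pattern
        self.paths = sorted(_glob.glob(pattern))
        self._load = load_func
        self._cache: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.paths)

    def __getitem__(self, index: int) -> np.ndarray:
        if not -len(self.paths) <= index < len(self.paths):
            raise IndexError(
                f"collection index {index} out of range for {len(self.paths)} files"
            )
        index %= len(self.paths)
        if index not in self._cache:
            self._cache[index] = self._load(self.paths[index])
        return self._cache[index]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ImageCollection({self.pattern!r}, {len(self)} files)"


def open_collection(pattern: str, load_func=read_image) -> ImageCollection:
    """Open a lazily-loaded :class:`ImageCollection` for `pattern`."""
    return ImageCollection(pattern, load_func=load_func)
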