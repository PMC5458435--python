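"""Grayscale raster I/O and view-orientation handling.

Images are plain 2-D ``numpy.uint32`` arrays, row-major with row 0 at the
top.  Stored sample values are carried verbatim into the 32-bit container:
an 8-bit sample 200 becomes the integer 200, a 16-bit sample 65535 stays
65535.  Supported on-disk formats are PGM (P2/P5, maxval <= 65535) and
single-channel PNG (8- or 16-bit).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "as_gray_image",
    "read_gray_image",
    "write_gray_image",
    "normalize_orientation",
    "RasterFormatError",
]

_FORMATS = ("pgm", "png")
_MAX_PIXEL = 2**32 - 1


class RasterFormatError(ValueError):
    """Raised for malformed, multi-channel, or out-of-range raster data."""


def as_gray_image(data) -> np.ndarray:
    """Validate *data* as a grayscale image and return it as 2-D uint32.

    Accepts any integer array-like with nonnegative values below 2**32.
    """
    arr = np.asarray(data)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise RasterFormatError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise RasterFormatError("pixel values must be integers")
    a = np.asarray(arr, dtype=np.int64)
    if a.min() < 0 or a.max() > _MAX_PIXEL:
        raise RasterFormatError("pixel values must lie in [0, 2**32 - 1]")
    return a.astype(np.uint32)


def _check_format(fmt: str) -> str:
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
    return fmt


def read_gray_image(path, format: str | None = None) -> np.ndarray:
    """Read a single-channel PGM or PNG raster, values preserved verbatim.

    ``format`` defaults to the file extension.  Errors are reported
    distinctly: ``FileNotFoundError`` for a missing file,
    ``RasterFormatError`` with "not single-channel" for color input,
    ``RasterFormatError`` for a malformed header.
    """
    path = Path(path)
    fmt = _check_format(format or path.suffix.lstrip(".") or "pgm")
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.format not in ("PPM", "PGM", "PNG"):
                raise RasterFormatError(
                    f"malformed header: {path} is not a {fmt.upper()} file (got {im.format})"
                )
            if im.mode in ("L", "I;16", "I;16B", "I", "I;16N"):
                arr = np.asarray(im, dtype=np.int64)
            else:
                raise RasterFormatError(
                    f"not single-channel: {path} has mode {im.mode}; "
                    "only grayscale rasters are supported"
                )
    except UnidentifiedImageError as exc:
        raise RasterFormatError(f"malformed header in {path}: {exc}") from exc
    return as_gray_image(arr)


def write_gray_image(image, path, format: str | None = None, depth: int = 8) -> None:
    """Write *image* so that :func:`read_gray_image` recovers it exactly.

    ``depth`` is the stored sample depth (8 or 16); every pixel must fit.
    """
    image = as_gray_image(image)
    path = Path(path)
    fmt = _check_format(format or path.suffix.lstrip(".") or "pgm")
    if depth not in (8, 16):
        raise ValueError(f"depth must be 8 or 16, got {depth!r}")
    limit = (1 << depth) - 1
    peak = int(image.max())
    if peak > limit:
        raise RasterFormatError(
            f"pixel value {peak} exceeds the {depth}-bit range [0, {limit}]"
        )
    if depth == 8:
        im = Image.fromarray(image.astype(np.uint8), mode="L")
    else:
        im = Image.fromarray(image.astype(np.uint16))  # mode I;16
    parent = path.parent
    if parent and not parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {parent}")
    # atomic write: render to a sibling temp file, then rename into place
    tmp = path.with_name(path.name + ".tmp")
    im.save(tmp, format="PPM" if fmt == "pgm" else "PNG")
    os.replace(tmp, path)


def normalize_orientation(image, view: str) -> np.ndarray:
    """Map the image to the right-sided layout (breast at column 0).

    ``view="right"`` is the identity; ``view="left"`` mirrors horizontally
    (column c -> cols-1-c), which is an involution, so the same call with
    ``view="left"`` also maps a right-layout result back to the left view.
    """
    image = as_gray_image(image)
    if view == "right":
        return image.copy()
    if view == "left":
        return image[:, ::-1].copy()
    raise ValueError(f"view must be 'left' or 'right', got {view!r}")
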