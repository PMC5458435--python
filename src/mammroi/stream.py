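"""Single-pass raster-scan (streaming) segmentation kernels.

Each kernel consumes the image top-down, left-to-right, exactly once, and
keeps only one row of state: a *line buffer* holding the kernel's OUTPUT of
the previous row (the "above pixel"), plus the current row's leftmost run
of non-black pixels (the "first white" run, the breast's anchor in that
row).  Under the structural assumptions the phantom generator encodes —
breast anchored at the chest-wall edge, column-anchored growth, detached
artifacts — these one-pass kernels reproduce the whole-image reference
results bit-exactly; the pectoral kernel matches its reference on *all*
images, being the same recurrence written twice.

The background kernel K_A:

* row 0: a pixel survives iff it lies inside the first run of row 0;
* rows r >= 1: a pixel is zeroed iff it is outside the first run of row r
  AND the line-buffer value at its column is black (< B).

The pectoral kernel K_B, with R = max(1, floor(rows * pectoral_fraction)):

* rows r < R: a pixel is zeroed iff its value >= T;
* rows r >= R: a pixel is zeroed iff its value >= T AND the line-buffer
  value at its column is black.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .params import SegParams, resolve_threshold
from .raster_io import as_gray_image, normalize_orientation

__all__ = [
    "RowRun",
    "first_run_bounds",
    "kernel_background",
    "kernel_pectoral",
    "segment_stream",
    "process_batch",
    "MAX_STREAMS",
]

#: hard manager capacity: eight input and eight output streams
MAX_STREAMS = 8


class RowRun(NamedTuple):
    """Inclusive column bounds of a row's leftmost non-black run."""

    start: int
    end: int


def first_run_bounds(row: Sequence[int], black: int) -> Optional[RowRun]:
    """Leftmost maximal run of values >= ``black``, or None if the row is black."""
    row = np.asarray(row)
    if row.ndim != 1 or row.size == 0:
        raise ValueError("row must be a non-empty 1-D sequence")
    nz = np.flatnonzero(row >= black)
    if nz.size == 0:
        return None
    start = int(nz[0])
    # end of the contiguous stretch starting at `start`
    breaks = np.flatnonzero(np.diff(nz) > 1)
    end = int(nz[breaks[0]]) if breaks.size else int(nz[-1])
    return RowRun(start, end)


def _in_first_run_mask(row: np.ndarray, black: int) -> np.ndarray:
    run = first_run_bounds(row, black)
    mask = np.zeros(row.shape, dtype=bool)
    if run is not None:
        mask[run.start : run.end + 1] = True
    return mask


def _stream_background(rows: Iterable[np.ndarray], black: int) -> Iterator[np.ndarray]:
    """Row generator form of K_A; consumes each input row exactly once."""
    line_buffer: np.ndarray | None = None
    for r, row in enumerate(rows):
        row = np.asarray(row, dtype=np.uint32)
        in_run = _in_first_run_mask(row, black)
        if r == 0:
            out = np.where(in_run, row, np.uint32(0))
        else:
            above_black = line_buffer < black
            out = np.where(~in_run & above_black, np.uint32(0), row)
        line_buffer = out
        yield out


def _stream_pectoral(
    rows: Iterable[np.ndarray], black: int, threshold: int, boundary_row: int
) -> Iterator[np.ndarray]:
    """Row generator form of K_B."""
    line_buffer: np.ndarray | None = None
    for r, row in enumerate(rows):
        row = np.asarray(row, dtype=np.uint32)
        hot = row >= threshold
        if r < boundary_row:
            out = np.where(hot, np.uint32(0), row)
        else:
            out = np.where(hot & (line_buffer < black), np.uint32(0), row)
        line_buffer = out
        yield out


def kernel_background(image, params: SegParams | None = None) -> np.ndarray:
    """Streaming background-partition removal (kernel K_A)."""
    params = params or SegParams()
    image = as_gray_image(image)
    return np.stack(list(_stream_background(iter(image), params.black)))


def kernel_pectoral(image, params: SegParams | None = None) -> np.ndarray:
    """Streaming pectoral-muscle removal (kernel K_B)."""
    params = params or SegParams()
    image = as_gray_image(image)
    T = resolve_threshold(params, image)
    R = params.pectoral_rows(image.shape[0])
    return np.stack(list(_stream_pectoral(iter(image), params.black, T, R)))


def segment_stream(image, params: SegParams | None = None) -> np.ndarray:
    """Full streaming ROI extraction: K_A then K_B, with view handling."""
    params = params or SegParams()
    work = normalize_orientation(image, params.view)
    work = kernel_background(work, params)
    work = kernel_pectoral(work, params)
    return normalize_orientation(work, params.view)


def process_batch(images: Sequence, params: SegParams | None = None) -> list[np.ndarray]:
    """Segment up to eight images, emulating the eight-way manager.

    The dataflow engine exposes eight input and eight output streams, so the
    kernel graph is replicated at most eight times; a larger batch is a
    capacity error.  Images may differ in shape; results come back in input
    order and equal per-image :func:`segment_stream`.
    """
    images = list(images)
    if len(images) > MAX_STREAMS:
        raise ValueError(
            f"batch of {len(images)} images exceeds the manager capacity of "
            f"{MAX_STREAMS} (the engine is limited to eight input and eight "
            "output streams)"
        )
    return [segment_stream(im, params) for im in images]
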