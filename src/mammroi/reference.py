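"""Whole-image reference segmentation.

These are the plain, two-pass-friendly formulations of the two stages:

* background-partition removal — keep only the largest connected area of
  non-black pixels (labels, markers and scanner artifacts detach from the
  breast and are zeroed);
* pectoral-muscle removal — threshold the bright chest-wall wedge in the
  top rows and let the removal propagate down each column while the pixel
  above (in the processed output) is black.

They serve as oracles for the single-pass streaming kernels in
:mod:`mammroi.stream`, so the pectoral recurrence here is deliberately an
independent per-pixel Python loop rather than sharing code with the
vectorised kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import SegParams, resolve_threshold
from .raster_io import as_gray_image, normalize_orientation

__all__ = [
    "ComponentLabeling",
    "label_components",
    "remove_background_reference",
    "remove_pectoral_reference",
    "segment_reference",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected components of the non-black pixel set.

    ``labels`` is an int array of the image shape, 0 on black pixels and a
    positive component label elsewhere; labels are numbered 1, 2, ... in the
    raster order of each component's first pixel.  ``sizes`` maps each label
    to its pixel count.
    """

    labels: np.ndarray
    sizes: dict[int, int]

    @property
    def n_components(self) -> int:
        return len(self.sizes)


def label_components(image, params: SegParams | None = None) -> ComponentLabeling:
    """Label connected non-black (value >= B) regions.

    Connectivity (4 or 8) comes from ``params``; labels are renumbered so
    that component k is the k-th one encountered scanning rows top-down,
    left-to-right.
    """
    params = params or SegParams()
    image = as_gray_image(image)
    mask = image >= params.black
    structure = _STRUCT_4 if params.connectivity == 4 else _STRUCT_8
    raw, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return ComponentLabeling(labels=raw, sizes={})
    flat = raw.ravel()
    order = np.full(n + 1, -1, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first raster index of each raw label -> renumber in that order
    firsts = {}
    for idx in nz:
        lab = flat[idx]
        if lab not in firsts:
            firsts[int(lab)] = int(idx)
            if len(firsts) == n:
                break
    for new, (lab, _) in enumerate(sorted(firsts.items(), key=lambda kv: kv[1]), start=1):
        order[lab] = new
    labels = order[raw]
    labels[raw == 0] = 0
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    sizes = {k: int(counts[k]) for k in range(1, n + 1)}
    return ComponentLabeling(labels=labels.astype(np.int64), sizes=sizes)


def remove_background_reference(image, params: SegParams | None = None) -> np.ndarray:
    """Keep the largest connected non-black component; zero everything else.

    Ties between equal-size components go to the one whose first pixel comes
    earliest in raster order (which, by the labelling convention, is the one
    with the smallest label).  An all-black image stays all black.
    """
    params = params or SegParams()
    image = as_gray_image(image)
    lab = label_components(image, params)
    if not lab.sizes:
        return np.zeros_like(image)
    best_size = max(lab.sizes.values())
    keep = min(k for k, s in lab.sizes.items() if s == best_size)
    out = image.copy()
    out[lab.labels != keep] = 0
    return out


def remove_pectoral_reference(image, params: SegParams | None = None) -> np.ndarray:
    """Threshold the pectoral wedge and propagate removal down columns.

    With R = max(1, floor(rows * pectoral_fraction)), a pixel (r, c) is
    zeroed iff its value is >= T and either r < R or the already-processed
    output pixel directly above, (r-1, c), is black (< B).  Everything else
    passes through unchanged.  Computed as an explicit top-down per-pixel
    recurrence.
    """
    params = params or SegParams()
    image = as_gray_image(image)
    T = resolve_threshold(params, image)
    B = params.black
    rows, cols = image.shape
    R = params.pectoral_rows(rows)
    src = image.tolist()  # raw values drive the >= T test
    out = [row[:] for row in src]  # processed values drive the above test
    for r in range(rows):
        prev = out[r - 1] if r else None
        cur = out[r]
        for c in range(cols):
            if src[r][c] >= T and (r < R or prev[c] < B):
                cur[c] = 0
    return np.asarray(out, dtype=np.uint32)


def segment_reference(image, params: SegParams | None = None) -> np.ndarray:
    """Full reference ROI extraction: background removal then pectoral removal.

    Left-sided views are mirrored into the right-sided layout first and the
    result mirrored back, so one code path serves both views.
    """
    params = params or SegParams()
    work = normalize_orientation(image, params.view)
    work = remove_background_reference(work, params)
    work = remove_pectoral_reference(work, params)
    return normalize_orientation(work, params.view)
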