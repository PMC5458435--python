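"""Synthetic mammogram-like phantoms with ground-truth masks.

A phantom is the minimal geometry the streaming heuristic relies on, made
explicit: a breast rendered as a half-ellipse attached to the chest-wall
edge (column 0), a brighter pectoral wedge in the top-left corner whose
width shrinks with row index, and optional detached background artifacts
(markers, labels) strictly to the right of the breast.  The structural
invariants — the breast/pectoral union is one 4-connected region touching
column 0 in every row, each row's leftmost non-black run belongs to that
union, growth below a row is column-anchored, and the wedge is
column-anchored from its top row — are exactly the conditions under which
the single-pass kernels reproduce the whole-image reference segmentation,
and :func:`validate_phantom_structure` turns them into a testable contract.

Intensities are banded: breast tissue in ``[B, T)``, pectoral muscle in
``[T, ...)``, so the ground-truth ROI after segmentation is precisely the
breast mask.  Noise is added only inside the masks (clipped to each band),
keeping the background exactly 0 and "non-black" unambiguous for any B >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .params import SegParams
from .raster_io import write_gray_image
from .stream import first_run_bounds

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "validate_phantom_structure",
    "default_seg_params",
    "export_phantom",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom.  Intensity ranges are inclusive pairs.

    Defaults draw an 8-bit-like 256x256 image: breast band [30, 169],
    pectoral band [170, 255] (so T = 170 separates them), three small
    detached artifacts, and +/-10 intensity noise inside the masks.
    """

    rows: int = 256
    cols: int = 256
    breast_intensity_range: tuple[int, int] = (30, 169)
    pectoral_intensity_range: tuple[int, int] = (170, 255)
    n_artifacts: int = 3
    artifact_intensity_range: tuple[int, int] = (40, 255)
    noise_amplitude: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("breast_intensity_range", "pectoral_intensity_range", "artifact_intensity_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        if self.breast_intensity_range[1] >= self.pectoral_intensity_range[0]:
            raise ValueError(
                "breast intensities must stay strictly below the pectoral band "
                "(no threshold T could separate them otherwise)"
            )
        if self.n_artifacts < 0 or self.noise_amplitude < 0:
            raise ValueError("n_artifacts and noise_amplitude must be nonnegative")


@dataclass(frozen=True)
class Phantom:
    """A generated image with its ground-truth masks (pairwise disjoint)."""

    image: np.ndarray
    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    artifact_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def default_seg_params(spec: PhantomSpec, view: str = "right") -> SegParams:
    """SegParams under which the phantom's ROI is exactly its breast mask."""
    return SegParams(black=1, threshold=spec.pectoral_intensity_range[0], view=view)


def _banded_noise(rng, base: np.ndarray, lo: int, hi: int, amplitude: int) -> np.ndarray:
    if amplitude == 0:
        return base
    noisy = base.astype(np.int64) + rng.integers(-amplitude, amplitude + 1, size=base.shape)
    return np.clip(noisy, lo, hi)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically render the phantom described by *spec*.

    Requires rows >= 20 and cols >= 20 so every structure has room.
    """
    rows, cols = spec.rows, spec.cols
    if rows < 20 or cols < 20:
        raise ValueError(f"phantom needs rows >= 20 and cols >= 20, got {rows}x{cols}")
    rng = np.random.default_rng(spec.seed)

    # breast half-ellipse attached to column 0, occupying every row
    max_width = cols - 8 if spec.n_artifacts else cols - 1
    a = int(round(max_width * rng.uniform(0.7, 0.95)))
    cy = (rows - 1) / 2.0
    b = rows / 2.0 + 1.0  # slightly past the edges so no row degenerates
    rr = np.arange(rows)
    profile = np.sqrt(np.clip(1.0 - ((rr - cy) / b) ** 2, 0.0, None))
    breast_width = np.clip(np.round(a * profile).astype(int), 1, max_width)

    # pectoral wedge: right triangle at the top-left, width shrinking to 0
    pect_rows = max(3, rows // 4)
    pect_w0 = max(2, min(cols // 4, int(breast_width[:pect_rows].min())))
    wedge_width = np.ceil(pect_w0 * (pect_rows - np.arange(pect_rows)) / pect_rows).astype(int)

    pect = np.zeros((rows, cols), dtype=bool)
    for r in range(pect_rows):
        pect[r, : wedge_width[r]] = True
    breast = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        breast[r, : breast_width[r]] = True
    breast &= ~pect

    # detached artifacts: small discs strictly right of the breast, with at
    # least one all-black column between them and the breast/pectoral union
    artifact = np.zeros((rows, cols), dtype=bool)
    union_w = int(max(breast_width.max(), wedge_width.max() if pect_rows else 0))
    for _ in range(spec.n_artifacts):
        radius = int(rng.integers(1, 3))
        c_lo, c_hi = union_w + 1 + radius, cols - 1 - radius
        if c_lo > c_hi:
            break  # no room; fewer artifacts than requested
        cr = int(rng.integers(radius, rows - radius))
        cc = int(rng.integers(c_lo, c_hi + 1))
        yy, xx = np.ogrid[:rows, :cols]
        artifact |= (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2

    image = np.zeros((rows, cols), dtype=np.int64)
    for mask, band in (
        (breast, spec.breast_intensity_range),
        (pect, spec.pectoral_intensity_range),
        (artifact, spec.artifact_intensity_range),
    ):
        n = int(mask.sum())
        if n:
            base = rng.integers(band[0], band[1] + 1, size=n)
            image[mask] = _banded_noise(rng, base, band[0], band[1], spec.noise_amplitude)

    return Phantom(
        image=image.astype(np.uint32),
        breast_mask=breast,
        pectoral_mask=pect,
        artifact_mask=artifact,
    )


def validate_phantom_structure(phantom: Phantom, params: SegParams) -> bool:
    """Pure check of every structural invariant for the given B and T.

    Returns True iff the phantom satisfies all of them; raises only on a
    mask/image shape mismatch.  T must be concrete in ``params``.
    """
    img = phantom.image
    breast, pect, art = phantom.breast_mask, phantom.pectoral_mask, phantom.artifact_mask
    for m in (breast, pect, art):
        if m.shape != img.shape:
            raise ValueError(f"mask shape {m.shape} does not match image shape {img.shape}")
    B = params.black
    T = params.threshold
    if T is None:
        raise ValueError("validation needs a concrete threshold T")

    # disjointness and exact-zero background
    if np.any(breast & pect) or np.any(breast & art) or np.any(pect & art):
        return False
    if np.any(img[~(breast | pect | art)] != 0):
        return False

    # intensity bands relative to B and T
    if np.any(img[breast] < B) or np.any(img[breast] >= T):
        return False
    if np.any(img[pect] < T):
        return False
    if np.any(img[art] < B):
        return False

    union = breast | pect
    if union.any():
        _, n = ndimage.label(union, structure=_STRUCT_4)
        if n != 1:
            return False
        occupied = union.any(axis=1)
        if not union[occupied, 0].all():
            return False

    # per-row first-run and column-anchoring conditions
    rows = img.shape[0]
    nonblack = img >= B
    for r in range(rows):
        if not nonblack[r].any():
            continue
        run = first_run_bounds(img[r], B)
        if not union[r, run.start : run.end + 1].all():
            return False
        outside = union[r].copy()
        outside[run.start : run.end + 1] = False
        if outside.any():
            if r == 0 or not union[r - 1][outside].all():
                return False

    # pectoral wedge: contiguous prefix runs from column 0, anchored row-on-row
    pect_rows = np.flatnonzero(pect.any(axis=1))
    if pect_rows.size:
        if np.any(np.diff(pect_rows) != 1):
            return False
        top = pect_rows[0]
        for r in pect_rows:
            w = int(pect[r].sum())
            if not pect[r, :w].all():  # must be a prefix of columns
                return False
            if r > top and not pect[r - 1, :w].all():
                return False
    return True


def export_phantom(
    phantom: Phantom, directory, stem: str = "phantom", format: str = "pgm", depth: int = 8
) -> dict[str, Path]:
    """Write the image and its three masks as paired raster files.

    Masks are stored as 0/1 images.  Returns the written paths keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    items = {
        "image": phantom.image,
        "breast_mask": phantom.breast_mask.astype(np.uint32),
        "pectoral_mask": phantom.pectoral_mask.astype(np.uint32),
        "artifact_mask": phantom.artifact_mask.astype(np.uint32),
    }
    for role, data in items.items():
        path = directory / f"{stem}_{role}.{format}"
        write_gray_image(data, path, format=format, depth=depth)
        paths[role] = path
    return paths
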