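"""Segmentation parameters shared by every engine.

Two scalars drive the whole pipeline: ``black`` (B) separates background
from tissue — a pixel is *non-black* iff its value is >= B — and
``threshold`` (T) marks pectoral-muscle intensity.  Both are absolute pixel
values on whatever scale the input image uses; no rescaling is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

__all__ = ["SegParams", "resolve_threshold"]

_VIEWS = ("left", "right")


@dataclass(frozen=True)
class SegParams:
    """Parameters of the ROI segmentation.

    Parameters
    ----------
    black : int
        Black level B >= 1.  A pixel is non-black iff ``value >= black``.
    threshold : int or None
        Pectoral threshold T >= 1.  ``None`` means "resolve per image" to
        70% of the image maximum (a starting point, not a calibrated value).
    pectoral_fraction : float or Fraction
        Fraction of the top rows in which thresholding applies
        unconditionally; the boundary row count is
        ``max(1, floor(rows * pectoral_fraction))``.
    connectivity : {4, 8}
        Pixel adjacency used for background connected components.
    view : {"left", "right"}
        Which side the breast touches.  Left-sided views are mirrored to the
        right-sided layout before segmentation and mirrored back after.
    """

    black: int = 1
    threshold: int | None = None
    pectoral_fraction: float | Fraction = Fraction(1, 10)
    connectivity: int = 4
    view: str = "right"

    def __post_init__(self) -> None:
        if int(self.black) != self.black or self.black < 1:
            raise ValueError(f"black level must be an integer >= 1, got {self.black!r}")
        if self.threshold is not None and (
            int(self.threshold) != self.threshold or self.threshold < 1
        ):
            raise ValueError(f"threshold must be an integer >= 1, got {self.threshold!r}")
        frac = self.fraction
        if not (0 < frac <= 1):
            raise ValueError(f"pectoral_fraction must lie in (0, 1], got {self.pectoral_fraction!r}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity!r}")
        if self.view not in _VIEWS:
            raise ValueError(f"view must be one of {_VIEWS}, got {self.view!r}")

    @property
    def fraction(self) -> Fraction:
        """``pectoral_fraction`` as an exact rational (floats are snapped)."""
        f = self.pectoral_fraction
        if isinstance(f, Fraction):
            return f
        return Fraction(f).limit_denominator(1_000_000)

    def pectoral_rows(self, rows: int) -> int:
        """Boundary row count R = max(1, floor(rows * fraction))."""
        return max(1, int(rows * self.fraction))

    def with_(self, **changes) -> "SegParams":
        return replace(self, **changes)


def resolve_threshold(params: SegParams, image) -> int:
    """Concrete T for *image*: the given one, else 70% of the image max.

    An all-black image resolves to T=1 (nothing reaches it anyway).
    """
    if params.threshold is not None:
        return int(params.threshold)
    peak = int(image.max()) if image.size else 0
    return max(1, (7 * peak) // 10)
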