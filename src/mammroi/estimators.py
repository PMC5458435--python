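"""scikit-learn style transformers for the ROI segmentation stages.

Each transformer is stateless (no parameters are learned from data): ``fit``
validates parameters and records the input shape, ``transform`` maps a
grayscale image — a 2-D integer array — to the segmented image of the same
shape.  The ``engine`` parameter selects among the three interchangeable
implementations:

``"reference"``
    whole-image formulation (connected components / whole-row recurrence);
``"stream"``
    single-pass raster-scan kernels with a one-row line buffer;
``"graph"``
    tick-per-pixel evaluation of the explicit dataflow graphs.

On images satisfying the phantom structural contract the three engines are
bit-identical; the pectoral stage is identical on all images.  Being
standard transformers they compose with :class:`sklearn.pipeline.Pipeline`
— ``ROISegmenter`` is in fact equivalent to
``Pipeline([("background", BackgroundRemover(...)), ("pectoral",
PectoralRemover(...))])`` wrapped in view normalization.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import graph as _graph
from . import reference as _ref
from . import stream as _stream
from .params import SegParams
from .raster_io import as_gray_image, normalize_orientation

__all__ = ["BackgroundRemover", "PectoralRemover", "ROISegmenter"]

_ENGINES = ("reference", "stream", "graph")


class _SegTransformer(TransformerMixin, BaseEstimator):
    """Shared machinery: parameter plumbing and engine dispatch."""

    def _seg_params(self) -> SegParams:
        raise NotImplementedError

    def _check_engine(self) -> str:
        if self.engine not in _ENGINES:
            raise ValueError(f"engine must be one of {_ENGINES}, got {self.engine!r}")
        return self.engine

    def fit(self, X, y=None):
        """Validate parameters against one image; returns self."""
        X = as_gray_image(X)
        self._check_engine()
        self._seg_params()  # raises on bad parameter values
        self.n_rows_, self.n_cols_ = X.shape
        return self

    def transform(self, X) -> np.ndarray:
        X = as_gray_image(X)
        self._check_engine()
        return self._apply(X, self._seg_params())

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def _apply(self, X: np.ndarray, params: SegParams) -> np.ndarray:
        raise NotImplementedError


class BackgroundRemover(_SegTransformer):
    """Remove everything but the largest connected non-black region.

    Parameters
    ----------
    black : int, default 1
        Black level B; a pixel is non-black iff value >= B.
    connectivity : {4, 8}, default 4
        Adjacency for the reference connected-component engine.
    engine : {"reference", "stream", "graph"}, default "stream"
    """

    def __init__(self, black: int = 1, connectivity: int = 4, engine: str = "stream"):
        self.black = black
        self.connectivity = connectivity
        self.engine = engine

    def _seg_params(self) -> SegParams:
        return SegParams(black=self.black, connectivity=self.connectivity)

    def _apply(self, X, params):
        if self.engine == "reference":
            return _ref.remove_background_reference(X, params)
        if self.engine == "stream":
            return _stream.kernel_background(X, params)
        return _graph.run_graph_on_image("background", X, params)


class PectoralRemover(_SegTransformer):
    """Remove the bright pectoral wedge by banded thresholding + propagation.

    Parameters
    ----------
    threshold : int or None, default None
        Pectoral threshold T; None resolves per image to 70% of its maximum.
    black : int, default 1
    pectoral_fraction : float, default 0.1
        Top fraction of rows where >= T alone removes a pixel.
    engine : {"reference", "stream", "graph"}, default "stream"
    """

    def __init__(
        self,
        threshold: int | None = None,
        black: int = 1,
        pectoral_fraction: float = 0.1,
        engine: str = "stream",
    ):
        self.threshold = threshold
        self.black = black
        self.pectoral_fraction = pectoral_fraction
        self.engine = engine

    def _seg_params(self) -> SegParams:
        return SegParams(
            black=self.black, threshold=self.threshold, pectoral_fraction=self.pectoral_fraction
        )

    def _apply(self, X, params):
        if self.engine == "reference":
            return _ref.remove_pectoral_reference(X, params)
        if self.engine == "stream":
            return _stream.kernel_pectoral(X, params)
        return _graph.run_graph_on_image("pectoral", X, params)


class ROISegmenter(_SegTransformer):
    """Full ROI extraction: background removal followed by pectoral removal.

    ``view="left"`` mirrors the image into the right-sided layout before the
    stages and mirrors the result back.
    """

    def __init__(
        self,
        black: int = 1,
        threshold: int | None = None,
        pectoral_fraction: float = 0.1,
        connectivity: int = 4,
        view: str = "right",
        engine: str = "stream",
    ):
        self.black = black
        self.threshold = threshold
        self.pectoral_fraction = pectoral_fraction
        self.connectivity = connectivity
        self.view = view
        self.engine = engine

    def _seg_params(self) -> SegParams:
        return SegParams(
            black=self.black,
            threshold=self.threshold,
            pectoral_fraction=self.pectoral_fraction,
            connectivity=self.connectivity,
            view=self.view,
        )

    def _apply(self, X, params):
        work = normalize_orientation(X, params.view)
        bg = BackgroundRemover(
            black=self.black, connectivity=self.connectivity, engine=self.engine
        )
        pm = PectoralRemover(
            threshold=self.threshold,
            black=self.black,
            pectoral_fraction=self.pectoral_fraction,
            engine=self.engine,
        )
        work = pm.fit_transform(bg.fit_transform(work))
        return normalize_orientation(work, params.view)
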