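"""Calibrated raster containers shared by every stage of the pipeline.

An :class:`Image2D` couples an intensity raster to its physical pixel size so
that downstream morphometry can report lengths in µm and areas in µm² without
threading calibration constants through every call.  A :class:`LabelMask` is
an integer raster over the same grid: 0 is background, ``k > 0`` is object
``k``, and after :meth:`LabelMask.relabeled` the label set is contiguous
``1..K`` ordered by raster position of the object centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi


class PipelineError(Exception):
    """Base class for errors raised by the pipeline."""


class ParameterError(PipelineError, ValueError):
    """A parameter violates its documented constraint."""


class DimensionError(PipelineError, ValueError):
    """Rasters that must share a grid do not."""


@dataclass(frozen=True)
class Image2D:
    """A 2D intensity image with physical calibration.

    Parameters
    ----------
    pixels
        Non-negative float raster of shape ``(rows, cols)``.
    pixel_size
        Edge length of one pixel in µm; must be positive.
    channel
        Free-form channel name (``"egfp"``, ``"tmrm"``, ...).
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise DimensionError(f"Image2D requires a 2D raster, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ParameterError("Image2D pixels must be finite")
        if not self.pixel_size > 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size**2

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled segmentation sharing shape and calibration with its source."""

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise DimensionError(f"LabelMask requires a 2D raster, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise ParameterError("labels must be non-negative")
        if not self.pixel_size > 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids.size)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def relabeled(self) -> "LabelMask":
        """Return a copy with contiguous labels 1..K in raster order of centroids."""
        ids = self.label_ids
        if ids.size == 0:
            return self
        cents = ndi.center_of_mass(np.ones(self.shape), self.labels, ids)
        order = np.lexsort((np.array([c[1] for c in cents]), np.array([c[0] for c in cents])))
        lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
        for new, idx in enumerate(order, start=1):
            lut[ids[idx]] = new
        return LabelMask(lut[self.labels], self.pixel_size)


def require_same_grid(a, b, what: str = "inputs") -> None:
    """Raise :class:`DimensionError` unless two rasters share shape and pixel size."""
    if a.shape != b.shape:
        raise DimensionError(f"{what} must share shape: {a.shape} vs {b.shape}")
    pa = getattr(a, "pixel_size", None)
    pb = getattr(b, "pixel_size", None)
    if pa is not None and pb is not None and not np.isclose(pa, pb):
        raise DimensionError(f"{what} must share pixel size: {pa} vs {pb}")
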