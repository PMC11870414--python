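"""Preprocessing, blob detection, EQ-image construction and watershed segmentation.

The segmentation strategy follows standard single-cell fluorescence
practice: cell bodies (or nuclei) are found by Gaussian blurring and
thresholding with size/roundness exclusion, and serve as seeds for a
marker-controlled watershed over an intensity terrain — either the raw
cytoplasmic channel or an enhanced-contrast "EQ" image built by
histogram-equalizing two channels to [0, 1] and summing them pixelwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_hist
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion
from skimage.segmentation import watershed

from .core import DimensionError, Image2D, LabelMask, ParameterError, require_same_grid

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BlobParams:
    """Detection parameters for cell bodies or nuclei.

    Areas are physical (µm²); ``min_roundness`` filters on circularity
    ``4 * pi * A / P **2``.  Defaults suit iMN somata at 20x; nuclei
    detection typically narrows the area band (see :func:`nuclei_params`).
    """

    blur_sigma: float = 2.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area_um2: float = 20.0
    max_area_um2: float = 400.0
    min_roundness: float = 0.5
    open_radius_px: int = 0  # grey opening before blurring; erases thin neurites

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ParameterError("blur_sigma must be >= 0")
        if self.open_radius_px < 0:
            raise ParameterError("open_radius_px must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ParameterError("fixed thresholding needs threshold_value")
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ParameterError("need 0 < min_area < max_area")
        if not 0.0 <= self.min_roundness <= 1.0:
            raise ParameterError("min_roundness must be in [0, 1]")


def soma_params(**overrides) -> BlobParams:
    """Default soma detection: 20-400 µm², roundness >= 0.5."""
    return BlobParams(**overrides)


def nuclei_params(**overrides) -> BlobParams:
    """Default nuclei detection: 20-250 µm²."""
    kw = dict(max_area_um2=250.0)
    kw.update(overrides)
    return BlobParams(**kw)


def candidate_params(**overrides) -> BlobParams:
    """Permissive detection used upstream of classification.

    Classification must see every cell body — including large flat
    non-neurons and small condensed dead cells — so the area band is wide
    and the roundness gate low; the classifier applies the strict criteria.
    The grey opening detaches cell bodies from their thin neurites so a
    soma is detected as one round blob rather than a soma-plus-arbor shape.
    """
    kw = dict(min_area_um2=10.0, max_area_um2=2000.0, min_roundness=0.2, open_radius_px=2)
    kw.update(overrides)
    return BlobParams(**kw)


def subtract_background(img: Image2D, radius: int = 50, smooth_sigma: float = 4.0) -> Image2D:
    """Rolling-ball-style background removal via morphological opening.

    The background estimate is a grey opening (disk of ``radius``) of a
    lightly smoothed copy — smoothing keeps the erosion from chasing noise
    minima — and is subtracted from the original image.  A flat image maps
    to (near-)zero; objects much smaller than ``radius`` pass through
    essentially unchanged.
    """
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    if 2 * radius + 1 > min(img.shape):
        raise ParameterError(
            f"background radius {radius} px exceeds image extent {img.shape}"
        )
    smoothed = ndi.gaussian_filter(img.pixels, smooth_sigma) if smooth_sigma > 0 else img.pixels
    footprint = disk(radius, decomposition="sequence")
    background = dilation(erosion(smoothed, footprint), footprint)
    return img.with_pixels(np.clip(img.pixels - background, 0.0, None))


def detect_blobs(img: Image2D, p: BlobParams) -> LabelMask:
    """Blur, threshold and size/roundness-filter bright blobs.

    Returns a mask with contiguous labels in raster order of centroids.
    An all-flat image yields an empty mask.
    """
    work = img.pixels
    if p.open_radius_px > 0:
        work = ndi.grey_opening(work, footprint=disk(p.open_radius_px))
    blurred = ndi.gaussian_filter(work, p.blur_sigma) if p.blur_sigma > 0 else work
    if p.threshold_method == "fixed":
        thr = float(p.threshold_value)  # type: ignore[arg-type]
    else:
        if np.ptp(blurred) == 0:
            return LabelMask(np.zeros(img.shape, dtype=np.int32), img.pixel_size)
        thr = float(threshold_otsu(blurred))
    binary = blurred > thr
    labels, _ = ndi.label(binary, structure=_EIGHT)
    if labels.max() == 0:
        return LabelMask(labels.astype(np.int32), img.pixel_size)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    area_scale = img.pixel_area
    for rp in regionprops(labels):
        area = rp.area * area_scale
        if not p.min_area_um2 <= area <= p.max_area_um2:
            continue
        perim = rp.perimeter_crofton
        roundness = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 1.0
        if roundness < p.min_roundness:
            continue
        keep[rp.label] = True
    filtered = np.where(keep[labels], labels, 0).astype(np.int32)
    return LabelMask(filtered, img.pixel_size).relabeled()


def make_eq_image(chan_a: Image2D, chan_b: Image2D, nbins: int = 256) -> Image2D:
    """Enhanced-contrast image: equalize both channels to [0, 1] and sum.

    Symmetric in its arguments; output values lie in [0, 2].
    """
    require_same_grid(chan_a, chan_b, "EQ channels")
    eq = equalize_hist(chan_a.pixels, nbins=nbins) + equalize_hist(chan_b.pixels, nbins=nbins)
    return Image2D(eq, pixel_size=chan_a.pixel_size, channel="eq")


def segment_cells_watershed(
    seeds: LabelMask, terrain: Image2D, fg_threshold: float
) -> LabelMask:
    """Marker-controlled watershed partitioning the foreground among seeds.

    Foreground is ``terrain >= fg_threshold``; each seed claims one region
    and regions are disjoint.  A seed entirely outside the foreground still
    yields a region (its own pixels) and is logged.
    """
    require_same_grid(seeds, terrain, "seeds and terrain")
    if seeds.n_labels == 0:
        raise ParameterError("watershed needs at least one seed")
    fg = terrain.pixels >= fg_threshold
    seed_px = seeds.labels > 0
    orphan = [
        int(l) for l in seeds.label_ids if not np.any(fg[seeds.labels == l])
    ]
    if orphan:
        log.warning("seeds outside foreground keep only their own pixels: %s", orphan)
    mask = fg | seed_px
    regions = watershed(-terrain.pixels, markers=seeds.labels, mask=mask, connectivity=2)
    return LabelMask(regions.astype(np.int32), terrain.pixel_size)


@dataclass
class NucleusPairing:
    """Result of matching nuclei to watershed cell regions."""

    nucleus_to_cell: dict  # nucleus label -> cell label
    unpaired_nuclei: tuple
    multi_nucleus_cells: tuple  # cell labels claimed by >= 2 nuclei


def pair_nuclei_to_cells(nuclei: LabelMask, cells: LabelMask) -> NucleusPairing:
    """Assign each nucleus to the cell with maximal pixel overlap."""
    if nuclei.shape != cells.shape:
        raise DimensionError(f"masks must share shape: {nuclei.shape} vs {cells.shape}")
    mapping: dict = {}
    unpaired = []
    n_max = int(cells.labels.max()) + 1
    for nl in nuclei.label_ids:
        overlap = cells.labels[nuclei.labels == nl]
        counts = np.bincount(overlap[overlap > 0], minlength=n_max)
        if counts.sum() == 0:
            unpaired.append(int(nl))
            continue
        mapping[int(nl)] = int(np.argmax(counts))
    seen: dict = {}
    multi = set()
    for nl, cl in mapping.items():
        if cl in seen:
            multi.add(cl)
        seen[cl] = nl
    return NucleusPairing(
        nucleus_to_cell=mapping,
        unpaired_nuclei=tuple(unpaired),
        multi_nucleus_cells=tuple(sorted(multi)),
    )
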