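"""Morphology-feature classification of segmented cells.

Each candidate cell body is centre-cropped and classified as ``iMN``,
``non_neuron`` or ``dead`` from interpretable morphological features — the
same cues a trained image classifier would exploit: an iMN is a small,
bright, round soma with attached neurites; a dead cell is a small
condensed body without processes; everything else (large, flat, elongated,
or round-but-neurite-less) is a non-neuron.

The classifier is pluggable: anything implementing
:class:`CellClassifier` (crops in, class labels out) can replace the
default rule-based :class:`MorphologyClassifier` without changes elsewhere
in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.measure import regionprops

from .core import Image2D, ParameterError, PipelineError
from .morphometry import measure_neurites, skeletonize_cell
from .synth.scene import CLASS_DEAD, CLASS_IMN, CLASS_NON_NEURON

DEFAULT_CROP_SIDE = 128


@dataclass
class CellCrop:
    """A patch centred on one cell-body centroid, with its masks.

    Out-of-image area is zero-padded; the crop is centred within 1 px of
    the requested centroid.
    """

    cell_id: int
    image: np.ndarray
    soma_mask: np.ndarray
    cell_mask: np.ndarray
    pixel_size: float
    center: tuple[float, float]  # (row, col) in the source image


def crop_cell(
    img: Image2D,
    soma_labels: np.ndarray,
    cell_labels: np.ndarray,
    cell_id: int,
    center: tuple[float, float],
    side: int = DEFAULT_CROP_SIDE,
) -> CellCrop:
    """Centre-crop the image and this cell's masks to a ``side`` px patch."""
    r0 = int(round(center[0])) - side // 2
    c0 = int(round(center[1])) - side // 2
    out_img = np.zeros((side, side), dtype=np.float64)
    out_soma = np.zeros((side, side), dtype=bool)
    out_cell = np.zeros((side, side), dtype=bool)
    rows, cols = img.shape
    rlo, rhi = max(r0, 0), min(r0 + side, rows)
    clo, chi = max(c0, 0), min(c0 + side, cols)
    if rlo < rhi and clo < chi:
        dst = (slice(rlo - r0, rhi - r0), slice(clo - c0, chi - c0))
        src = (slice(rlo, rhi), slice(clo, chi))
        out_img[dst] = img.pixels[src]
        out_soma[dst] = soma_labels[src] == cell_id
        out_cell[dst] = cell_labels[src] == cell_id
    return CellCrop(
        cell_id=cell_id,
        image=out_img,
        soma_mask=out_soma,
        cell_mask=out_cell,
        pixel_size=img.pixel_size,
        center=(float(center[0]), float(center[1])),
    )


@dataclass(frozen=True)
class CellFeatures:
    """Interpretable per-cell morphology features."""

    cell_id: int
    soma_area_um2: float
    soma_roundness: float
    soma_mean_intensity: float
    eccentricity: float
    has_neurites: bool
    skeleton_length_um: float

    def __post_init__(self) -> None:
        for name in ("soma_area_um2", "soma_roundness", "soma_mean_intensity", "eccentricity"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"feature {name} must be finite")


@dataclass(frozen=True)
class ClassifierRules:
    """Thresholds of the default rule-based classifier.

    An iMN must have a soma in the stated area band, roundness at or above
    the gate, and at least ``imn_min_skeleton_um`` of attached skeleton
    outside the soma.  A cell below ``dead_max_area_um2`` without neurites
    is dead; the neurite flag breaks the tie for small neurite-bearing
    cells in favour of iMN.
    """

    imn_min_area_um2: float = 30.0
    imn_max_area_um2: float = 300.0
    imn_min_roundness: float = 0.7
    imn_min_skeleton_um: float = 20.0
    dead_max_area_um2: float = 40.0

    def __post_init__(self) -> None:
        vals = (
            self.imn_min_area_um2,
            self.imn_max_area_um2,
            self.imn_min_roundness,
            self.imn_min_skeleton_um,
            self.dead_max_area_um2,
        )
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ParameterError("classifier rules incomplete: all thresholds required")
        if not self.imn_min_area_um2 < self.imn_max_area_um2:
            raise ParameterError("need imn_min_area < imn_max_area")


def extract_features(
    crop: CellCrop, skeleton_prune_px: float = 5.0, neurite_min_um: float = 20.0
) -> CellFeatures:
    """Compute morphology features on the masked pixels of one crop.

    ``neurite_min_um`` sets the attached-skeleton length at which the
    neurite-presence flag turns on; classification re-derives the flag from
    its own rules so the two stay consistent when rules are customized.
    """
    if not crop.soma_mask.any():
        raise PipelineError(f"cell {crop.cell_id}: empty soma mask in crop")
    rp = regionprops(crop.soma_mask.astype(np.uint8))[0]
    px = crop.pixel_size
    area = rp.area * px**2
    perim = rp.perimeter_crofton  # Crofton estimate: unbiased for discs
    roundness = min(1.0, 4.0 * np.pi * rp.area / perim**2) if perim > 0 else 1.0
    mean_int = float(crop.image[crop.soma_mask].mean())
    skel_len = 0.0
    mask = crop.cell_mask if crop.cell_mask.any() else crop.soma_mask
    skel = skeletonize_cell(mask, px, prune_px=skeleton_prune_px)
    nm = measure_neurites(skel, crop.soma_mask, px)
    skel_len = nm.total_length_um
    return CellFeatures(
        cell_id=crop.cell_id,
        soma_area_um2=float(area),
        soma_roundness=float(roundness),
        soma_mean_intensity=mean_int,
        eccentricity=float(rp.eccentricity),
        has_neurites=bool(skel_len >= neurite_min_um),
        skeleton_length_um=float(skel_len),
    )


def classify_features(features: Sequence[CellFeatures], rules: ClassifierRules) -> list:
    """Pure function features -> classes; one label per input."""
    out = []
    for f in features:
        has_neurites = f.skeleton_length_um >= rules.imn_min_skeleton_um
        small_round = (
            rules.imn_min_area_um2 <= f.soma_area_um2 <= rules.imn_max_area_um2
            and f.soma_roundness >= rules.imn_min_roundness
        )
        if has_neurites and small_round:
            out.append(CLASS_IMN)
        elif not has_neurites and f.soma_area_um2 < rules.dead_max_area_um2:
            out.append(CLASS_DEAD)
        else:
            out.append(CLASS_NON_NEURON)
    return out


@runtime_checkable
class CellClassifier(Protocol):
    """Contract: centre-cropped cells in, one class label per crop out."""

    def classify(self, crops: Sequence[CellCrop]) -> list: ...


@dataclass
class MorphologyClassifier:
    """Default deterministic classifier: features + threshold rules."""

    rules: ClassifierRules = ClassifierRules()

    def classify(self, crops: Sequence[CellCrop]) -> list:
        feats = [extract_features(c) for c in crops]
        return classify_features(feats, self.rules)


def transformation_efficiency(classes: Sequence[str]) -> float:
    """Fraction of classified cells that are iMN, in [0, 1]."""
    if len(classes) == 0:
        raise ParameterError("transformation efficiency undefined for zero cells")
    return sum(1 for c in classes if c == CLASS_IMN) / len(classes)
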