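"""End-to-end orchestration: phenotyping and survival runs.

``run_phenotyping`` chains soma/nuclei detection, watershed single-cell
segmentation, morphology classification, and the per-cell measurements
(neurites, TDP-43 localization, mitochondria) into one table with a
transformation-efficiency summary.  ``run_survival`` applies the same
detect-and-classify front end to every frame of one movie per group, links
detections into tracks, converts tracks to censored lifelines, and fits
Kaplan-Meier curves, pairwise logrank tests and a Cox model.

Both runs are deterministic given config and seed, and never drop cells
silently: exclusions are counted with reasons in the QC block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .bioenergetics import compute_flux_stages, stages_table
from .classify import (
    ClassifierRules,
    MorphologyClassifier,
    crop_cell,
    extract_features,
    classify_features,
    transformation_efficiency,
)
from .core import Image2D, LabelMask, ParameterError, PipelineError
from .image_ops import (
    BlobParams,
    candidate_params,
    detect_blobs,
    nuclei_params,
    pair_nuclei_to_cells,
    segment_cells_watershed,
)
from .mitochondria import measure_mito_morphology, segment_mitochondria
from .morphometry import measure_neurites, measure_tdp43_localization, skeletonize_cell
from .survival import (
    Detection,
    fit_cox,
    fit_km,
    link_detections,
    logrank_pairwise,
    sample_lifelines,
    tracks_to_lifelines,
)
from .synth.scene import CLASS_IMN, SceneSpec, generate_static_scene

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_PER_GROUP = 500


@dataclass
class SegmentationResult:
    """Front-end output shared by phenotyping and survival runs."""

    somas: LabelMask
    cells: LabelMask
    centroids: dict  # label -> (row, col)
    classes: dict  # label -> class
    features: dict  # label -> CellFeatures


def detect_and_classify(
    egfp: Image2D,
    detection: BlobParams | None = None,
    rules: ClassifierRules | None = None,
    crop_side: int = 128,
    terrain_sigma: float = 2.0,
) -> SegmentationResult:
    """Detect cell bodies, watershed single cells, classify each cell."""
    detection = detection if detection is not None else candidate_params()
    rules = rules if rules is not None else ClassifierRules()
    somas = detect_blobs(egfp, detection)
    if somas.n_labels == 0:
        return SegmentationResult(somas, somas, {}, {}, {})
    blurred = ndi.gaussian_filter(egfp.pixels, terrain_sigma)
    terrain = Image2D(blurred, pixel_size=egfp.pixel_size, channel="terrain")
    from skimage.filters import threshold_otsu

    fg_thr = float(threshold_otsu(blurred))
    cells = segment_cells_watershed(somas, terrain, fg_thr)
    cents = ndi.center_of_mass(np.ones(somas.shape), somas.labels, somas.label_ids)
    centroids = {int(l): c for l, c in zip(somas.label_ids, cents)}
    crops = [
        crop_cell(egfp, somas.labels, cells.labels, int(l), centroids[int(l)], side=crop_side)
        for l in somas.label_ids
    ]
    feats = [extract_features(c, neurite_min_um=rules.imn_min_skeleton_um) for c in crops]
    classes = classify_features(feats, rules)
    return SegmentationResult(
        somas=somas,
        cells=cells,
        centroids=centroids,
        classes={int(l): cl for l, cl in zip(somas.label_ids, classes)},
        features={int(l): f for l, f in zip(somas.label_ids, feats)},
    )


@dataclass
class PhenotypeResult:
    table: pd.DataFrame
    summary: dict
    segmentation: SegmentationResult


def run_phenotyping(
    channels: dict | None = None,
    scene: SceneSpec | None = None,
    detection: BlobParams | None = None,
    rules: ClassifierRules | None = None,
    measure_tdp43: bool = True,
    measure_mito: bool = True,
    crop_side: int = 128,
) -> PhenotypeResult:
    """Static-scene phenotyping: one row per segmented cell.

    Exactly one of ``channels`` (name -> :class:`Image2D`) or ``scene``
    (synthetic spec) must be given.
    """
    if (channels is None) == (scene is None):
        raise ParameterError("provide exactly one of channels or scene")
    if scene is not None:
        channels, _truth = generate_static_scene(scene)
    assert channels is not None
    if "egfp" not in channels:
        raise PipelineError("phenotyping requires an 'egfp' channel")
    if measure_tdp43 and "tdp43" in channels and "nuclei" not in channels:
        raise PipelineError("TDP-43 metrics requested but channel 'nuclei' is missing")

    egfp = channels["egfp"]
    seg = detect_and_classify(egfp, detection=detection, rules=rules, crop_side=crop_side)
    if seg.somas.n_labels == 0:
        raise PipelineError("no cells detected in the scene")

    pairing = None
    nucleus_of_cell: dict = {}
    if "nuclei" in channels:
        nuclei_mask = detect_blobs(
            channels["nuclei"], nuclei_params(min_area_um2=5.0)
        )
        pairing = pair_nuclei_to_cells(nuclei_mask, seg.cells)
        for nl, cl in pairing.nucleus_to_cell.items():
            nucleus_of_cell.setdefault(cl, nl)

    rows = []
    px = egfp.pixel_size
    for label in sorted(seg.classes):
        f = seg.features[label]
        cls = seg.classes[label]
        row = {
            "cell_id": label,
            "class": cls,
            "centroid_row": seg.centroids[label][0],
            "centroid_col": seg.centroids[label][1],
            "soma_area_um2": f.soma_area_um2,
            "soma_roundness": f.soma_roundness,
            "soma_mean_intensity": f.soma_mean_intensity,
            "eccentricity": f.eccentricity,
            "skeleton_length_um": f.skeleton_length_um,
        }
        if cls == CLASS_IMN:
            cell_mask = seg.cells.mask_of(label)
            soma_mask = seg.somas.mask_of(label)
            skel = skeletonize_cell(cell_mask, px)
            nm = measure_neurites(skel, soma_mask, px)
            row["neurite_length_um"] = nm.total_length_um
            row["branch_count"] = nm.branch_count
            if measure_tdp43 and "tdp43" in channels and label in nucleus_of_cell:
                nuc = nuclei_mask.mask_of(nucleus_of_cell[label])
                tdp = measure_tdp43_localization(channels["tdp43"], nuc, cell_mask)
                row["tdp43_nuc"] = tdp.nuclear_mean
                row["tdp43_cyt"] = tdp.cytosolic_mean
                row["tdp43_ratio"] = tdp.cyt_nuc_ratio
            if measure_mito and "tmrm" in channels:
                mito = segment_mitochondria(channels["tmrm"], soma_mask)
                mm = measure_mito_morphology(mito, channels["tmrm"], cell_mask)
                row["mito_count"] = mm.mito_count
                row["mito_mean_area_um2"] = mm.mean_area_um2
                row["mito_mean_intensity"] = mm.mean_mito_intensity
                row["whole_cell_tmrm"] = mm.whole_cell_tmrm
        rows.append(row)
    table = pd.DataFrame(rows)
    classes = list(seg.classes.values())
    summary = {
        "n_cells": len(rows),
        "class_counts": {c: classes.count(c) for c in sorted(set(classes))},
        "transformation_efficiency": transformation_efficiency(classes),
        "unpaired_nuclei": len(pairing.unpaired_nuclei) if pairing else 0,
        "multi_nucleus_cells": len(pairing.multi_nucleus_cells) if pairing else 0,
    }
    return PhenotypeResult(table=table, summary=summary, segmentation=seg)


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalResult:
    lifelines_table: pd.DataFrame
    km: dict  # group -> KMCurve
    logrank: pd.DataFrame | None
    cox: object | None
    qc: dict
    notices: list = field(default_factory=list)


def detections_from_frames(
    frames,
    detection: BlobParams | None = None,
    rules: ClassifierRules | None = None,
    crop_side: int = 128,
):
    """Per-frame detect-and-classify; returns list of Detection lists."""
    out = []
    for k, frame in enumerate(frames):
        seg = detect_and_classify(frame, detection=detection, rules=rules, crop_side=crop_side)
        dets = [
            Detection(
                frame=k,
                row=seg.centroids[l][0],
                col=seg.centroids[l][1],
                cell_class=seg.classes[l],
            )
            for l in sorted(seg.classes)
        ]
        out.append(dets)
    return out


def run_survival(
    group_movies: dict,
    frame_days,
    detection: BlobParams | None = None,
    rules: ClassifierRules | None = None,
    max_dist_um: float = 20.0,
    max_gap: int = 1,
    n_per_group: int = DEFAULT_SAMPLE_PER_GROUP,
    seed: int = 0,
    reference_group: str | None = None,
) -> SurvivalResult:
    """Image-based survival analysis over one movie per group.

    ``group_movies`` maps group label to a frame sequence (Image2D).  The
    chain is detect -> classify -> link -> lifelines -> sample -> KM +
    pairwise logrank + Cox (logrank/Cox skipped with a notice for a single
    group).
    """
    frame_days = [float(d) for d in frame_days]
    if len(frame_days) < 2:
        raise ParameterError("survival needs >= 2 frames")
    notices: list = []
    qc: dict = {}
    all_lifelines = []
    by_group: dict = {}
    for group in sorted(group_movies):
        frames = group_movies[group]
        if len(frames) != len(frame_days):
            raise ParameterError(
                f"group {group!r}: {len(frames)} frames but {len(frame_days)} frame days"
            )
        dets = detections_from_frames(frames, detection=detection, rules=rules)
        n_imn_dets = sum(1 for fr in dets for d in fr if d.cell_class == CLASS_IMN)
        if n_imn_dets == 0:
            raise PipelineError(
                f"group {group!r}: no iMN detected in any frame "
                f"({sum(len(fr) for fr in dets)} detections of other classes)"
            )
        pixel_size = frames[0].pixel_size
        tracks = link_detections(
            dets, max_dist_um=max_dist_um, max_gap=max_gap, pixel_size=pixel_size
        )
        lifelines, excluded = tracks_to_lifelines(
            tracks, frame_days, group=group, id_prefix=f"{group}_"
        )
        if not lifelines:
            raise PipelineError(f"group {group!r}: no tracks classified as iMN")
        sampled = sample_lifelines(lifelines, n_per_group, seed=seed)
        qc[group] = {
            "n_detections": sum(len(fr) for fr in dets),
            "n_tracks": len(tracks),
            "n_excluded_never_imn": excluded,
            "n_lifelines": len(lifelines),
            "n_sampled": len(sampled),
        }
        by_group[group] = sampled
        all_lifelines.extend(sampled)

    km = {g: fit_km(ls) for g, ls in by_group.items()}
    logrank = None
    cox = None
    if len(by_group) >= 2:
        logrank = logrank_pairwise(by_group)
        cox = fit_cox(all_lifelines, reference_group=reference_group)
    else:
        notices.append("single group: logrank and Cox skipped")
    table = pd.DataFrame(
        [
            {
                "subject_id": l.subject_id,
                "group": l.group,
                "entry_day": l.entry_day,
                "duration_days": l.duration_days,
                "event": l.event,
            }
            for l in all_lifelines
        ]
    )
    return SurvivalResult(
        lifelines_table=table, km=km, logrank=logrank, cox=cox, qc=qc, notices=notices
    )
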