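"""Mitochondrial morphometry from TMRM images and motility from kymographs.

TMRM is a potentiometric dye: its punctate accumulation marks polarized
mitochondria, so per-cell segmentation of the TMRM channel yields counts,
areas and intensities of individual mitochondria, while the integrated
TMRM signal over the whole cell tracks total membrane potential.

Motility is measured along manually (or synthetically) defined neurite
paths: a kymograph stacks the path's intensity profile over time, a moving
mitochondrion traces a sloped line, and per-column peak linking turns those
lines into tracks with distances, speeds and an anterograde/retrograde
direction sign (anterograde = away from the marked soma end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat

from .core import Image2D, LabelMask, ParameterError

_EIGHT = np.ones((3, 3), dtype=bool)


def segment_mitochondria(
    tmrm: Image2D,
    cell_mask: np.ndarray,
    tophat_radius_px: int = 5,
    min_size_px: int = 2,
) -> LabelMask:
    """Segment punctate TMRM signal within one cell.

    A white top-hat (radius ``tophat_radius_px``) flattens the cytosolic
    haze, Otsu within the cell picks the puncta, and objects below
    ``min_size_px`` pixels are dropped.  A cell with no signal variation
    yields an empty mask.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("cell mask is empty")
    # work in the cell's bounding box; top-hat is the slow step
    rows, cols = np.nonzero(mask)
    pad = tophat_radius_px + 1
    r0, r1 = max(0, rows.min() - pad), min(tmrm.shape[0], rows.max() + pad + 1)
    c0, c1 = max(0, cols.min() - pad), min(tmrm.shape[1], cols.max() + pad + 1)
    sub = tmrm.pixels[r0:r1, c0:c1]
    sub_mask = mask[r0:r1, c0:c1]
    flat = white_tophat(sub, footprint=disk(tophat_radius_px))
    vals = flat[sub_mask]
    labels = np.zeros(tmrm.shape, dtype=np.int32)
    if vals.size and np.ptp(vals) > 0:
        thr = float(threshold_otsu(vals))
        binary = (flat > thr) & sub_mask
        lab, _ = ndi.label(binary, structure=_EIGHT)
        if lab.max():
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_size_px
            keep[0] = False
            lab = np.where(keep[lab], lab, 0)
        labels[r0:r1, c0:c1] = lab
    return LabelMask(labels, tmrm.pixel_size).relabeled()


@dataclass(frozen=True)
class MitoCellMetrics:
    """Per-cell mitochondrial morphology summary.

    ``mean_mito_intensity`` averages per-mitochondrion mean TMRM over the
    mitochondria of the cell; ``whole_cell_tmrm`` is the integrated (sum)
    TMRM over the full cell mask.  Skeleton length and aspect ratio are
    shape descriptors emitted alongside the headline metrics.
    """

    mito_count: int
    mean_area_um2: float
    mean_mito_intensity: float
    whole_cell_tmrm: float
    mean_aspect_ratio: float


def measure_mito_morphology(
    mito: LabelMask, tmrm: Image2D, cell_mask: np.ndarray, pixel_size: float | None = None
) -> MitoCellMetrics:
    """Average single-mitochondrion measurements for one cell."""
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("cell mask is empty")
    px = pixel_size if pixel_size is not None else tmrm.pixel_size
    whole = float(tmrm.pixels[mask].sum())
    ids = mito.label_ids
    if ids.size == 0:
        return MitoCellMetrics(0, float("nan"), float("nan"), whole, float("nan"))
    areas, intens, aspects = [], [], []
    for rp in regionprops(mito.labels, intensity_image=tmrm.pixels):
        areas.append(rp.area * px**2)
        intens.append(rp.intensity_mean)
        minor = rp.axis_minor_length
        aspects.append(rp.axis_major_length / minor if minor > 0 else float("nan"))
    return MitoCellMetrics(
        mito_count=int(ids.size),
        mean_area_um2=float(np.mean(areas)),
        mean_mito_intensity=float(np.mean(intens)),
        whole_cell_tmrm=whole,
        mean_aspect_ratio=float(np.nanmean(aspects)),
    )


# ---------------------------------------------------------------------------
# kymographs and motility


@dataclass
class Kymograph:
    """Position x time raster along a neurite path.

    Rows are 1-px arc steps from the path start; columns are frames.
    ``soma_end`` marks which end of the path is proximal, fixing the
    anterograde sign convention.
    """

    data: np.ndarray  # (L, T)
    dx_um: float
    dt_s: float
    soma_end: str = "start"

    def __post_init__(self) -> None:
        if self.dx_um <= 0 or self.dt_s <= 0:
            raise ParameterError("dx and dt must be > 0")
        if self.soma_end not in ("start", "end"):
            raise ParameterError("soma_end must be 'start' or 'end'")


def build_kymograph(
    frames,
    path_px: np.ndarray,
    width_px: int = 5,
    soma_end: str = "start",
    dt_s: float = 1.0,
    pixel_size: float | None = None,
) -> Kymograph:
    """Max-project a ``width_px`` band normal to the path, per frame.

    The path polyline is resampled at 1-px arc steps; column ``t`` holds
    the maximum intensity across the band at every arc position.  ``dt_s``
    is the frame interval; ``pixel_size`` defaults to the frames' own.
    """
    if width_px % 2 != 1 or width_px < 1:
        raise ParameterError("width_px must be odd and >= 1")
    path = np.asarray(path_px, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ParameterError("path needs >= 2 points")
    d = np.diff(path, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    total = seg.sum()
    if total < 2:
        raise ParameterError("path shorter than 2 px")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = np.arange(0.0, total + 1e-9, 1.0)
    rows = np.interp(arc, cum, path[:, 0])
    cols = np.interp(arc, cum, path[:, 1])
    # unit tangents -> normals, via central differences along the resampled path
    tr = np.gradient(rows)
    tc = np.gradient(cols)
    norm = np.hypot(tr, tc)
    norm[norm == 0] = 1.0
    nr, nc = -tc / norm, tr / norm
    offsets = np.arange(width_px) - width_px // 2

    first = frames[0]
    px_size = pixel_size if pixel_size is not None else getattr(first, "pixel_size", 1.0)
    L = arc.size
    T = len(frames)
    data = np.zeros((L, T))
    band_r = rows[:, None] + nr[:, None] * offsets[None, :]
    band_c = cols[:, None] + nc[:, None] * offsets[None, :]
    coords = np.stack([band_r.ravel(), band_c.ravel()])
    for t, fr in enumerate(frames):
        arrpx = fr.pixels if hasattr(fr, "pixels") else np.asarray(fr, dtype=float)
        sampled = ndi.map_coordinates(arrpx, coords, order=1, mode="nearest")
        data[:, t] = sampled.reshape(L, width_px).max(axis=1)
    return Kymograph(data=data, dx_um=float(px_size), dt_s=float(dt_s), soma_end=soma_end)


@dataclass
class MitoTrack:
    """One mitochondrion's trajectory extracted from a kymograph."""

    track_id: int
    positions_um: np.ndarray  # per frame; NaN when absent
    motile: bool
    total_distance_um: float
    net_displacement_um: float  # signed, + = anterograde
    avg_speed_um_s: float  # segmental: mean speed over moving steps only
    max_speed_um_s: float
    antero_distance_um: float
    retro_distance_um: float


def extract_mito_tracks(
    kymo: Kymograph,
    gate_um_per_frame: float = 4.0,
    max_gap: int = 2,
    motile_threshold_um: float = 2.0,
    min_track_frames: int = 5,
    peak_rel_height: float = 0.3,
    move_step_um: float = 0.1,
) -> list:
    """Per-column peak detection linked into tracks by nearest position.

    Peaks brighter than ``median + peak_rel_height * (max - median)`` are
    linked column-to-column within ``gate_um_per_frame`` (scaled by the gap
    length when bridging up to ``max_gap`` missing columns; bridged
    positions are linearly interpolated).  A track is motile when its net
    displacement reaches ``motile_threshold_um``.
    """
    data = kymo.data
    if data.size == 0:
        raise ParameterError("empty kymograph")
    L, T = data.shape
    med = float(np.median(data))
    thr = med + peak_rel_height * (float(data.max()) - med)
    if data.max() <= med:
        return []
    min_dist = max(2, int(round(motile_threshold_um / kymo.dx_um / 2)))

    active = []  # dicts: positions (px, per frame), last_col, last_pos
    done = []
    for t in range(T):
        peaks, _ = find_peaks(data[:, t], height=thr, distance=min_dist)
        # greedy global nearest matching between active tracks and peaks
        pairs = []
        for ai, tr in enumerate(active):
            for pi, p in enumerate(peaks):
                gap = t - tr["last_col"]
                dist = abs(float(p) - tr["last_pos"]) * kymo.dx_um
                if dist <= gate_um_per_frame * gap:
                    pairs.append((dist / gap, ai, pi))
        pairs.sort()
        used_a, used_p = set(), set()
        for _, ai, pi in pairs:
            if ai in used_a or pi in used_p:
                continue
            used_a.add(ai)
            used_p.add(pi)
            tr = active[ai]
            gap = t - tr["last_col"]
            pos = float(peaks[pi])
            if gap > 1:  # interpolate bridged columns
                for g in range(1, gap):
                    tr["positions"][tr["last_col"] + g] = (
                        tr["last_pos"] + (pos - tr["last_pos"]) * g / gap
                    )
            tr["positions"][t] = pos
            tr["last_col"] = t
            tr["last_pos"] = pos
        for pi, p in enumerate(peaks):
            if pi not in used_p:
                positions = np.full(T, np.nan)
                positions[t] = float(p)
                active.append({"positions": positions, "last_col": t, "last_pos": float(p)})
        still = []
        for ai, tr in enumerate(active):
            if t - tr["last_col"] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)

    tracks = []
    tid = 0
    for tr in done:
        pos_px = tr["positions"]
        present = np.nonzero(np.isfinite(pos_px))[0]
        if present.size < min_track_frames:
            continue
        # express positions as arc length from the soma end, so increasing
        # position always means anterograde transport
        if kymo.soma_end == "end":
            pos_px = (L - 1) - pos_px
        pos_um = pos_px * kymo.dx_um
        span = pos_um[present[0] : present[-1] + 1]
        steps = np.diff(span)
        total = float(np.abs(steps).sum())
        net = float(span[-1] - span[0])
        # segmental average: steps where the punctum actually moved (a parked
        # or paused phase does not dilute the speed of the moving phase)
        moving = np.abs(steps) >= move_step_um
        avg = float(np.abs(steps[moving]).mean() / kymo.dt_s) if moving.any() else 0.0
        mx = float(np.abs(steps).max() / kymo.dt_s) if steps.size else 0.0
        tracks.append(
            MitoTrack(
                track_id=tid,
                positions_um=pos_um,
                motile=abs(net) >= motile_threshold_um,
                total_distance_um=total,
                net_displacement_um=net,
                avg_speed_um_s=avg,
                max_speed_um_s=mx,
                antero_distance_um=float(steps[steps > 0].sum()),
                retro_distance_um=float(-steps[steps < 0].sum()),
            )
        )
        tid += 1
    return tracks


@dataclass(frozen=True)
class MotilityMetrics:
    """Culture-level motility summary over the tracks of one neurite/cell."""

    n_tracks: int
    motile_fraction: float
    antero_total_um: float
    retro_total_um: float
    retro_antero_ratio: float  # NaN when no anterograde travel


def measure_motility(tracks) -> MotilityMetrics:
    """Motile fraction and per-direction travel totals (motile tracks only)."""
    if len(tracks) == 0:
        raise ParameterError("no tracks to summarize")
    motile = [t for t in tracks if t.motile]
    antero = sum(t.antero_distance_um for t in motile)
    retro = sum(t.retro_distance_um for t in motile)
    return MotilityMetrics(
        n_tracks=len(tracks),
        motile_fraction=len(motile) / len(tracks),
        antero_total_um=float(antero),
        retro_total_um=float(retro),
        retro_antero_ratio=float(retro / antero) if antero > 0 else float("nan"),
    )
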