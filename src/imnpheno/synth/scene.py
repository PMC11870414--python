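"""Static multi-channel scenes of induced motor neuron cultures.

A scene mixes three morphological classes on a constant background:

* **iMN** — small, bright, round soma (rendered as a Gaussian-profile disc)
  with branching neurites two pixels wide;
* **non-neurons** — large, dim, elongated elliptical blobs (flat
  fibroblast-like cells that failed to convert), axis ratio >= 2;
* **dead cells** — small condensed high-intensity discs without neurites.

Four channels are rendered on a shared grid: nuclei (Hoechst-like), eGFP
(cytoplasmic reporter filling soma and neurites), TMRM (punctate
mitochondrial signal inside the cell body) and TDP-43 (nuclear level with a
programmed cytosol/nucleus ratio).  Ground truth stores the label rasters
and per-cell scalars exactly as rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line
from skimage.morphology import dilation

from ..core import Image2D, ParameterError, PipelineError

CLASS_IMN = "iMN"
CLASS_NON_NEURON = "non_neuron"
CLASS_DEAD = "dead"
CLASSES = (CLASS_IMN, CLASS_NON_NEURON, CLASS_DEAD)

#: pixel sizes of the imaging modes used throughout, µm/pixel
PIXEL_SIZE_10X = 0.69
PIXEL_SIZE_20X = 0.345
PIXEL_SIZE_40X = 0.1725


class PlacementError(PipelineError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered culture field.

    Counts are per class; geometry is in µm and converted to pixels via
    ``pixel_size``.  ``neurite_length_um`` is the *total* arc length of one
    primary neurite tree (branches share the budget), so the true total
    neurite length of an iMN is ``neurite_count * neurite_length_um``.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = PIXEL_SIZE_20X
    n_imn: int = 20
    n_non_neuron: int = 20
    n_dead: int = 10
    soma_radius_um: float = 5.0
    nucleus_radius_um: float = 3.0
    neurite_count: int = 2
    neurite_length_um: float = 40.0
    branch_prob: float = 0.25
    neurite_width_px: int = 2
    nonneuron_axes_um: tuple[float, float] = (15.0, 6.0)
    dead_radius_um: float = 2.5
    channel_levels: dict = field(
        default_factory=lambda: {"nuclei": 120.0, "egfp": 150.0, "tmrm": 8.0, "tdp43": 100.0}
    )
    neurite_level_fraction: float = 0.6
    tdp43_cyt_nuc_ratio: float = 0.5
    mito_per_cell: int = 12
    mito_radius_um: float = 0.45
    mito_intensity: float = 150.0
    noise_sigma: float = 10.0
    background: float = 12.0
    min_separation_um: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_imn", "n_non_neuron", "n_dead", "mito_per_cell", "neurite_count"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")
        if not self.tdp43_cyt_nuc_ratio > 0:
            raise ParameterError("tdp43_cyt_nuc_ratio must be > 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ParameterError("branch_prob must be in [0, 1]")
        if self.noise_sigma < 0 or self.background < 0:
            raise ParameterError("noise_sigma and background must be >= 0")
        a, b = self.nonneuron_axes_um
        if a < 2 * b:
            raise ParameterError("non-neuron axis ratio must be >= 2")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell; metrics are exactly those rendered."""

    cell_id: int
    cell_class: str
    centroid: tuple[float, float]  # (row, col), px
    soma_area_um2: float
    neurite_total_length_um: float = 0.0
    branch_count: int = 0
    branch_points_px: tuple = ()
    tdp43_ratio: float = float("nan")
    mito_count: int = 0
    mito_areas_um2: tuple = ()
    mito_mean_intensity: float = float("nan")


@dataclass
class GroundTruth:
    """Label rasters plus per-cell records for a rendered scene."""

    cells: list
    soma_labels: np.ndarray
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    mito_labels: np.ndarray
    pixel_size: float

    def of_class(self, cell_class: str) -> list:
        return [c for c in self.cells if c.cell_class == cell_class]

    @property
    def class_counts(self) -> dict:
        return {k: len(self.of_class(k)) for k in CLASSES}


# ---------------------------------------------------------------------------
# rendering primitives


def _disc(shape, center, radius_px):
    """Boolean disc mask and the (rows, cols) index grids of its bbox."""
    r0 = max(0, int(math.floor(center[0] - radius_px - 1)))
    r1 = min(shape[0], int(math.ceil(center[0] + radius_px + 2)))
    c0 = max(0, int(math.floor(center[1] - radius_px - 1)))
    c1 = min(shape[1], int(math.ceil(center[1] + radius_px + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (slice(r0, r1), slice(c0, c1)), d2 <= radius_px**2, d2


def _ellipse_mask(shape, center, a_px, b_px, theta):
    ext = max(a_px, b_px)
    r0 = max(0, int(center[0] - ext - 1))
    r1 = min(shape[0], int(center[0] + ext + 2))
    c0 = max(0, int(center[1] - ext - 1))
    c1 = min(shape[1], int(center[1] + ext + 2))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - center[0], cc - center[1]
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    return (slice(r0, r1), slice(c0, c1)), (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


class _PointGrid:
    """Spatial hash of waypoints for O(1) clearance queries during growth."""

    def __init__(self, cell_um: float = 3.0):
        self.cell = cell_um
        self.bins: dict = {}

    def insert(self, pt) -> None:
        key = (int(pt[0] // self.cell), int(pt[1] // self.cell))
        self.bins.setdefault(key, []).append((float(pt[0]), float(pt[1])))

    def any_within(self, pt, radius: float) -> bool:
        ci, cj = int(pt[0] // self.cell), int(pt[1] // self.cell)
        reach = int(math.ceil(radius / self.cell))
        for i in range(ci - reach, ci + reach + 1):
            for j in range(cj - reach, cj + reach + 1):
                for q in self.bins.get((i, j), ()):
                    if math.hypot(pt[0] - q[0], pt[1] - q[1]) < radius:
                        return True
        return False


def _grow_neurite_tree(
    rng,
    origin_um,
    direction,
    total_length_um,
    branch_prob,
    seg_len_um=6.0,
    obstacles=(),
    avoid=None,
    clearance_um=1.8,
):
    """Recursive segment growth; returns (segments, n_branch_events, branch_points).

    The length budget is split in half at every branch event so the summed
    arc length of the tree equals ``total_length_um`` exactly.  Branching is
    suppressed when < 12 µm of budget remains, keeping every arm longer than
    the downstream spur-pruning length.  ``obstacles`` is a sequence of
    ``(center_um, clearance_um)`` cell bodies the tree steers around.
    ``avoid`` is a shared :class:`_PointGrid` of neurite waypoints (own and
    other cells', lagging two steps behind each growing tip, sampled at
    half-segment spacing): arms steer around existing arms because
    overlapping arms would merge in the rendered mask and corrupt both
    length and branch-count truth.
    """
    if avoid is None:
        avoid = _PointGrid()

    def _ok(a, b):
        """Candidate step a -> b is clear at its midpoint and endpoint."""
        mid = (a + b) / 2.0
        for point in (mid, b):
            for c, r in obstacles:
                if math.hypot(point[0] - c[0], point[1] - c[1]) < r:
                    return False
            if avoid.any_within(point, clearance_um):
                return False
        return True

    segments = []
    branches = 0
    branch_pts = []
    cooldown = 0
    pending: list = []  # waypoints not yet public, two steps behind the tip
    p = np.asarray(origin_um, dtype=float)
    d = float(direction)
    remaining = float(total_length_um)
    while remaining > 1e-9:
        step = min(seg_len_um, remaining)
        q = p + step * np.array([math.sin(d), math.cos(d)])
        if not _ok(p, q):
            # gentle deflections only: a sharp switchback would fold the arm
            # onto itself and thinning would read the fold as a branch point;
            # if every candidate is blocked the step proceeds and the rare
            # crossing costs a few erased pixels instead of a false junction
            for delta_deg in (35, -35, 70, -70):
                d_try = d + math.radians(delta_deg)
                q_try = p + step * np.array([math.sin(d_try), math.cos(d_try)])
                if _ok(p, q_try):
                    d, q = d_try, q_try
                    break
        segments.append((p.copy(), q.copy()))
        remaining -= step
        pending.append([p.copy(), (p + q) / 2.0])
        if len(pending) > 2:
            for pt in pending.pop(0):
                avoid.insert(pt)
        p = q
        if cooldown > 0:
            cooldown -= 1
        elif remaining >= 12.0 and rng.random() < branch_prob:
            # wide divergence keeps daughter and mother arms resolvable, so
            # thinning recovers exactly one junction per branch event; a
            # branch is only committed when both the daughter's and the
            # mother's next steps are unobstructed — otherwise the daughter
            # would be deflected parallel to the mother and the two arms
            # would merge in the rendered mask
            side = 1.0 if rng.random() < 0.5 else -1.0
            angle = math.radians(45.0 + 10.0 * rng.random())
            for s in (side, -side):
                b_dir = d + s * angle
                m_dir = d - s * math.radians(15.0)
                q_b = p + seg_len_um * np.array([math.sin(b_dir), math.cos(b_dir)])
                q_m = p + seg_len_um * np.array([math.sin(m_dir), math.cos(m_dir)])
                if _ok(p, q_b) and _ok(p, q_m):
                    branches += 1
                    branch_pts.append(p.copy())
                    half = remaining / 2.0
                    sub, sub_b, sub_pts = _grow_neurite_tree(
                        rng,
                        p,
                        b_dir,
                        half,
                        branch_prob,
                        seg_len_um,
                        obstacles,
                        avoid,
                        clearance_um,
                    )
                    segments.extend(sub)
                    branches += sub_b
                    branch_pts.extend(sub_pts)
                    remaining -= half
                    d = m_dir
                    cooldown = 1
                    break
        d += math.radians(rng.uniform(-6.0, 6.0))
    for chunk in pending:
        for pt in chunk:
            avoid.insert(pt)
    avoid.insert(p)
    return segments, branches, branch_pts


def _rasterize_segments(shape, segments_px, width_px):
    """Binary mask of polyline segments drawn ``width_px`` pixels wide."""
    mask = np.zeros(shape, dtype=bool)
    for p, q in segments_px:
        rr, cc = draw_line(
            int(round(p[0])), int(round(p[1])), int(round(q[0])), int(round(q[1]))
        )
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    if width_px > 1:
        mask = dilation(mask, footprint=np.ones((width_px, width_px), dtype=bool))
    return mask


def _place_centers(rng, shape, radii_px, margins_px, min_sep_px, gap_px=12.0, max_tries=4000):
    """Sequentially place cell centres without body overlap.

    ``radii_px`` / ``margins_px`` are per-cell body radii and border
    margins; two cells must be at least ``max(min_sep, r_i + r_j + gap)``
    apart so even large elliptical bodies cannot merge.
    """
    centers = []
    n = len(radii_px)
    for i in range(n):
        m = margins_px[i]
        lo_r, hi_r = m, shape[0] - m
        lo_c, hi_c = m, shape[1] - m
        if hi_r <= lo_r or hi_c <= lo_c:
            raise PlacementError(
                f"image {shape} too small for margin {m:.0f} px; "
                "increase image_shape or reduce cell geometry"
            )
        for _attempt in range(max_tries):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            ok = all(
                np.hypot(*(cand - c))
                >= max(min_sep_px, radii_px[i] + radii_px[j] + gap_px)
                for j, c in enumerate(centers)
            )
            if ok:
                centers.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {n} cells with min separation {min_sep_px:.0f} px "
                f"in image {shape}; requested counts exceed field capacity"
            )
    return centers


def _place_puncta(rng, inside_mask, sl, n, min_sep_px, max_tries=400):
    """Pick ``n`` punctum centres (global px coords) inside a soma mask."""
    rows, cols = np.nonzero(inside_mask)
    if rows.size == 0:
        return []
    rows = rows + sl[0].start
    cols = cols + sl[1].start
    chosen = []
    for _ in range(n):
        for _attempt in range(max_tries):
            i = rng.integers(rows.size)
            cand = (float(rows[i]), float(cols[i]))
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep_px for p in chosen):
                chosen.append(cand)
                break
        else:
            break  # soma saturated; render fewer puncta and record the truth
    return chosen


# ---------------------------------------------------------------------------


def generate_static_scene(spec: SceneSpec):
    """Render one scene; returns ``(channels, truth)``.

    ``channels`` maps channel name to :class:`Image2D`; ``truth`` is a
    :class:`GroundTruth` with one entry per rendered cell.  With
    ``noise_sigma == 0`` the output is a deterministic function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    px = spec.pixel_size

    soma_r = spec.soma_radius_um / px
    nuc_r = spec.nucleus_radius_um / px
    dead_r = spec.dead_radius_um / px
    a_px, b_px = (spec.nonneuron_axes_um[0] / px, spec.nonneuron_axes_um[1] / px)
    mito_r = spec.mito_radius_um / px
    min_sep = spec.min_separation_um / px

    class_seq = (
        [CLASS_IMN] * spec.n_imn
        + [CLASS_NON_NEURON] * spec.n_non_neuron
        + [CLASS_DEAD] * spec.n_dead
    )
    body_r = {CLASS_IMN: soma_r, CLASS_NON_NEURON: a_px, CLASS_DEAD: dead_r}
    margin_of = {
        CLASS_IMN: soma_r + spec.neurite_length_um / px + 3,
        CLASS_NON_NEURON: a_px + 3,
        CLASS_DEAD: dead_r + 3,
    }
    centers = _place_centers(
        rng,
        shape,
        [body_r[c] for c in class_seq],
        [margin_of[c] for c in class_seq],
        min_sep,
    )

    # cell bodies as obstacles (µm) so neurites steer around neighbours
    body_radius = {
        CLASS_IMN: spec.soma_radius_um,
        CLASS_NON_NEURON: spec.nonneuron_axes_um[0],
        CLASS_DEAD: spec.dead_radius_um,
    }
    obstacles_um = [
        (np.asarray(c) * px, body_radius[cls] + 3.0) for c, cls in zip(centers, class_seq)
    ]
    arbor_grid = _PointGrid()  # shared: every tree avoids every other tree

    chans = {
        name: np.full(shape, spec.background, dtype=np.float64) for name in spec.channel_levels
    }
    soma_lab = np.zeros(shape, dtype=np.int32)
    cell_lab = np.zeros(shape, dtype=np.int32)
    nuc_lab = np.zeros(shape, dtype=np.int32)
    mito_lab = np.zeros(shape, dtype=np.int32)
    cells: list[CellTruth] = []
    next_mito = 1
    lv = spec.channel_levels

    for cid, (center, cls) in enumerate(zip(centers, class_seq), start=1):
        if cls == CLASS_IMN:
            sl, soma, d2 = _disc(shape, center, soma_r)
            sigma = soma_r / 1.6
            profile = lv["egfp"] * np.exp(-d2 / (2 * sigma**2))
            chans["egfp"][sl][soma] += profile[soma]
            soma_lab[sl][soma] = cid
            cell_lab[sl][soma] = cid

            # neurites: trees rooted on the soma rim, total length budgeted
            total_len = 0.0
            branches = 0
            branch_points: list = []
            neurite_mask = np.zeros(shape, dtype=bool)
            base = rng.uniform(0, 2 * math.pi)
            others = obstacles_um[: cid - 1] + obstacles_um[cid:]
            for k in range(spec.neurite_count):
                direction = base + 2 * math.pi * k / max(spec.neurite_count, 1)
                origin = center + (soma_r - 1.0) * np.array(
                    [math.sin(direction), math.cos(direction)]
                )
                segs_um, nb, bpts = _grow_neurite_tree(
                    rng,
                    origin * px,
                    direction,
                    spec.neurite_length_um,
                    spec.branch_prob,
                    obstacles=others,
                    avoid=arbor_grid,
                )
                branch_points.extend(bpts)
                segs_px = [(p / px, q / px) for p, q in segs_um]
                neurite_mask |= _rasterize_segments(shape, segs_px, spec.neurite_width_px)
                total_len += spec.neurite_length_um
                branches += nb
            neurite_mask &= cell_lab == 0
            chans["egfp"][neurite_mask] += lv["egfp"] * spec.neurite_level_fraction
            cell_lab[neurite_mask] = cid

            nsl, nuc, _ = _disc(shape, center, nuc_r)
            chans["nuclei"][nsl][nuc] += lv["nuclei"]
            nuc_lab[nsl][nuc] = cid

            # TDP-43: nucleus at full level, cytosol at the programmed ratio
            cell_here = cell_lab == cid
            nuc_here = nuc_lab == cid
            chans["tdp43"][nuc_here] += lv["tdp43"]
            chans["tdp43"][cell_here & ~nuc_here] += lv["tdp43"] * spec.tdp43_cyt_nuc_ratio

            # mitochondria: discs inside the soma, cytosolic TMRM haze under them
            chans["tmrm"][sl][soma] += lv["tmrm"]
            erode_sl, inner, _ = _disc(shape, center, soma_r - mito_r - 1.0)
            pts = _place_puncta(rng, inner, erode_sl, spec.mito_per_cell, 2 * mito_r + 2.0)
            areas = []
            m_int = []
            for pt in pts:
                msl, mdisc, _ = _disc(shape, pt, mito_r)
                mdisc &= soma_lab[msl] == cid
                chans["tmrm"][msl][mdisc] += spec.mito_intensity
                mito_lab[msl][mdisc] = next_mito
                areas.append(float(mdisc.sum()) * px**2)
                m_int.append(float(np.mean(chans["tmrm"][msl][mdisc])) if mdisc.any() else np.nan)
                next_mito += 1
            cells.append(
                CellTruth(
                    cell_id=cid,
                    cell_class=cls,
                    centroid=(float(center[0]), float(center[1])),
                    soma_area_um2=float(soma.sum()) * px**2,
                    neurite_total_length_um=total_len,
                    branch_count=branches,
                    branch_points_px=tuple((bp / px).tolist() for bp in branch_points),
                    tdp43_ratio=spec.tdp43_cyt_nuc_ratio,
                    mito_count=len(pts),
                    mito_areas_um2=tuple(areas),
                    mito_mean_intensity=float(np.mean(m_int)) if m_int else float("nan"),
                )
            )
        elif cls == CLASS_NON_NEURON:
            theta = rng.uniform(0, math.pi)
            sl, body = _ellipse_mask(shape, center, a_px, b_px, theta)
            chans["egfp"][sl][body] += lv["egfp"] * 0.4
            soma_lab[sl][body] = cid
            cell_lab[sl][body] = cid
            nsl, nuc, _ = _disc(shape, center, nuc_r * 1.1)
            chans["nuclei"][nsl][nuc] += lv["nuclei"]
            nuc_lab[nsl][nuc] = cid
            cell_here = cell_lab == cid
            nuc_here = nuc_lab == cid
            chans["tdp43"][nuc_here] += lv["tdp43"]
            chans["tdp43"][cell_here & ~nuc_here] += lv["tdp43"] * spec.tdp43_cyt_nuc_ratio
            chans["tmrm"][sl][body] += lv["tmrm"]
            cells.append(
                CellTruth(
                    cell_id=cid,
                    cell_class=cls,
                    centroid=(float(center[0]), float(center[1])),
                    soma_area_um2=float(body.sum()) * px**2,
                )
            )
        else:  # dead
            sl, body, d2 = _disc(shape, center, dead_r)
            chans["egfp"][sl][body] += lv["egfp"] * 1.2
            soma_lab[sl][body] = cid
            cell_lab[sl][body] = cid
            nsl, nuc, _ = _disc(shape, center, dead_r * 0.6)
            chans["nuclei"][nsl][nuc] += lv["nuclei"] * 1.5  # condensed chromatin
            nuc_lab[nsl][nuc] = cid
            chans["tdp43"][sl][body] += lv["tdp43"] * 0.5
            cells.append(
                CellTruth(
                    cell_id=cid,
                    cell_class=cls,
                    centroid=(float(center[0]), float(center[1])),
                    soma_area_um2=float(body.sum()) * px**2,
                )
            )

    if spec.noise_sigma > 0:
        for name in sorted(chans):
            chans[name] = np.clip(
                chans[name] + rng.normal(0.0, spec.noise_sigma, shape), 0.0, None
            )

    channels = {
        name: Image2D(chans[name], pixel_size=px, channel=name) for name in chans
    }
    truth = GroundTruth(
        cells=cells,
        soma_labels=soma_lab,
        cell_labels=cell_lab,
        nucleus_labels=nuc_lab,
        mito_labels=mito_lab,
        pixel_size=px,
    )
    return channels, truth
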