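"""Time-lapse cultures with exponential per-cell death hazards.

The default schedule images every second day from D12 to D46 (18 frames).
Each iMN draws a death time from an exponential distribution with the
movie's hazard (events/day, times the optional multiplier); once a cell
dies its pixels are removed from all later frames — the optical signature
of death used by the survival pipeline.  Cells drift as a small random
walk, and a per-frame dropout probability emulates transient detection
failures (a cell simply not rendered in that frame).

One movie carries one hazard; grouped designs (genotype, drug) are built by
:func:`generate_survival_experiment`, which renders one movie per group so
group identity survives the image-only analysis chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..core import Image2D, ParameterError
from .scene import (
    CLASS_DEAD,
    CLASS_IMN,
    CLASS_NON_NEURON,
    PIXEL_SIZE_10X,
    SceneSpec,
    _disc,
    _ellipse_mask,
    _grow_neurite_tree,
    _place_centers,
    _PointGrid,
    _rasterize_segments,
)

DEFAULT_FRAME_DAYS = tuple(float(d) for d in range(12, 47, 2))  # D12..D46, 18 frames


def default_timelapse_scene(n_imn: int = 40, seed: int = 0) -> SceneSpec:
    """Scene geometry for viability tracking at 10x (0.69 µm/pixel)."""
    return SceneSpec(
        image_shape=(512, 512),
        pixel_size=PIXEL_SIZE_10X,
        n_imn=n_imn,
        n_non_neuron=6,
        n_dead=4,
        neurite_length_um=30.0,
        branch_prob=0.15,
        min_separation_um=26.0,
        noise_sigma=8.0,
        seed=seed,
    )


@dataclass(frozen=True)
class TimeLapseSpec:
    """One movie: imaging schedule, death hazard, drift and dropout."""

    frame_days: tuple = DEFAULT_FRAME_DAYS
    hazard_per_day: float = 0.03
    hazard_multiplier: float = 1.0
    drift_um_per_frame: float = 0.5
    dropout_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.frame_days)
        if len(days) == 0:
            raise ParameterError("frame_days must be non-empty")
        if len(days) < 2:
            raise ParameterError("a time-lapse needs at least 2 frame times")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterError("frame_days must be strictly increasing")
        if self.hazard_per_day < 0 or self.hazard_multiplier < 0:
            raise ParameterError("hazards must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ParameterError("dropout_prob must be in [0, 1)")
        object.__setattr__(self, "frame_days", days)

    @property
    def hazard(self) -> float:
        return self.hazard_per_day * self.hazard_multiplier


@dataclass
class CellTrackTruth:
    """Ground-truth fate and per-frame position of one cell."""

    cell_id: int
    cell_class: str
    entry_day: float
    death_day: float  # inf when the cell outlives the window
    positions: np.ndarray  # (n_frames, 2) row/col px; NaN when not rendered
    rendered: np.ndarray  # bool per frame

    @property
    def event_observed(self) -> bool:
        return bool(np.isfinite(self.death_day))


@dataclass
class TimeLapseTruth:
    frame_days: tuple
    tracks: list
    hazard: float

    def imn_tracks(self) -> list:
        return [t for t in self.tracks if t.cell_class == CLASS_IMN]


def _sample_death_day(rng, entry_day: float, hazard: float, last_day: float) -> float:
    if hazard <= 0:
        rng.exponential()  # keep the stream aligned across hazard settings
        return math.inf
    t = entry_day + rng.exponential(1.0 / hazard)
    return t if t <= last_day else math.inf


def generate_time_lapse(spec: TimeLapseSpec, scene: SceneSpec):
    """Render one movie; returns ``(frames, truth)``.

    ``frames`` is a list of eGFP :class:`Image2D`; ``truth`` records entry
    day (first frame for every cell), continuous death day and per-frame
    positions.  Death days beyond the last frame are stored as ``inf``
    (censored).  Non-neurons and dead debris from the scene spec are
    rendered as static distractors and never die.
    """
    rng = np.random.default_rng(spec.seed)
    days = spec.frame_days
    last_day = days[-1]
    shape = tuple(scene.image_shape)
    px = scene.pixel_size
    soma_r = scene.soma_radius_um / px
    a_px, b_px = scene.nonneuron_axes_um[0] / px, scene.nonneuron_axes_um[1] / px
    dead_r = scene.dead_radius_um / px

    class_seq = (
        [CLASS_IMN] * scene.n_imn
        + [CLASS_NON_NEURON] * scene.n_non_neuron
        + [CLASS_DEAD] * scene.n_dead
    )
    body_r_px = {CLASS_IMN: soma_r, CLASS_NON_NEURON: a_px, CLASS_DEAD: dead_r}
    margin_of = {
        CLASS_IMN: soma_r + scene.neurite_length_um / px + 3,
        CLASS_NON_NEURON: a_px + 3,
        CLASS_DEAD: dead_r + 3,
    }
    centers = _place_centers(
        rng,
        shape,
        [body_r_px[c] for c in class_seq],
        [margin_of[c] for c in class_seq],
        scene.min_separation_um / px,
    )

    # per-cell static geometry (neurite trees in cell-local µm coordinates)
    body_radius = {
        CLASS_IMN: scene.soma_radius_um,
        CLASS_NON_NEURON: scene.nonneuron_axes_um[0],
        CLASS_DEAD: scene.dead_radius_um,
    }
    arbor_grid = _PointGrid()
    geoms = []
    for i, (center, cls) in enumerate(zip(centers, class_seq)):
        if cls == CLASS_IMN:
            obstacles = [
                (np.asarray(c) * px, body_radius[c_cls] + 3.0)
                for j, (c, c_cls) in enumerate(zip(centers, class_seq))
                if j != i
            ]
            # grown in global µm coordinates (shared avoidance grid), stored
            # cell-local so the tree translates rigidly with drift
            center_um = np.asarray(center) * px
            trees = []
            base = rng.uniform(0, 2 * math.pi)
            for k in range(scene.neurite_count):
                direction = base + 2 * math.pi * k / max(scene.neurite_count, 1)
                origin_um = center_um + (soma_r - 1.0) * px * np.array(
                    [math.sin(direction), math.cos(direction)]
                )
                segs, _nb, _bp = _grow_neurite_tree(
                    rng,
                    origin_um,
                    direction,
                    scene.neurite_length_um,
                    scene.branch_prob,
                    obstacles=obstacles,
                    avoid=arbor_grid,
                )
                trees.extend((a - center_um, b - center_um) for a, b in segs)
            geoms.append(trees)
        elif cls == CLASS_NON_NEURON:
            geoms.append(rng.uniform(0, math.pi))
        else:
            geoms.append(None)

    # fates and drifted positions
    tracks = []
    n_frames = len(days)
    for cid, (center, cls) in enumerate(zip(centers, class_seq), start=1):
        death = (
            _sample_death_day(rng, days[0], spec.hazard, last_day)
            if cls == CLASS_IMN
            else math.inf
        )
        pos = np.full((n_frames, 2), np.nan)
        rendered = np.zeros(n_frames, dtype=bool)
        cur = np.asarray(center, dtype=float)
        for k, day in enumerate(days):
            if k > 0 and spec.drift_um_per_frame > 0:
                cur = cur + rng.normal(0.0, spec.drift_um_per_frame / px, size=2)
            alive = day < death
            drop = cls == CLASS_IMN and rng.random() < spec.dropout_prob
            if alive and not drop:
                pos[k] = cur
                rendered[k] = True
        tracks.append(
            CellTrackTruth(
                cell_id=cid,
                cell_class=cls,
                entry_day=days[0],
                death_day=death,
                positions=pos,
                rendered=rendered,
            )
        )

    # render frames
    lv = scene.channel_levels["egfp"]
    frames = []
    for k in range(n_frames):
        img = np.full(shape, scene.background, dtype=np.float64)
        for tr, cls, geom in zip(tracks, class_seq, geoms):
            if not tr.rendered[k]:
                continue
            c = tr.positions[k]
            if cls == CLASS_IMN:
                sl, soma, d2 = _disc(shape, c, soma_r)
                sigma = soma_r / 1.6
                img[sl][soma] += lv * np.exp(-d2[soma] / (2 * sigma**2))
                segs_px = [(c + p / px, c + q / px) for p, q in geom]
                nmask = _rasterize_segments(shape, segs_px, scene.neurite_width_px)
                nmask[sl] &= ~soma
                img[nmask] += lv * scene.neurite_level_fraction
            elif cls == CLASS_NON_NEURON:
                sl, body = _ellipse_mask(shape, c, a_px, b_px, geom)
                img[sl][body] += lv * 0.4
            else:
                sl, body, _ = _disc(shape, c, dead_r)
                img[sl][body] += lv * 1.2
        if scene.noise_sigma > 0:
            img = np.clip(img + rng.normal(0.0, scene.noise_sigma, shape), 0.0, None)
        frames.append(Image2D(img, pixel_size=px, channel="egfp"))

    return frames, TimeLapseTruth(frame_days=days, tracks=tracks, hazard=spec.hazard)


def generate_survival_experiment(
    group_hazards: dict,
    n_per_group: int = 40,
    seed: int = 0,
    frame_days: tuple = DEFAULT_FRAME_DAYS,
    dropout_prob: float = 0.05,
    drift_um_per_frame: float = 0.5,
    scene_factory=default_timelapse_scene,
):
    """Render one movie per group; returns ``{group: (frames, truth)}``.

    ``group_hazards`` maps group label to death hazard (events/day).  Each
    group gets an independent seed derived from ``seed`` so movies differ
    while the whole experiment stays reproducible.
    """
    out = {}
    for i, (group, hazard) in enumerate(sorted(group_hazards.items())):
        sub = (seed * 1000003 + i * 7919) % (2**31 - 1)
        scene = scene_factory(n_imn=n_per_group, seed=sub)
        spec = TimeLapseSpec(
            frame_days=frame_days,
            hazard_per_day=hazard,
            dropout_prob=dropout_prob,
            drift_um_per_frame=drift_um_per_frame,
            seed=sub + 1,
        )
        out[group] = generate_time_lapse(spec, scene)
    return out
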