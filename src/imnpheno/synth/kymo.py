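"""Neurite movies with stationary and motile mitochondrial puncta.

Default acquisition mirrors live TMRM imaging of neurites: 10 minutes at
0.33 Hz and 40x (0.1725 µm/pixel), giving ``floor(600 * 0.33) = 198``
frames.  Each punctum moves along the neurite path at a programmed constant
speed (µm/s, anterograde or retrograde, with optional pause intervals) or
stays put; the truth records its exact arc-length position at every frame.
A punctum pushed past a path end clamps there and is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..core import Image2D, ParameterError
from .scene import PIXEL_SIZE_40X


@dataclass(frozen=True)
class PunctumSpec:
    """Motion program of one mitochondrion along the path (arc µm from soma end)."""

    start_um: float
    speed_um_s: float = 0.0
    direction: int = 1  # +1 anterograde (away from soma), -1 retrograde
    pauses: tuple = ()  # ((t0_s, t1_s), ...) intervals with zero velocity

    def __post_init__(self) -> None:
        if self.speed_um_s < 0:
            raise ParameterError("speeds must be >= 0")
        if self.direction not in (-1, 1):
            raise ParameterError("direction must be +1 or -1")


def _default_path():
    # straight horizontal neurite, soma at the left end
    return np.array([[32.0, 8.0], [32.0, 412.0]])


@dataclass(frozen=True)
class KymographMovieSpec:
    duration_s: float = 600.0
    frame_rate_hz: float = 0.33
    pixel_size: float = PIXEL_SIZE_40X
    image_shape: tuple = (64, 420)
    path_px: np.ndarray = field(default_factory=_default_path)  # (row, col) polyline
    soma_end: str = "start"
    puncta: tuple = ()
    punctum_radius_um: float = 0.45
    punctum_intensity: float = 150.0
    neurite_intensity: float = 12.0
    background: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        path = np.asarray(self.path_px, dtype=float)
        if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
            raise ParameterError("path polyline needs >= 2 (row, col) points")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ParameterError("duration and frame rate must be > 0")
        if self.soma_end not in ("start", "end"):
            raise ParameterError("soma_end must be 'start' or 'end'")
        object.__setattr__(self, "path_px", path)
        object.__setattr__(self, "puncta", tuple(self.puncta))

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_s * self.frame_rate_hz + 1e-9))

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def path_length_um(self) -> float:
        d = np.diff(self.path_px, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum()) * self.pixel_size


@dataclass
class NeuriteMovieTruth:
    positions_um: np.ndarray  # (n_puncta, n_frames) arc length from soma end
    motile: np.ndarray  # bool per punctum (net truth displacement >= threshold)
    clamped: np.ndarray  # bool per punctum: hit a path end at some frame
    frame_times_s: np.ndarray
    path_length_um: float
    motile_threshold_um: float


def _arc_to_xy(path_px, arc_px):
    """Interpolate (row, col) at the given arc-length positions (px)."""
    d = np.diff(path_px, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = np.clip(arc_px, 0.0, cum[-1])
    rows = np.interp(arc, cum, path_px[:, 0])
    cols = np.interp(arc, cum, path_px[:, 1])
    return rows, cols


def _effective_time(t: float, pauses) -> float:
    """Time elapsed at ``t`` minus time spent inside pause intervals."""
    eff = t
    for t0, t1 in pauses:
        eff -= max(0.0, min(t, t1) - t0) if t > t0 else 0.0
    return eff


def generate_neurite_movie(spec: KymographMovieSpec, motile_threshold_um: float = 2.0):
    """Render the movie; returns ``(frames, truth)``.

    Punctum kinematics are exact in the truth: arc position at frame time
    ``t`` is ``start + direction * speed * effective_time(t)`` clamped to
    the path, where pauses freeze the effective clock.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_frames
    times = np.arange(T) * spec.dt_s
    L = spec.path_length_um
    n = len(spec.puncta)

    pos = np.zeros((n, T))
    clamped = np.zeros(n, dtype=bool)
    for i, p in enumerate(spec.puncta):
        if not 0.0 <= p.start_um <= L:
            raise ParameterError(f"punctum start {p.start_um} outside path [0, {L:.1f}] µm")
        raw = p.start_um + p.direction * p.speed_um_s * np.array(
            [_effective_time(t, p.pauses) for t in times]
        )
        clipped = np.clip(raw, 0.0, L)
        clamped[i] = bool(np.any(raw != clipped))
        pos[i] = clipped
    net = np.abs(pos[:, -1] - pos[:, 0]) if T > 0 else np.zeros(n)
    motile = net >= motile_threshold_um

    # render
    shape = tuple(spec.image_shape)
    r_px = spec.punctum_radius_um / spec.pixel_size
    # static neurite backbone
    arc_samples = np.arange(0.0, L / spec.pixel_size, 1.0)
    nr, nc = _arc_to_xy(spec.path_px, arc_samples)
    base = np.full(shape, spec.background, dtype=np.float64)
    ri, ci = np.round(nr).astype(int), np.round(nc).astype(int)
    ok = (ri >= 0) & (ri < shape[0]) & (ci >= 0) & (ci < shape[1])
    base[ri[ok], ci[ok]] += spec.neurite_intensity

    frames = []
    win = int(math.ceil(3 * r_px)) + 1
    for k in range(T):
        img = base.copy()
        rows, cols = _arc_to_xy(spec.path_px, pos[:, k] / spec.pixel_size)
        for r0, c0 in zip(rows, cols):
            rlo, rhi = max(0, int(r0) - win), min(shape[0], int(r0) + win + 1)
            clo, chi = max(0, int(c0) - win), min(shape[1], int(c0) + win + 1)
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            img[rlo:rhi, clo:chi] += spec.punctum_intensity * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * r_px**2)
            )
        if spec.noise_sigma > 0:
            img = np.clip(img + rng.normal(0.0, spec.noise_sigma, shape), 0.0, None)
        frames.append(Image2D(img, pixel_size=spec.pixel_size, channel="tmrm"))

    truth = NeuriteMovieTruth(
        positions_um=pos,
        motile=motile,
        clamped=clamped,
        frame_times_s=times,
        path_length_um=L,
        motile_threshold_um=motile_threshold_um,
    )
    return frames, truth
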