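"""Two-channel PercevalHR biosensor traces.

The biosensor reports the intracellular ATP/ADP ratio as the ratio of its
490 nm (green) to 405 nm (blue) excitation signals.  The default protocol
images for 25 minutes at 0.2 Hz (300 samples) with oligomycin added at
5 minutes and 2-deoxy-D-glucose at 15 minutes.  Phase ratios are programmed
as shifts relative to baseline; the sample acquired at each injection is
rendered halfway through the transition to exercise the analysis' settle
window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..core import ParameterError


@dataclass(frozen=True)
class PercevalSpec:
    baseline_ratio: float = 1.0
    oligo_shift: float = 0.3
    dg_shift: float = -0.4
    t_oligo_min: float = 5.0
    t_2dg_min: float = 15.0
    duration_min: float = 25.0
    rate_hz: float = 0.2
    blue_level: float = 100.0
    noise_sigma: float = 0.0  # additive, same units as the channel signals
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0:
            raise ParameterError("baseline ratio must be > 0")
        for name, r in zip(("post-oligomycin", "post-2DG"), self.phase_ratios[1:]):
            if r <= 0:
                raise ParameterError(f"{name} ratio must be > 0, got {r}")
        if not 0 < self.t_oligo_min < self.t_2dg_min < self.duration_min:
            raise ParameterError("injections must be ordered and within the recording")

    @property
    def phase_ratios(self) -> tuple:
        """(baseline, post-oligomycin, post-2DG) true ratios; shifts are vs baseline."""
        return (
            self.baseline_ratio,
            self.baseline_ratio + self.oligo_shift,
            self.baseline_ratio + self.dg_shift,
        )

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration_min * 60.0 * self.rate_hz + 1e-9))


def generate_perceval_trace(spec: PercevalSpec):
    """Render blue/green series; returns ``(blue, green, times_s, truth_ratios)``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    times = np.arange(n) / spec.rate_hz
    t1, t2 = spec.t_oligo_min * 60.0, spec.t_2dg_min * 60.0
    r0, r1, r2 = spec.phase_ratios

    ratio = np.where(times < t1, r0, np.where(times < t2, r1, r2))
    # sample caught mid-injection: halfway between adjacent phase ratios
    for t_inj, before, after in ((t1, r0, r1), (t2, r1, r2)):
        idx = np.nonzero(times >= t_inj)[0]
        if idx.size:
            ratio[idx[0]] = 0.5 * (before + after)

    blue = np.full(n, spec.blue_level)
    green = ratio * spec.blue_level
    if spec.noise_sigma > 0:
        blue = blue + rng.normal(0.0, spec.noise_sigma, n)
        green = green + rng.normal(0.0, spec.noise_sigma, n)
    return blue, green, times, spec.phase_ratios
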