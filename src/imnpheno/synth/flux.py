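"""Synthetic extracellular-flux plates.

Each well follows the four-segment injection schedule (baseline,
oligomycin, FCCP, antimycin A + rotenone with 2-deoxy-D-glucose) with six
replicate wells by default.  Per segment the instrument takes a few
measurements; the first measurement after each injection is rendered
mid-transition (halfway between the adjacent plateaus), which is exactly
what the analysis' one-cycle settle window is meant to absorb.  Truth
stages are computed from the programmed plateaus by the same arithmetic
the analysis applies (:func:`imnpheno.bioenergetics.stages_from_segment_rates`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import ParameterError
from ..bioenergetics import FluxPlate, FluxStages, stages_from_segment_rates


@dataclass(frozen=True)
class FluxPlateSpec:
    n_wells: int = 6
    points_per_segment: tuple = (3, 3, 3, 3)
    interval_min: float = 6.0
    ocr_plateaus: tuple = (100.0, 40.0, 150.0, 20.0)
    ecar_plateaus: tuple = (50.0, 70.0, 80.0, 10.0)
    cell_count: int = 20000
    noise_sigma_ocr: float = 0.0
    noise_sigma_ecar: float = 0.0
    transition_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ParameterError("n_wells must be >= 1")
        if len(self.ocr_plateaus) != 4 or len(self.ecar_plateaus) != 4:
            raise ParameterError("need a plateau rate for each of the 4 segments")
        if not all(np.isfinite(self.ocr_plateaus)) or not all(np.isfinite(self.ecar_plateaus)):
            raise ParameterError("plateau rates must be finite")
        if len(self.points_per_segment) != 4 or any(p < 2 for p in self.points_per_segment):
            raise ParameterError("each segment needs >= 2 measurements (settle window)")
        if self.cell_count <= 0:
            raise ParameterError("cell_count must be > 0")


def generate_flux_plate(spec: FluxPlateSpec):
    """Build the plate; returns ``(plate, truth)``.

    ``truth`` maps well -> :class:`FluxStages` computed from the programmed
    plateaus (unnormalized — divide by ``spec.cell_count`` for per-cell
    values, matching the analysis' normalized output).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    t = 0.0
    schedule = []  # (segment, is_first_after_injection)
    for seg, npts in enumerate(spec.points_per_segment):
        for j in range(npts):
            schedule.append((seg, seg > 0 and j == 0))
    for w in range(spec.n_wells):
        well = f"W{w + 1}"
        t = 0.0
        for seg, transitional in schedule:
            ocr = spec.ocr_plateaus[seg]
            ecar = spec.ecar_plateaus[seg]
            if transitional:
                ocr = spec.ocr_plateaus[seg - 1] + spec.transition_fraction * (
                    ocr - spec.ocr_plateaus[seg - 1]
                )
                ecar = spec.ecar_plateaus[seg - 1] + spec.transition_fraction * (
                    ecar - spec.ecar_plateaus[seg - 1]
                )
            if spec.noise_sigma_ocr > 0:
                ocr += rng.normal(0.0, spec.noise_sigma_ocr)
            if spec.noise_sigma_ecar > 0:
                ecar += rng.normal(0.0, spec.noise_sigma_ecar)
            rows.append(
                {
                    "well": well,
                    "time_min": round(t, 3),
                    "segment": seg,
                    "ocr": ocr,
                    "ecar": ecar,
                    "cell_count": spec.cell_count,
                }
            )
            t += spec.interval_min
    plate = FluxPlate(pd.DataFrame(rows))
    true_stages = stages_from_segment_rates(spec.ocr_plateaus, spec.ecar_plateaus)
    truth = {f"W{w + 1}": true_stages for w in range(spec.n_wells)}
    return plate, truth
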