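"""Extracellular-flux stage analysis and ATP/ADP biosensor summaries.

A flux assay records oxygen consumption (OCR) and extracellular
acidification (ECAR) per well through four segments — baseline, after
oligomycin (ATP-synthase inhibitor), after FCCP (uncoupler), and after
antimycin A + rotenone (respiratory chain block) given together with
2-deoxy-D-glucose (glycolysis block).  Stages are derived per well:

* non-mitochondrial OCR / non-glycolytic ECAR = mean rate of the final
  segment, subtracted from all OCR / ECAR values respectively;
* basal OCR = corrected baseline; maximal OCR = corrected FCCP segment;
* ATP-linked (oligomycin-sensitive) OCR = basal − corrected post-oligomycin;
* spare capacity = maximal − basal; basal ECAR analogous; OCR/ECAR ratio
  from corrected basal rates.

Wells where any corrected stage is negative are discarded and logged;
surviving rates are normalized by the cell count of the well.  Segment
rates are means excluding the first post-injection measurement (one-cycle
settle window), so an instrument cycle caught mid-transition does not bias
the plateau.

The PercevalHR summary averages the 490/405 nm (green/blue) ratio within
three phases delimited by the oligomycin and 2-deoxy-D-glucose injections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParameterError, PipelineError

SEGMENT_NAMES = ("baseline", "oligomycin", "fccp", "antimycin_rotenone_2dg")


class QCError(PipelineError):
    """All wells failed quality control."""


@dataclass(frozen=True)
class FluxStages:
    """Derived respiration/acidification quantities for one well."""

    basal_ocr: float
    atp_linked_ocr: float
    max_ocr: float
    spare_capacity: float
    basal_ecar: float
    ocr_ecar_ratio: float  # NaN when basal_ecar <= 0

    def as_dict(self) -> dict:
        return {
            "basal_ocr": self.basal_ocr,
            "atp_linked_ocr": self.atp_linked_ocr,
            "max_ocr": self.max_ocr,
            "spare_capacity": self.spare_capacity,
            "basal_ecar": self.basal_ecar,
            "ocr_ecar_ratio": self.ocr_ecar_ratio,
        }


@dataclass
class FluxPlate:
    """Long-format plate: one row per (well, measurement).

    ``data`` columns: well, time_min, segment (0..3), ocr, ecar, cell_count.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "time_min", "segment", "ocr", "ecar", "cell_count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"FluxPlate data missing columns: {sorted(missing)}")
        if (self.data["cell_count"] <= 0).any():
            raise ParameterError("cell_count must be > 0 for every well")

    @property
    def wells(self) -> list:
        return sorted(self.data["well"].unique())


def stages_from_segment_rates(ocr_rates, ecar_rates) -> FluxStages:
    """Stage arithmetic on four per-segment rates (the analytic core).

    ``ocr_rates`` / ``ecar_rates`` are the plateau rates of the four
    segments in schedule order.  Used both by the analysis (on measured
    segment means) and by the plate generator (on programmed plateaus), so
    the synthetic truth is by construction the same arithmetic.
    """
    ocr = [float(x) for x in ocr_rates]
    ecar = [float(x) for x in ecar_rates]
    if len(ocr) != 4 or len(ecar) != 4:
        raise ParameterError("need one rate per segment (4 segments)")
    if not all(np.isfinite(ocr)) or not all(np.isfinite(ecar)):
        raise ParameterError("segment rates must be finite")
    non_mito = ocr[3]
    non_glyc = ecar[3]
    basal = ocr[0] - non_mito
    post_oligo = ocr[1] - non_mito
    max_ocr = ocr[2] - non_mito
    basal_ecar = ecar[0] - non_glyc
    ratio = basal / basal_ecar if basal_ecar > 0 else float("nan")
    return FluxStages(
        basal_ocr=basal,
        atp_linked_ocr=basal - post_oligo,
        max_ocr=max_ocr,
        spare_capacity=max_ocr - basal,
        basal_ecar=basal_ecar,
        ocr_ecar_ratio=ratio,
    )


def _segment_means(sub: pd.DataFrame, column: str, settle_points: int) -> list:
    means = []
    for seg in range(4):
        vals = sub.loc[sub["segment"] == seg, column].to_numpy()
        if seg > 0:
            vals = vals[settle_points:]
        if vals.size == 0:
            raise ParameterError(
                f"segment '{SEGMENT_NAMES[seg]}' has no usable measurements "
                f"(settle window {settle_points})"
            )
        means.append(float(vals.mean()))
    return means


def compute_flux_stages(plate: FluxPlate, settle_points: int = 1, normalize: bool = True):
    """Per-well stages plus QC log; returns ``(stages, qc)``.

    ``stages`` maps well -> :class:`FluxStages` (normalized per cell when
    ``normalize``); ``qc`` is a DataFrame with one row per well recording
    whether it was kept and, if discarded, which stage was negative.
    Raises :class:`QCError` when every well is discarded.
    """
    segs = set(plate.data["segment"].unique())
    if segs != {0, 1, 2, 3}:
        raise ParameterError(f"plate must contain segments 0..3, got {sorted(segs)}")
    stages: dict = {}
    qc_rows = []
    for well in plate.wells:
        sub = plate.data[plate.data["well"] == well].sort_values("time_min")
        ocr_means = _segment_means(sub, "ocr", settle_points)
        ecar_means = _segment_means(sub, "ecar", settle_points)
        raw = stages_from_segment_rates(ocr_means, ecar_means)
        checked = {
            "basal_ocr": raw.basal_ocr,
            "atp_linked_ocr": raw.atp_linked_ocr,
            "max_ocr": raw.max_ocr,
            "spare_capacity": raw.spare_capacity,
            "basal_ecar": raw.basal_ecar,
        }
        negative = [k for k, v in checked.items() if v < 0]
        if negative:
            qc_rows.append({"well": well, "kept": False, "reason": f"negative {negative[0]}"})
            continue
        qc_rows.append({"well": well, "kept": True, "reason": ""})
        if normalize:
            n = float(sub["cell_count"].iloc[0])
            stages[well] = FluxStages(
                basal_ocr=raw.basal_ocr / n,
                atp_linked_ocr=raw.atp_linked_ocr / n,
                max_ocr=raw.max_ocr / n,
                spare_capacity=raw.spare_capacity / n,
                basal_ecar=raw.basal_ecar / n,
                ocr_ecar_ratio=raw.ocr_ecar_ratio,  # scale-free
            )
        else:
            stages[well] = raw
    qc = pd.DataFrame(qc_rows, columns=["well", "kept", "reason"])
    if not stages:
        raise QCError(f"all wells discarded by QC:\n{qc.to_string(index=False)}")
    return stages, qc


def stages_table(stages: dict, qc: pd.DataFrame) -> pd.DataFrame:
    """Flatten stage results and QC into one table (one row per well)."""
    rows = []
    for _, q in qc.iterrows():
        row = {"well": q["well"], "kept": q["kept"], "qc_reason": q["reason"]}
        if q["well"] in stages:
            row.update(stages[q["well"]].as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PercevalHR


@dataclass(frozen=True)
class PercevalSummary:
    """Phase means of the 490/405 nm ratio around the two injections."""

    baseline: float
    post_oligomycin: float
    post_2dg: float
    excluded_fraction: tuple  # per phase
    flagged_phases: tuple  # phase names with > 50% excluded samples

    def as_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "post_oligomycin": self.post_oligomycin,
            "post_2dg": self.post_2dg,
        }


def summarize_perceval(
    blue: np.ndarray,
    green: np.ndarray,
    times_s: np.ndarray,
    injection_times_s: tuple,
    settle_samples: int = 2,
) -> PercevalSummary:
    """Average green/blue per phase: [0, t1), [t1 + settle, t2), [t2 + settle, end].

    Samples with non-positive blue signal are excluded; a phase with more
    than half its samples excluded is reported as NaN and flagged.
    """
    blue = np.asarray(blue, dtype=float)
    green = np.asarray(green, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if blue.shape != green.shape or blue.shape != times.shape:
        raise ParameterError("blue, green and times must be aligned 1D series")
    t1, t2 = (float(t) for t in injection_times_s)
    if not (times[0] <= t1 < t2 <= times[-1]):
        raise ParameterError("injection times must be ordered and within the series")

    def phase_indices(lo_idx, hi_mask):
        idx = np.nonzero(hi_mask)[0]
        return idx[lo_idx:] if lo_idx else idx

    masks = [times < t1, (times >= t1) & (times < t2), times >= t2]
    skips = [0, settle_samples, settle_samples]
    names = ("baseline", "post_oligomycin", "post_2dg")
    means = []
    excluded = []
    flagged = []
    for name, mask, skip in zip(names, masks, skips):
        idx = np.nonzero(mask)[0][skip:]
        if idx.size == 0:
            raise ParameterError(f"phase '{name}' has no samples after the settle window")
        usable = blue[idx] > 0
        frac_excl = 1.0 - usable.mean()
        excluded.append(float(frac_excl))
        if frac_excl > 0.5:
            means.append(float("nan"))
            flagged.append(name)
        else:
            means.append(float(np.mean(green[idx][usable] / blue[idx][usable])))
    return PercevalSummary(
        baseline=means[0],
        post_oligomycin=means[1],
        post_2dg=means[2],
        excluded_fraction=tuple(excluded),
        flagged_phases=tuple(flagged),
    )
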