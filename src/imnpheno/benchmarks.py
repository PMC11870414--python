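"""Self-contained verification experiments over the whole pipeline.

Each function here re-runs one slice of the pipeline against a ground
truth the synthetic generators control — closed-form survival oracles,
brute-force likelihood maximization, or rendered-scene truth — and
returns plain numbers.  They back both the acceptance test suite and the
``scripts/acceptance.py`` report, so the two always measure the same
quantities the same way.

Every function takes a ``seed``; derived per-replicate seeds stay below
2**31.
"""

from __future__ import annotations

import math
import time

import numpy as np
from scipy.optimize import minimize_scalar

from .bioenergetics import compute_flux_stages, summarize_perceval
from .image_ops import subtract_background
from .mitochondria import (
    build_kymograph,
    extract_mito_tracks,
    measure_mito_morphology,
    measure_motility,
    segment_mitochondria,
)
from .morphometry import measure_neurites, measure_tdp43_localization, skeletonize_cell
from .pipeline import run_phenotyping, run_survival
from .survival import SeparationError, cox_fit, fit_km, Lifeline, logrank_statistic
from .synth import (
    FluxPlateSpec,
    KymographMovieSpec,
    PercevalSpec,
    PunctumSpec,
    SceneSpec,
    generate_flux_plate,
    generate_neurite_movie,
    generate_perceval_trace,
    generate_static_scene,
    generate_survival_experiment,
)
from .synth.scene import PIXEL_SIZE_40X


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k * 7_919 + 17) % (2**31 - 1)


# ---------------------------------------------------------------------------
# survival statistics


def km_hand_example() -> dict:
    """Product-limit estimate on the four-subject hand-computable dataset."""
    lls = [
        Lifeline("a", "g", 0.0, 1.0, 1),
        Lifeline("b", "g", 0.0, 2.0, 0),
        Lifeline("c", "g", 0.0, 3.0, 1),
        Lifeline("d", "g", 0.0, 4.0, 0),
    ]
    t0 = time.perf_counter()
    km = fit_km(lls)
    return {
        "survival_at_1": km.survival_at(1.0),
        "survival_at_3": km.survival_at(3.0),
        "elapsed_s": time.perf_counter() - t0,
        "n": 4,
    }


def _efron_loglik_reference(beta, durations, events, x):
    """Straightforwardly coded Efron partial log-likelihood (loops only)."""
    ll = 0.0
    for t in sorted({t for t, e in zip(durations, events) if e == 1}):
        D = [i for i in range(len(durations)) if durations[i] == t and events[i] == 1]
        R = [i for i in range(len(durations)) if durations[i] >= t]
        s_r = sum(math.exp(beta * x[i]) for i in R)
        s_d = sum(math.exp(beta * x[i]) for i in D)
        d = len(D)
        ll += sum(beta * x[i] for i in D)
        for l in range(d):
            ll -= math.log(s_r - (l / d) * s_d)
    return ll


def cox_vs_bruteforce(n_datasets: int = 200, seed: int = 0) -> dict:
    """Newton fit vs brute-force maximization on random tiny datasets.

    Datasets have <= 8 subjects and one binary covariate; degenerate draws
    (an arm without events, or a near-monotone likelihood) are redrawn so
    exactly ``n_datasets`` comparisons happen.
    """
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()
    diffs = []
    while len(diffs) < n_datasets:
        n = int(rng.integers(4, 9))
        x = rng.integers(0, 2, n).astype(float)
        durs = np.round(rng.exponential(10.0, n), 1) + 0.5
        evs = rng.integers(0, 2, n)
        if evs[x == 1].sum() == 0 or evs[x == 0].sum() == 0:
            continue
        try:
            fitted = cox_fit(durs, evs, x.reshape(-1, 1)).coef[0]
        except SeparationError:
            continue
        if abs(fitted) > 6:
            continue
        ref = minimize_scalar(
            lambda b: -_efron_loglik_reference(b, durs, evs, x),
            bounds=(-8.0, 8.0),
            method="bounded",
            options={"xatol": 1e-7},
        ).x
        diffs.append(abs(fitted - ref))
    return {
        "max_abs_diff": float(np.max(diffs)),
        "n": n_datasets,
        "elapsed_s": time.perf_counter() - t0,
    }


def cox_recovery(
    n_seeds: int = 20,
    n_per_group: int = 500,
    true_hr: float = 2.0,
    base_hazard: float = 0.05,
    censor_day: float = 34.0,
    seed: int = 0,
) -> dict:
    """Two-group exponential simulation: does the 95% CI cover ln(HR)?"""
    covered = 0
    estimates = []
    for k in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, k))
        x = np.repeat([0.0, 1.0], n_per_group)
        lam = base_hazard * np.exp(math.log(true_hr) * x)
        t = rng.exponential(1.0 / lam)
        ev = (t <= censor_day).astype(int)
        res = cox_fit(np.minimum(t, censor_day), ev, x.reshape(-1, 1))
        estimates.append(res.coef[0])
        if res.ci_lower[0] <= math.log(true_hr) <= res.ci_upper[0]:
            covered += 1
    return {
        "coverage": covered / n_seeds,
        "covered": covered,
        "n_seeds": n_seeds,
        "mean_loghr": float(np.mean(estimates)),
        "true_loghr": math.log(true_hr),
        "n": 2 * n_per_group,
    }


def logrank_type1(
    n_reps: int = 1000, n_per_group: int = 200, hazard: float = 0.05,
    censor_day: float = 34.0, alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Null rejection rate of the logrank test at level alpha."""
    rejections = 0
    for k in range(n_reps):
        rng = np.random.default_rng(_sub_seed(seed, k))
        t = rng.exponential(1.0 / hazard, 2 * n_per_group)
        ev = (t <= censor_day).astype(int)
        t = np.minimum(t, censor_day)
        _, p = logrank_statistic(
            t[:n_per_group], ev[:n_per_group], t[n_per_group:], ev[n_per_group:]
        )
        rejections += p < alpha
    return {
        "rejection_rate": rejections / n_reps,
        "alpha": alpha,
        "n_reps": n_reps,
        "binomial_se": math.sqrt(alpha * (1 - alpha) / n_reps),
        "n": n_per_group,
    }


# ---------------------------------------------------------------------------
# imaging pipeline


def _track_purity(tracks, truth, frame_days, pixel_size, max_dist_um=15.0):
    """Mean per-track purity: fraction of detections from the majority cell."""
    purities = []
    for track in tracks:
        owners = []
        for det in track.detections:
            best, best_d = None, max_dist_um / pixel_size
            for cell in truth.tracks:
                pos = cell.positions[det.frame]
                if not np.isfinite(pos[0]):
                    continue
                d = math.hypot(det.row - pos[0], det.col - pos[1])
                if d < best_d:
                    best, best_d = cell.cell_id, d
            owners.append(best)
        owners = [o for o in owners if o is not None]
        if len(owners) >= 2:
            majority = max(set(owners), key=owners.count)
            purities.append(owners.count(majority) / len(owners))
    return float(np.mean(purities)) if purities else float("nan")


def tracking_end_to_end(
    n_seeds: int = 20,
    n_per_group: int = 40,
    true_hr: float = 2.0,
    base_hazard: float = 0.03,
    dropout: float = 0.05,
    seed: int = 0,
) -> dict:
    """Full image chain: render movies, detect, track, fit Cox; CI coverage.

    Two groups (control vs mutant at the programmed hazard ratio), default
    imaging schedule D12-D46 every second day, 5% detection dropout.
    Reports the fraction of seeds whose Cox 95% CI covers ln(HR) and the
    mean identity purity of the extracted tracks.
    """
    from .survival import link_detections
    from .pipeline import detections_from_frames

    covered = 0
    purities = []
    estimates = []
    for k in range(n_seeds):
        sub = _sub_seed(seed, k)
        movies = generate_survival_experiment(
            {"control": base_hazard, "mutant": base_hazard * true_hr},
            n_per_group=n_per_group,
            seed=sub,
            dropout_prob=dropout,
        )
        frame_days = movies["control"][1].frame_days
        res = run_survival(
            {g: frames for g, (frames, _t) in movies.items()}, frame_days, seed=sub
        )
        estimates.append(res.cox.coef[0])
        if res.cox.ci_lower[0] <= math.log(true_hr) <= res.cox.ci_upper[0]:
            covered += 1
        # purity on the control movie of this replicate
        frames, truth = movies["control"]
        dets = detections_from_frames(frames)
        tracks = link_detections(dets, pixel_size=frames[0].pixel_size)
        purities.append(_track_purity(tracks, truth, frame_days, frames[0].pixel_size))
    return {
        "coverage": covered / n_seeds,
        "covered": covered,
        "n_seeds": n_seeds,
        "mean_loghr": float(np.mean(estimates)),
        "true_loghr": math.log(true_hr),
        "mean_purity": float(np.nanmean(purities)),
        "n": 2 * n_per_group,
    }


def classification_benchmark(n_seeds: int = 10, seed: int = 0) -> dict:
    """Per-class precision/recall of detect+classify on default scenes."""
    per_class: dict = {c: {"tp": 0, "fp": 0, "n_truth": 0} for c in ("iMN", "non_neuron", "dead")}
    for k in range(n_seeds):
        spec = SceneSpec(seed=_sub_seed(seed, k))
        channels, truth = generate_static_scene(spec)
        result = run_phenotyping(channels=channels)
        for cls in per_class:
            per_class[cls]["n_truth"] += len(truth.of_class(cls))
        for _, row in result.table.iterrows():
            best, best_d = None, 15.0
            for cell in truth.cells:
                d = math.hypot(
                    row.centroid_row - cell.centroid[0], row.centroid_col - cell.centroid[1]
                )
                if d < best_d:
                    best, best_d = cell, d
            cls = row["class"]
            if best is not None and best.cell_class == cls:
                per_class[cls]["tp"] += 1
            else:
                per_class[cls]["fp"] += 1
    out = {}
    for cls, c in per_class.items():
        out[f"{cls}_precision"] = c["tp"] / max(1, c["tp"] + c["fp"])
        out[f"{cls}_recall"] = c["tp"] / max(1, c["n_truth"])
    out["n"] = n_seeds * 50
    return out


def morphometry_benchmark(n_scenes: int = 5, seed: int = 0) -> dict:
    """Neurite length / branch recovery on noiseless cells; TDP-43 ratios.

    Length is compared as the mean relative error over all cells (about 50
    across the scenes); branch counts must match the generator exactly.
    TDP-43 cytosol/nucleus ratios 0.25 / 0.5 / 1.0 are measured at 5%
    intensity noise after background subtraction.
    """
    length_errs = []
    branch_exact = 0
    n_cells = 0
    for k in range(n_scenes):
        spec = SceneSpec(
            seed=_sub_seed(seed, k),
            n_imn=10,
            n_non_neuron=0,
            n_dead=0,
            noise_sigma=0.0,
            min_separation_um=40.0,
        )
        _, truth = generate_static_scene(spec)
        for cell in truth.of_class("iMN"):
            mask = truth.cell_labels == cell.cell_id
            soma = truth.soma_labels == cell.cell_id
            nm = measure_neurites(skeletonize_cell(mask, spec.pixel_size), soma, spec.pixel_size)
            length_errs.append(
                (nm.total_length_um - cell.neurite_total_length_um)
                / cell.neurite_total_length_um
            )
            branch_exact += nm.branch_count == cell.branch_count
            n_cells += 1
    tdp = {}
    for j, ratio in enumerate((0.25, 0.5, 1.0)):
        spec = SceneSpec(
            seed=_sub_seed(seed, 100 + j),
            n_imn=12,
            n_non_neuron=0,
            n_dead=0,
            tdp43_cyt_nuc_ratio=ratio,
            noise_sigma=5.0,  # 5% of the nuclear signal level
            min_separation_um=35.0,
        )
        channels, truth = generate_static_scene(spec)
        img = subtract_background(channels["tdp43"], radius=60)
        vals = [
            measure_tdp43_localization(
                img, truth.nucleus_labels == c.cell_id, truth.cell_labels == c.cell_id
            ).cyt_nuc_ratio
            for c in truth.of_class("iMN")
        ]
        tdp[ratio] = float(np.mean(vals))
    return {
        "mean_length_rel_err": float(np.mean(length_errs)),
        "branch_exact_fraction": branch_exact / n_cells,
        "tdp_ratio_rel_errs": {str(r): abs(v - r) / r for r, v in tdp.items()},
        "tdp_ratios_measured": {str(r): v for r, v in tdp.items()},
        "n": n_cells,
    }


def mitochondria_benchmark(seed: int = 0) -> dict:
    """Punctum count/area recovery and a programmed 2x TMRM group difference."""

    def scene(k, intensity):
        return SceneSpec(
            image_shape=(768, 768),
            pixel_size=PIXEL_SIZE_40X,
            n_imn=6,
            n_non_neuron=0,
            n_dead=0,
            neurite_length_um=20.0,
            min_separation_um=30.0,
            mito_intensity=intensity,
            noise_sigma=4.0,
            seed=_sub_seed(seed, k),
        )

    count_exact = 0
    n_cells = 0
    area_errs = []
    group_measured = []
    group_truth = []
    for g, intensity in enumerate((150.0, 300.0)):
        meas, tru = [], []
        for k in range(2):
            channels, truth = generate_static_scene(scene(10 * g + k, intensity))
            for cell in truth.of_class("iMN"):
                soma = truth.soma_labels == cell.cell_id
                mito = segment_mitochondria(channels["tmrm"], soma)
                m = measure_mito_morphology(mito, channels["tmrm"], soma)
                count_exact += m.mito_count == cell.mito_count
                n_cells += 1
                true_area = float(np.mean(cell.mito_areas_um2))
                area_errs.append(abs(m.mean_area_um2 - true_area) / true_area)
                meas.append(m.mean_mito_intensity)
                tru.append(cell.mito_mean_intensity)
        group_measured.append(float(np.mean(meas)))
        group_truth.append(float(np.mean(tru)))
    measured_ratio = group_measured[1] / group_measured[0]
    truth_ratio = group_truth[1] / group_truth[0]
    return {
        "count_exact_fraction": count_exact / n_cells,
        "max_area_rel_err": float(np.max(area_errs)),
        "tmrm_ratio_measured": measured_ratio,
        "tmrm_ratio_truth": truth_ratio,
        "tmrm_ratio_rel_err": abs(measured_ratio - truth_ratio) / truth_ratio,
        "n": n_cells,
    }


def motility_benchmark(seed: int = 0) -> dict:
    """Motile fraction (noiseless, exact) and speed recovery 0.1-1.0 µm/s."""
    stationary = tuple(PunctumSpec(start_um=4.0 * (i + 1)) for i in range(7))
    motile = tuple(
        PunctumSpec(start_um=32.0 + 4 * i, speed_um_s=0.04 + 0.005 * i) for i in range(3)
    )
    spec = KymographMovieSpec(puncta=stationary + motile, seed=_sub_seed(seed, 0))
    t0 = time.perf_counter()
    frames, truth = generate_neurite_movie(spec)
    kymo = build_kymograph(frames, spec.path_px, dt_s=spec.dt_s)
    tracks = extract_mito_tracks(kymo)
    metrics = measure_motility(tracks)
    elapsed = time.perf_counter() - t0

    speed_errs = {}
    for j, v in enumerate((0.1, 0.25, 0.5, 0.75, 1.0)):
        sp = KymographMovieSpec(
            puncta=(PunctumSpec(start_um=2.0, speed_um_s=v),), seed=_sub_seed(seed, j + 1)
        )
        fr, _ = generate_neurite_movie(sp)
        k = build_kymograph(fr, sp.path_px, dt_s=sp.dt_s)
        tr = extract_mito_tracks(k)
        speed_errs[str(v)] = abs(tr[0].avg_speed_um_s - v) / v
    return {
        "motile_fraction_measured": metrics.motile_fraction,
        "motile_fraction_truth": float(truth.motile.mean()),
        "n_tracks": metrics.n_tracks,
        "n_puncta": len(spec.puncta),
        "speed_rel_errs": speed_errs,
        "movie_frames": spec.n_frames,
        "movie_elapsed_s": elapsed,
        "n": len(spec.puncta),
    }


def flux_benchmark(seed: int = 0) -> dict:
    """Stage arithmetic on the constructed plateaus, and the QC discard rule."""
    plate, truth = generate_flux_plate(FluxPlateSpec(seed=_sub_seed(seed, 0)))
    stages, _ = compute_flux_stages(plate, normalize=False)
    s = stages["W1"]
    # well whose corrected basal is negative must be discarded
    bad_plate, _ = generate_flux_plate(
        FluxPlateSpec(ocr_plateaus=(15.0, 40.0, 150.0, 20.0), seed=_sub_seed(seed, 1))
    )
    import pandas as pd

    bad = bad_plate.data.copy()
    bad["well"] = bad["well"].str.replace("W", "B")
    from .bioenergetics import FluxPlate

    merged = FluxPlate(pd.concat([plate.data, bad], ignore_index=True))
    merged_stages, qc = compute_flux_stages(merged)
    discarded = qc[~qc["kept"]]["well"].tolist()
    return {
        "basal_ocr": s.basal_ocr,
        "atp_linked_ocr": s.atp_linked_ocr,
        "max_ocr": s.max_ocr,
        "spare_capacity": s.spare_capacity,
        "basal_ecar": s.basal_ecar,
        "ocr_ecar_ratio": s.ocr_ecar_ratio,
        "negative_wells_discarded": len(discarded) == 6
        and all(w.startswith("B") for w in discarded),
        "n": len(plate.wells),
    }


def perceval_benchmark(seed: int = 0) -> dict:
    """Exact unit ratios for identical channels; 2DG decline at 1% noise."""
    n = 300
    t = np.arange(n) * 5.0
    sig = np.full(n, 100.0)
    exact = summarize_perceval(sig, sig, t, (300.0, 900.0))
    spec = PercevalSpec(dg_shift=-0.4, noise_sigma=1.0, seed=_sub_seed(seed, 0))
    blue, green, times, truth_ratios = generate_perceval_trace(spec)
    s = summarize_perceval(blue, green, times, (300.0, 900.0))
    return {
        "identical_channels_ratios": [exact.baseline, exact.post_oligomycin, exact.post_2dg],
        "post_2dg_measured": s.post_2dg,
        "post_2dg_truth": truth_ratios[2],
        "post_2dg_rel_err": abs(s.post_2dg - truth_ratios[2]) / truth_ratios[2],
        "n": n,
    }
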