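"""Generator contracts: determinism, conservation, programmed statistics."""

import math

import numpy as np
import pytest

from imnpheno.core import ParameterError
from imnpheno.bioenergetics import compute_flux_stages
from imnpheno.synth import (
    FluxPlateSpec,
    KymographMovieSpec,
    PercevalSpec,
    PlacementError,
    PunctumSpec,
    SceneSpec,
    TimeLapseSpec,
    generate_flux_plate,
    generate_neurite_movie,
    generate_perceval_trace,
    generate_static_scene,
    generate_time_lapse,
)
from imnpheno.synth.timelapse import default_timelapse_scene, _sample_death_day


class TestStaticScene:
    def test_counts_per_class_match_spec(self):
        spec = SceneSpec(n_imn=10, n_non_neuron=5, n_dead=3, seed=1)
        _, truth = generate_static_scene(spec)
        assert truth.class_counts == {"iMN": 10, "non_neuron": 5, "dead": 3}

    def test_same_spec_same_seed_bit_identical(self):
        spec = SceneSpec(n_imn=5, n_non_neuron=3, n_dead=2, seed=42)
        a, _ = generate_static_scene(spec)
        b, _ = generate_static_scene(spec)
        for name in a:
            assert np.array_equal(a[name].pixels, b[name].pixels)

    def test_noiseless_background_outside_cells(self):
        spec = SceneSpec(n_imn=4, n_non_neuron=2, n_dead=2, noise_sigma=0.0, seed=3)
        channels, truth = generate_static_scene(spec)
        outside = truth.cell_labels == 0
        assert np.all(channels["egfp"].pixels[outside] == spec.background)

    def test_conservation_every_cell_has_pixels_and_masks_disjoint(self, default_scene):
        _, _, truth = default_scene
        for cell in truth.cells:
            assert np.any(truth.cell_labels == cell.cell_id)
        # disjointness is guaranteed by a single integer label raster, but the
        # soma raster must nest inside the cell raster
        soma_on = truth.soma_labels > 0
        assert np.all(truth.cell_labels[soma_on] == truth.soma_labels[soma_on])

    def test_placement_error_names_constraint(self):
        spec = SceneSpec(image_shape=(128, 128), n_imn=40, n_non_neuron=0, n_dead=0, seed=0)
        with pytest.raises(PlacementError):
            generate_static_scene(spec)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_imn": -1},
            {"pixel_size": 0.0},
            {"tdp43_cyt_nuc_ratio": 0.0},
            {"branch_prob": 1.5},
            {"nonneuron_axes_um": (10.0, 6.0)},  # axis ratio < 2
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SceneSpec(**kwargs)


class TestTimeLapse:
    def test_default_schedule_has_18_frames(self):
        spec = TimeLapseSpec()
        assert len(spec.frame_days) == 18
        assert spec.frame_days[0] == 12.0 and spec.frame_days[-1] == 46.0
        scene = default_timelapse_scene(n_imn=5, seed=2)
        frames, truth = generate_time_lapse(TimeLapseSpec(seed=2), scene)
        assert len(frames) == 18

    def test_zero_hazard_all_censored(self):
        scene = default_timelapse_scene(n_imn=8, seed=4)
        _, truth = generate_time_lapse(TimeLapseSpec(hazard_per_day=0.0, seed=4), scene)
        assert all(not t.event_observed for t in truth.imn_tracks())

    def test_dead_cell_never_reappears(self):
        scene = default_timelapse_scene(n_imn=20, seed=5)
        _, truth = generate_time_lapse(TimeLapseSpec(hazard_per_day=0.1, seed=5), scene)
        for track in truth.imn_tracks():
            dead_from = np.searchsorted(np.array(truth.frame_days), track.death_day)
            assert not track.rendered[dead_from:].any()

    def test_death_fraction_matches_exponential_cdf(self):
        # closed-form oracle: P(death within window) = 1 - exp(-lambda * w)
        lam, window, n = 0.05, 34.0, 1000
        rng = np.random.default_rng(9)
        deaths = [_sample_death_day(rng, 12.0, lam, 46.0) for _ in range(n)]
        frac = np.mean([math.isfinite(d) for d in deaths])
        p = 1.0 - math.exp(-lam * window)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se

    def test_empty_schedule_rejected(self):
        with pytest.raises(ParameterError):
            TimeLapseSpec(frame_days=())
        with pytest.raises(ParameterError):
            TimeLapseSpec(frame_days=(12.0,))


class TestNeuriteMovie:
    def test_default_frame_count_198(self):
        spec = KymographMovieSpec()
        assert spec.n_frames == 198

    def test_stationary_puncta_not_motile(self):
        spec = KymographMovieSpec(
            puncta=(PunctumSpec(start_um=10.0), PunctumSpec(start_um=30.0)), seed=1
        )
        _, truth = generate_neurite_movie(spec)
        assert not truth.motile.any()

    def test_constant_velocity_kinematics_exact(self):
        v = 0.1
        spec = KymographMovieSpec(puncta=(PunctumSpec(start_um=2.0, speed_um_s=v),), seed=1)
        _, truth = generate_neurite_movie(spec)
        pos = truth.positions_um[0]
        expected = 2.0 + v * truth.frame_times_s
        assert np.allclose(pos, expected)
        assert np.all(np.diff(pos) >= 0)

    def test_clamped_at_path_end_and_flagged(self):
        spec = KymographMovieSpec(puncta=(PunctumSpec(start_um=60.0, speed_um_s=1.0),), seed=1)
        _, truth = generate_neurite_movie(spec)
        assert truth.clamped[0]
        assert truth.positions_um[0].max() <= truth.path_length_um

    def test_negative_speed_rejected(self):
        with pytest.raises(ParameterError):
            PunctumSpec(start_um=1.0, speed_um_s=-0.5)


class TestFluxPlate:
    def test_truth_stage_arithmetic(self):
        _, truth = generate_flux_plate(FluxPlateSpec())
        s = truth["W1"]
        assert (s.basal_ocr, s.atp_linked_ocr, s.max_ocr, s.spare_capacity) == (
            80.0,
            60.0,
            130.0,
            50.0,
        )

    def test_noiseless_measured_rates_equal_plateaus(self):
        plate, truth = generate_flux_plate(FluxPlateSpec(seed=2))
        stages, _ = compute_flux_stages(plate, normalize=False)
        for well in truth:
            assert stages[well].as_dict() == pytest.approx(truth[well].as_dict())

    def test_six_replicate_wells(self):
        plate, _ = generate_flux_plate(FluxPlateSpec())
        assert len(plate.wells) == 6

    def test_missing_segment_rate_rejected(self):
        with pytest.raises(ParameterError):
            FluxPlateSpec(ocr_plateaus=(100.0, 40.0, 150.0))


class TestPerceval:
    def test_sample_count_300(self):
        assert PercevalSpec().n_samples == 300

    def test_green_equals_blue_when_ratio_one(self):
        blue, green, _, ratios = generate_perceval_trace(
            PercevalSpec(baseline_ratio=1.0, oligo_shift=0.0, dg_shift=0.0)
        )
        assert np.allclose(green, blue)
        assert ratios == (1.0, 1.0, 1.0)

    def test_post_2dg_shift_applied_to_baseline(self):
        _, _, _, ratios = generate_perceval_trace(PercevalSpec(dg_shift=-0.4))
        assert ratios[2] == pytest.approx(0.6)

    def test_nonpositive_phase_ratio_rejected(self):
        with pytest.raises(ParameterError):
            PercevalSpec(dg_shift=-1.0)
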