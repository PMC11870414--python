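"""Mitochondrial segmentation, morphology and kymograph motility."""

import numpy as np
import pytest

from imnpheno.core import Image2D, LabelMask, ParameterError
from imnpheno.mitochondria import (
    Kymograph,
    build_kymograph,
    extract_mito_tracks,
    measure_mito_morphology,
    measure_motility,
    segment_mitochondria,
)
from imnpheno.synth import (
    KymographMovieSpec,
    PunctumSpec,
    SceneSpec,
    generate_neurite_movie,
    generate_static_scene,
)
from imnpheno.synth.scene import PIXEL_SIZE_40X


@pytest.fixture(scope="module")
def mito_scene():
    spec = SceneSpec(
        image_shape=(768, 768),
        pixel_size=PIXEL_SIZE_40X,
        n_imn=5,
        n_non_neuron=0,
        n_dead=0,
        neurite_length_um=20.0,
        min_separation_um=30.0,
        noise_sigma=4.0,
        seed=13,
    )
    channels, truth = generate_static_scene(spec)
    return spec, channels, truth


class TestSegmentMitochondria:
    def test_zero_signal_gives_zero_mitochondria(self):
        tmrm = Image2D(np.zeros((64, 64)), PIXEL_SIZE_40X, "tmrm")
        mask = np.zeros((64, 64), dtype=bool)
        mask[16:48, 16:48] = True
        assert segment_mitochondria(tmrm, mask).n_labels == 0

    def test_generated_puncta_counted_exactly(self, mito_scene):
        spec, channels, truth = mito_scene
        for cell in truth.of_class("iMN"):
            soma = truth.soma_labels == cell.cell_id
            mito = segment_mitochondria(channels["tmrm"], soma)
            assert mito.n_labels == cell.mito_count

    def test_punctum_outside_mask_not_labelled(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[:64, :64]
        img[(rr - 16) ** 2 + (cc - 16) ** 2 <= 9] = 200.0  # inside
        img[(rr - 48) ** 2 + (cc - 48) ** 2 <= 9] = 200.0  # outside
        cell = np.zeros((64, 64), dtype=bool)
        cell[:32, :32] = True
        mito = segment_mitochondria(Image2D(img, PIXEL_SIZE_40X, "tmrm"), cell)
        assert mito.n_labels == 1
        assert not np.any(mito.labels[~cell])


class TestMitoMorphology:
    def _discs(self, n=4, radius=3):
        img = np.zeros((96, 96))
        lab = np.zeros((96, 96), dtype=np.int32)
        rr, cc = np.mgrid[:96, :96]
        for i in range(n):
            d = (rr - 20 - 18 * i) ** 2 + (cc - 48) ** 2 <= radius**2
            img[d] = 100.0
            lab[d] = i + 1
        return Image2D(img, 1.0, "tmrm"), LabelMask(lab, 1.0)

    def test_identical_discs_mean_area(self):
        tmrm, mito = self._discs()
        cell = np.ones((96, 96), dtype=bool)
        m = measure_mito_morphology(mito, tmrm, cell)
        area = (mito.labels == 1).sum()
        assert m.mito_count == 4
        assert m.mean_area_um2 == pytest.approx(area)

    def test_gain_linearity(self):
        tmrm, mito = self._discs()
        cell = np.ones((96, 96), dtype=bool)
        a = measure_mito_morphology(mito, tmrm, cell)
        b = measure_mito_morphology(mito, tmrm.with_pixels(tmrm.pixels * 2), cell)
        assert b.whole_cell_tmrm == pytest.approx(2 * a.whole_cell_tmrm)
        assert b.mean_mito_intensity == pytest.approx(2 * a.mean_mito_intensity)
        assert (b.mito_count, b.mean_area_um2) == (a.mito_count, a.mean_area_um2)

    def test_mean_area_recovered_within_10_percent(self, mito_scene):
        spec, channels, truth = mito_scene
        for cell in truth.of_class("iMN"):
            soma = truth.soma_labels == cell.cell_id
            mito = segment_mitochondria(channels["tmrm"], soma)
            m = measure_mito_morphology(mito, channels["tmrm"], soma)
            assert m.mean_area_um2 == pytest.approx(np.mean(cell.mito_areas_um2), rel=0.10)

    def test_empty_cell_mask_rejected(self):
        tmrm, mito = self._discs()
        with pytest.raises(ParameterError):
            measure_mito_morphology(mito, tmrm, np.zeros((96, 96), dtype=bool))


class TestKymograph:
    def test_dims_are_path_length_by_frames(self):
        spec = KymographMovieSpec(puncta=(PunctumSpec(start_um=10.0),), seed=1)
        frames, _ = generate_neurite_movie(spec)
        kymo = build_kymograph(frames, spec.path_px, dt_s=spec.dt_s)
        L = int(spec.path_length_um / spec.pixel_size) + 1
        assert kymo.data.shape == (L, spec.n_frames)

    def test_static_punctum_traces_constant_row(self):
        spec = KymographMovieSpec(puncta=(PunctumSpec(start_um=20.0),), seed=1)
        frames, _ = generate_neurite_movie(spec)
        kymo = build_kymograph(frames, spec.path_px, dt_s=spec.dt_s)
        rows = kymo.data.argmax(axis=0)
        assert np.ptp(rows) <= 1

    def test_moving_punctum_slope_matches_velocity(self):
        v = 0.1
        spec = KymographMovieSpec(puncta=(PunctumSpec(start_um=2.0, speed_um_s=v),), seed=1)
        frames, _ = generate_neurite_movie(spec)
        kymo = build_kymograph(frames, spec.path_px, dt_s=spec.dt_s)
        rows = kymo.data.argmax(axis=0).astype(float)
        slope_px = np.polyfit(np.arange(rows.size), rows, 1)[0]
        assert slope_px * kymo.dx_um / kymo.dt_s == pytest.approx(v, rel=0.05)

    def test_even_width_rejected(self):
        spec = KymographMovieSpec(puncta=(), seed=1)
        frames, _ = generate_neurite_movie(spec)
        with pytest.raises(ParameterError):
            build_kymograph(frames, spec.path_px, width_px=4)


class TestTracksAndMotility:
    def _kymo_tracks(self, puncta, seed=2):
        spec = KymographMovieSpec(puncta=puncta, seed=seed)
        frames, truth = generate_neurite_movie(spec)
        kymo = build_kymograph(frames, spec.path_px, dt_s=spec.dt_s)
        return extract_mito_tracks(kymo), truth

    def test_stationary_punctum_not_motile(self):
        tracks, _ = self._kymo_tracks((PunctumSpec(start_um=30.0),))
        assert len(tracks) == 1
        assert not tracks[0].motile
        assert tracks[0].total_distance_um <= 1.0

    def test_track_conservation_and_no_switches(self):
        # two puncta always >= 10 µm apart
        tracks, _ = self._kymo_tracks(
            (PunctumSpec(start_um=10.0), PunctumSpec(start_um=40.0, speed_um_s=0.04))
        )
        assert len(tracks) == 2
        for t in tracks:
            steps = np.abs(np.diff(t.positions_um[np.isfinite(t.positions_um)]))
            assert steps.max() <= 1.0  # smooth: no identity jumps

    @pytest.mark.parametrize("v", [0.1, 0.5, 1.0])
    def test_programmed_speed_recovered(self, v):
        tracks, _ = self._kymo_tracks((PunctumSpec(start_um=2.0, speed_um_s=v),))
        assert len(tracks) == 1
        assert tracks[0].avg_speed_um_s == pytest.approx(v, rel=0.10)

    def test_retrograde_direction_sign(self):
        tracks, _ = self._kymo_tracks((PunctumSpec(start_um=60.0, speed_um_s=0.05, direction=-1),))
        assert tracks[0].net_displacement_um < 0
        assert tracks[0].retro_distance_um > 0
        assert tracks[0].antero_distance_um <= 1.0

    def test_motility_summary(self):
        tracks, truth = self._kymo_tracks(
            (PunctumSpec(start_um=10.0), PunctumSpec(start_um=40.0, speed_um_s=0.04))
        )
        m = measure_motility(tracks)
        assert m.motile_fraction == pytest.approx(0.5)
        assert m.retro_total_um == pytest.approx(0.0, abs=0.5)

    def test_empty_tracks_rejected(self):
        with pytest.raises(ParameterError):
            measure_motility([])
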