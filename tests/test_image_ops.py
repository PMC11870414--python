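"""Preprocessing, blob detection, EQ construction and watershed contracts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from imnpheno.core import DimensionError, Image2D, LabelMask, ParameterError
from imnpheno.image_ops import (
    BlobParams,
    detect_blobs,
    make_eq_image,
    pair_nuclei_to_cells,
    segment_cells_watershed,
    subtract_background,
)


def _img(arr, px=1.0, ch=""):
    return Image2D(np.asarray(arr, dtype=float), pixel_size=px, channel=ch)


class TestSubtractBackground:
    def test_flat_image_maps_to_zero(self):
        out = subtract_background(_img(np.full((128, 128), 37.0)), radius=20)
        assert np.allclose(out.pixels, 0.0, atol=1e-9)

    def test_small_disc_preserved(self):
        img = np.full((160, 160), 10.0)
        rr, cc = np.mgrid[:160, :160]
        disc = (rr - 80) ** 2 + (cc - 80) ** 2 <= 36
        img[disc] += 100.0
        out = subtract_background(_img(img), radius=40, smooth_sigma=0.0)
        assert out.pixels.max() == pytest.approx(100.0, rel=0.05)

    def test_idempotent_on_isolated_objects(self):
        img = np.full((160, 160), 10.0)
        rr, cc = np.mgrid[:160, :160]
        img[(rr - 60) ** 2 + (cc - 90) ** 2 <= 25] += 80.0
        once = subtract_background(_img(img), radius=40, smooth_sigma=0.0)
        twice = subtract_background(once, radius=40, smooth_sigma=0.0)
        assert np.allclose(once.pixels, twice.pixels, atol=1.0)

    def test_radius_exceeding_extent_rejected(self):
        with pytest.raises(ParameterError):
            subtract_background(_img(np.zeros((64, 64))), radius=64)
        with pytest.raises(ParameterError):
            subtract_background(_img(np.zeros((64, 64))), radius=0)


class TestDetectBlobs:
    def test_blank_image_gives_empty_mask(self):
        mask = detect_blobs(_img(np.zeros((64, 64))), BlobParams())
        assert mask.n_labels == 0

    def test_single_soma_detected_with_subpixel_centroid(self):
        # radius-5 µm disc at SNR 10
        rng = np.random.default_rng(0)
        px = 0.345
        img = np.full((256, 256), 10.0)
        rr, cc = np.mgrid[:256, :256]
        img[(rr - 120.3) ** 2 + (cc - 140.7) ** 2 <= (5.0 / px) ** 2] += 100.0
        img += rng.normal(0, 10.0, img.shape)
        mask = detect_blobs(_img(np.clip(img, 0, None), px=px), BlobParams(blur_sigma=2.0))
        assert mask.n_labels == 1
        com = np.argwhere(mask.labels == 1).mean(axis=0)
        assert np.hypot(com[0] - 120.3, com[1] - 140.7) <= 1.0

    def test_small_objects_excluded_by_area(self):
        img = np.zeros((128, 128))
        img[60:62, 60:62] = 100.0  # 4 px -> 4 µm² at 1 µm/px, below min_area 20
        mask = detect_blobs(
            _img(img), BlobParams(blur_sigma=0.0, threshold_method="fixed", threshold_value=50)
        )
        assert mask.n_labels == 0

    def test_labels_contiguous_in_raster_order(self):
        img = np.zeros((128, 128))
        for r, c in ((100, 20), (20, 100), (60, 60)):
            rr, cc = np.mgrid[:128, :128]
            img[(rr - r) ** 2 + (cc - c) ** 2 <= 36] = 100.0
        mask = detect_blobs(
            _img(img),
            BlobParams(blur_sigma=0.0, threshold_method="fixed", threshold_value=50,
                       min_area_um2=10.0),
        )
        assert list(mask.label_ids) == [1, 2, 3]
        first = np.argwhere(mask.labels == 1).mean(axis=0)
        assert first[0] == pytest.approx(20, abs=1)


class TestEqImage:
    def test_commutative(self):
        rng = np.random.default_rng(1)
        a, b = _img(rng.random((64, 64))), _img(rng.random((64, 64)))
        assert np.allclose(make_eq_image(a, b).pixels, make_eq_image(b, a).pixels)

    def test_bounded_by_two(self):
        rng = np.random.default_rng(2)
        out = make_eq_image(_img(rng.random((64, 64))), _img(rng.random((64, 64))))
        assert out.pixels.max() <= 2.0 + 1e-12

    def test_rank_preserving(self):
        # distinct values: equalization is monotone, so ranks are unchanged
        rng = np.random.default_rng(3)
        vals = rng.permutation(64 * 64).astype(float).reshape(64, 64)
        img = _img(vals)
        eq = make_eq_image(img, _img(np.zeros((64, 64))))
        rho = spearmanr(vals.ravel(), eq.pixels.ravel()).statistic
        assert rho == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            make_eq_image(_img(np.zeros((32, 32))), _img(np.zeros((64, 64))))


class TestWatershed:
    def _dumbbell(self):
        # two Gaussian lobes; the intensity saddle (neck minimum) sits at
        # the midpoint col 48, where the watershed boundary must land
        rr, cc = np.mgrid[:64, :96]
        d1 = (rr - 32.0) ** 2 + (cc - 28.0) ** 2
        d2 = (rr - 32.0) ** 2 + (cc - 68.0) ** 2
        img = 100.0 * np.maximum(np.exp(-d1 / 288.0), np.exp(-d2 / 288.0))
        return _img(img)

    def test_one_seed_one_blob(self):
        terrain = self._dumbbell()
        seeds = np.zeros((64, 96), dtype=np.int32)
        seeds[32, 28] = 1
        out = segment_cells_watershed(LabelMask(seeds), terrain, fg_threshold=10.0)
        assert out.n_labels == 1
        assert np.array_equal(out.labels > 0, terrain.pixels >= 10.0)

    def test_dumbbell_splits_near_neck(self):
        terrain = self._dumbbell()
        seeds = np.zeros((64, 96), dtype=np.int32)
        seeds[32, 28] = 1
        seeds[32, 68] = 2
        out = segment_cells_watershed(LabelMask(seeds), terrain, fg_threshold=10.0)
        assert out.n_labels == 2
        boundary_cols = [
            c
            for r in range(64)
            for c in range(95)
            if out.labels[r, c] == 1 and out.labels[r, c + 1] == 2
        ]
        assert all(abs(c - 48) <= 2 for c in boundary_cols)

    def test_regions_partition_foreground(self):
        terrain = self._dumbbell()
        seeds = np.zeros((64, 96), dtype=np.int32)
        seeds[32, 28] = 1
        seeds[32, 68] = 2
        out = segment_cells_watershed(LabelMask(seeds), terrain, fg_threshold=10.0)
        fg = terrain.pixels >= 10.0
        assert np.array_equal(out.labels > 0, fg)  # union = foreground (seeds inside)

    def test_region_count_equals_seed_count(self):
        rng = np.random.default_rng(4)
        terrain = _img(rng.random((64, 64)) + 1.0)
        seeds = np.zeros((64, 64), dtype=np.int32)
        for i, (r, c) in enumerate(rng.integers(5, 59, size=(5, 2)), start=1):
            seeds[r, c] = i
        out = segment_cells_watershed(LabelMask(seeds), terrain, fg_threshold=0.5)
        assert out.n_labels == 5

    def test_no_seeds_rejected(self):
        with pytest.raises(ParameterError):
            segment_cells_watershed(
                LabelMask(np.zeros((8, 8), dtype=np.int32)), _img(np.ones((8, 8))), 0.5
            )


class TestNucleusPairing:
    def _masks(self):
        cells = np.zeros((32, 32), dtype=np.int32)
        cells[:, :16] = 1
        cells[:, 16:] = 2
        return cells

    def test_nucleus_inside_cell_paired(self):
        cells = self._masks()
        nuc = np.zeros((32, 32), dtype=np.int32)
        nuc[10:14, 4:8] = 1
        res = pair_nuclei_to_cells(LabelMask(nuc), LabelMask(cells))
        assert res.nucleus_to_cell == {1: 1}

    def test_nucleus_on_background_unpaired(self):
        cells = np.zeros((32, 32), dtype=np.int32)
        cells[:8, :8] = 1
        nuc = np.zeros((32, 32), dtype=np.int32)
        nuc[20:24, 20:24] = 1
        res = pair_nuclei_to_cells(LabelMask(nuc), LabelMask(cells))
        assert res.nucleus_to_cell == {} and res.unpaired_nuclei == (1,)

    def test_majority_overlap_wins(self):
        cells = self._masks()
        nuc = np.zeros((32, 32), dtype=np.int32)
        nuc[10:20, 9:19] = 1  # 70 px in cell 1, 30 px in cell 2
        res = pair_nuclei_to_cells(LabelMask(nuc), LabelMask(cells))
        assert res.nucleus_to_cell[1] == 1

    def test_two_nuclei_in_one_cell_flagged(self):
        cells = self._masks()
        nuc = np.zeros((32, 32), dtype=np.int32)
        nuc[4:8, 4:8] = 1
        nuc[20:24, 4:8] = 2
        res = pair_nuclei_to_cells(LabelMask(nuc), LabelMask(cells))
        assert res.multi_nucleus_cells == (1,)
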