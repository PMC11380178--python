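"""Operator-level checks against brute-force oracles and morphology laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from myoquant.imageproc import (
    LabelMap,
    Micrograph,
    binary_close,
    binary_dilate,
    binary_erode,
    despeckle,
    fill_holes,
    gaussian_blur,
    label_particles,
    otsu_threshold,
    size_filter,
    watershed_split,
)

from .conftest import random_mask
from . import oracles

HYPO = settings(deadline=None, max_examples=25, derandomize=True)


# ---------------------------------------------------------------------------
# gaussian_blur

class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 7.5)
        for sigma in (0.5, 1.0, 3.0):
            np.testing.assert_allclose(gaussian_blur(img, sigma), img, atol=1e-12)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((9, 9))
        np.testing.assert_array_equal(gaussian_blur(img, 0.0), img)

    def test_impulse_mass_conserved(self):
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        assert gaussian_blur(img, 1.0).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_convolution_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((5, 5)) * 100
        ours = gaussian_blur(img, 1.0)
        ref = oracles.dense_gaussian_blur(img, 1.0)
        assert np.max(np.abs(ours - ref)) < 1e-9

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), -1.0)


# ---------------------------------------------------------------------------
# otsu_threshold

class TestOtsu:
    def test_two_level_image(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 200.0
        res = otsu_threshold(img)
        assert not res.degenerate
        np.testing.assert_array_equal(res.mask, img == 200.0)

    def test_constant_image_degenerate(self):
        res = otsu_threshold(np.full((8, 8), 3.0))
        assert res.degenerate
        assert res.mask.sum() == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of two intensity populations plus outliers
        img = np.concatenate([
            rng.normal(40, 10, 200), rng.normal(180, 25, 100),
            rng.uniform(0, 255, 20),
        ]).reshape(16, 20)
        _, ref_mask = oracles.exhaustive_otsu(img)
        res = otsu_threshold(img)
        np.testing.assert_array_equal(res.mask, ref_mask)
        np.testing.assert_array_equal(res.mask, img > res.threshold)

    def test_known_trimodal_histogram(self):
        # 10 px at 10, 5 px at 100, 5 px at 200: the best cut separates
        # the low population from the two high ones
        img = np.array([10.0] * 10 + [100.0] * 5 + [200.0] * 5).reshape(4, 5)
        cut, ref_mask = oracles.exhaustive_otsu(img)
        res = otsu_threshold(img)
        np.testing.assert_array_equal(res.mask, ref_mask)
        assert res.threshold < cut <= 100.0


# ---------------------------------------------------------------------------
# despeckle / morphology vs set-definition oracles

class TestMorphologyOracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_despeckle_is_3x3_median(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng)
        np.testing.assert_array_equal(despeckle(mask), oracles.median3x3(mask))

    def test_despeckle_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert despeckle(mask).sum() == 0

    def test_despeckle_keeps_solid_rectangle_interior(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 2:10] = True
        assert despeckle(mask)[4:8, 3:9].all()

    @pytest.mark.parametrize("seed", range(8))
    def test_dilate_matches_set_union_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = random_mask(rng)
        for k in (1, 2):
            np.testing.assert_array_equal(binary_dilate(mask, k), oracles.set_dilate(mask, k))

    @pytest.mark.parametrize("seed", range(8))
    def test_erode_matches_set_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        mask = random_mask(rng)
        np.testing.assert_array_equal(binary_erode(mask, 1), oracles.set_erode(mask, 1))

    @pytest.mark.parametrize("seed", range(8))
    def test_close_matches_composition_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        mask = random_mask(rng)
        ref = oracles.set_erode(oracles.set_dilate(mask, 1), 1)
        np.testing.assert_array_equal(binary_close(mask), ref)

    def test_single_pixel_dilates_to_square(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert binary_dilate(mask, 1).sum() == 9

    def test_dilate_erode_roundtrip_on_interior_convex_solid(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[6:14, 5:15] = True
        k = 2
        np.testing.assert_array_equal(binary_erode(binary_dilate(mask, k), k), mask)

    def test_close_bridges_one_pixel_gap(self):
        mask = np.zeros((8, 11), dtype=bool)
        mask[2:6, 1:5] = True
        mask[2:6, 6:10] = True
        closed = binary_close(mask)
        assert closed[2:6, 5].all()

    def test_iterations_zero_is_identity(self):
        rng = np.random.default_rng(1)
        mask = random_mask(rng)
        np.testing.assert_array_equal(binary_dilate(mask, 0), mask)
        np.testing.assert_array_equal(binary_erode(mask, 0), mask)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            binary_dilate(np.zeros((3, 3), dtype=bool), -1)


class TestMorphologyLaws:
    """Algebraic properties of the binary operators (seeded random masks)."""

    @HYPO
    @given(st.integers(0, 10_000))
    def test_erode_dilate_duality_on_padded_domain(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.pad(random_mask(rng, (16, 16)), 1, constant_values=False)
        eroded = binary_erode(mask, 1)
        dual = ~binary_dilate(~mask, 1)
        np.testing.assert_array_equal(eroded[1:-1, 1:-1], dual[1:-1, 1:-1])

    @HYPO
    @given(st.integers(0, 10_000))
    def test_close_and_fill_idempotent_on_outputs(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng, (16, 16))
        for op in (binary_close, fill_holes):
            once = op(mask)
            np.testing.assert_array_equal(op(once), once)

    def test_despeckle_stable_on_fixed_points(self):
        # a 2-D median is only guaranteed stable on its fixed points,
        # e.g. large uniform regions with straight boundaries
        mask = np.zeros((16, 16), dtype=bool)
        mask[:, 8:] = True
        np.testing.assert_array_equal(despeckle(mask), mask)
        np.testing.assert_array_equal(despeckle(despeckle(mask)), despeckle(mask))

    @HYPO
    @given(st.integers(0, 10_000))
    def test_extensivity_and_inclusion_preservation(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng, (16, 16))
        sub = mask & random_mask(rng, (16, 16))
        assert (mask | binary_dilate(mask, 1)).sum() == binary_dilate(mask, 1).sum()
        assert (binary_erode(mask, 1) & mask).sum() == binary_erode(mask, 1).sum()
        assert not (binary_dilate(sub, 1) & ~binary_dilate(mask, 1)).any()
        assert not (binary_erode(sub, 1) & ~binary_erode(mask, 1)).any()


# ---------------------------------------------------------------------------
# fill_holes

class TestFillHoles:
    def test_ring_becomes_disc(self):
        yy, xx = np.mgrid[0:21, 0:21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        ring = (r2 <= 64) & (r2 >= 36)
        filled = fill_holes(ring)
        assert filled[10, 10]
        assert filled.sum() > ring.sum()

    def test_no_enclosed_background_is_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:8] = True
        np.testing.assert_array_equal(fill_holes(mask), mask)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        mask = random_mask(rng)
        np.testing.assert_array_equal(fill_holes(mask), oracles.bfs_fill_holes(mask))


# ---------------------------------------------------------------------------
# watershed_split

class TestWatershedSplit:
    def test_empty_mask(self):
        out = watershed_split(np.zeros((10, 10), dtype=bool), 5)
        assert out.n_labels == 0

    def test_single_disc_single_label(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        out = watershed_split(disc, 5)
        assert out.n_labels == 1
        np.testing.assert_array_equal(out.mask(), disc)

    def test_overlapping_disc_pair_splits_in_two(self):
        yy, xx = np.mgrid[0:60, 0:80]
        pair = (((yy - 30) ** 2 + (xx - 30) ** 2) <= 100) | \
               (((yy - 30) ** 2 + (xx - 45) ** 2) <= 100)
        out = watershed_split(pair, 8)
        assert out.n_labels == 2
        # 1-px watershed line assigned to background between the lobes
        assert out.mask().sum() < pair.sum()
        assert out.raster[30, 30] != out.raster[30, 45]
        assert out.raster[30, 30] > 0 and out.raster[30, 45] > 0

    @pytest.mark.parametrize("k", [2, 3, 5, 8, 10])
    def test_k_separated_discs_keep_k_labels(self, k):
        h, w = 40, 42 * k
        yy, xx = np.mgrid[0:h, 0:w]
        mask = np.zeros((h, w), dtype=bool)
        for i in range(k):
            cx = 21 + 42 * i
            mask |= ((yy - 20) ** 2 + (xx - cx) ** 2) <= 144
        assert watershed_split(mask, 8).n_labels == k


# ---------------------------------------------------------------------------
# label_particles / size_filter

class TestLabelParticles:
    def test_disjoint_squares(self):
        mask = np.zeros((12, 20), dtype=bool)
        mask[2:7, 2:7] = True
        mask[2:7, 10:15] = True
        out = label_particles(mask, connectivity=8)
        assert out.n_labels == 2
        assert (out.raster == 1).sum() == 25 and (out.raster == 2).sum() == 25

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_particles(mask, connectivity=8).n_labels == 1
        assert label_particles(mask, connectivity=4).n_labels == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        mask = random_mask(rng, (64, 64), p=0.4)
        for conn in (4, 8):
            ref = oracles.union_find_label(mask, conn, min_area=5)
            out = label_particles(mask, connectivity=conn, min_area_px=5)
            np.testing.assert_array_equal(out.raster, ref)

    @pytest.mark.parametrize("seed", range(4))
    def test_foreground_conservation(self, seed):
        rng = np.random.default_rng(600 + seed)
        mask = random_mask(rng, (64, 64), p=0.35)
        kept = label_particles(mask, 8, min_area_px=5).mask()
        removed = label_particles(mask, 8, max_area_px=4).mask()
        np.testing.assert_array_equal(kept | removed, mask)
        assert not (kept & removed).any()

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            label_particles(np.zeros((3, 3), dtype=bool), connectivity=6)

    def test_size_filter_keeps_watershed_splits(self):
        yy, xx = np.mgrid[0:60, 0:80]
        pair = (((yy - 30) ** 2 + (xx - 30) ** 2) <= 100) | \
               (((yy - 30) ** 2 + (xx - 45) ** 2) <= 100)
        split = watershed_split(pair, 8)
        out = size_filter(split, min_area_px=10)
        assert out.n_labels == 2


# ---------------------------------------------------------------------------
# container types

class TestContainers:
    def test_labelmap_rejects_non_contiguous_labels(self):
        raster = np.zeros((4, 4), dtype=np.int32)
        raster[0, 0] = 2
        with pytest.raises(ValueError):
            LabelMap(raster)

    def test_micrograph_role_validation(self):
        chans = np.zeros((2, 4, 4))
        with pytest.raises(ValueError):
            Micrograph(chans, {"nuclei": 0, "myotubes": 0})
        with pytest.raises(ValueError):
            Micrograph(chans, {"nuclei": 0})
        with pytest.raises(IndexError):
            Micrograph(chans, {"nuclei": 0, "myotubes": 5})
        m = Micrograph(chans, {"nuclei": 1, "myotubes": 0})
        assert np.shares_memory(m.channel("nuclei"), m.channels[1])
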