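"""Disk normalization and GrowCut segmentation contracts."""

import numpy as np
import pytest

from marrowtex.phantom import AnatomyLabels, SpineVolume, DISK_BASE
from marrowtex.preprocess import (
    BACKGROUND_SEED,
    DiskROI,
    FOREGROUND,
    SeedSet,
    auto_seeds,
    dice_coefficient,
    growcut_segment,
    normalize_by_disk,
    select_reference_disk,
    split_disk_regions,
)

from _growcut_oracle import growcut_bruteforce


def _disk_mask(width, shape=(1, 3, None)):
    """A 1-slice, 3-row disk mask spanning `width` columns."""
    cols = width + 4
    m = np.zeros((1, 3, cols), dtype=bool)
    m[0, :, 2 : 2 + width] = True
    return m


class TestReferenceDisk:
    def _labels(self, flags):
        lab = np.zeros((1, 40, 10), dtype=np.int16)
        row = 2
        for level in (6, 5, 4, 3, 2, 1):  # cranial to caudal
            lab[0, row : row + 2, 2:8] = DISK_BASE + level
            row += 5
        return AnatomyLabels(lab, flags)

    def test_all_nondegenerated_returns_most_cranial(self):
        labels = self._labels({DISK_BASE + i: False for i in range(1, 7)})
        roi = select_reference_disk(labels)
        assert roi.disk_level == 6

    def test_single_candidate_returned(self):
        flags = {DISK_BASE + i: True for i in range(1, 7)}
        flags[DISK_BASE + 1] = False  # only the L5-S1 disk is usable
        roi = select_reference_disk(self._labels(flags))
        assert roi.disk_level == 1

    def test_all_degenerated_raises(self):
        flags = {DISK_BASE + i: True for i in range(1, 7)}
        with pytest.raises(ValueError, match="no reference disk"):
            select_reference_disk(self._labels(flags))


class TestSplitDiskRegions:
    def test_width_ten_gives_two_column_bins(self):
        roi = DiskROI(1, _disk_mask(10))
        bins, annulus = split_disk_regions(roi)
        ann_cols = set(np.nonzero(annulus)[2])
        assert ann_cols == {2, 3, 10, 11}  # first and last fifths

    @pytest.mark.parametrize("width", [5, 7, 10, 11, 23])
    def test_bins_partition_the_roi(self, width):
        roi = DiskROI(1, _disk_mask(width))
        bins, annulus = split_disk_regions(roi)
        union = np.zeros_like(roi.mask)
        total = 0
        for b in bins:
            assert not (union & b).any()  # pairwise disjoint
            union |= b
            total += b.sum()
        assert np.array_equal(union, roi.mask)
        assert np.array_equal(annulus, bins[0] | bins[4])

    def test_too_narrow_disk_raises(self):
        with pytest.raises(ValueError, match="too small"):
            split_disk_regions(DiskROI(1, _disk_mask(4)))


class TestNormalizeByDisk:
    def _roi(self):
        return DiskROI(1, _disk_mask(10))

    def test_constant_volume_maps_to_zero(self):
        vol = SpineVolume(np.full((1, 3, 14), 37.5))
        out = normalize_by_disk(vol, self._roi())
        assert np.allclose(out.voxels, 0.0)

    def test_shift_invariance_and_arithmetic(self):
        rng = np.random.default_rng(0)
        base = rng.normal(40, 5, (1, 3, 14))
        roi = self._roi()
        out1 = normalize_by_disk(SpineVolume(base), roi)
        out2 = normalize_by_disk(SpineVolume(base + 11.0), roi)
        assert np.allclose(out1.voxels, out2.voxels)
        # explicit arithmetic: voxel 50 under annulus mean 37.5 -> 12.5
        vol = np.full((1, 3, 14), 37.5)
        vol[0, 0, 0] = 50.0
        # keep annulus mean at exactly 37.5 (voxel 0 is outside the disk)
        out = normalize_by_disk(SpineVolume(vol), roi)
        assert out.voxels[0, 0, 0] == pytest.approx(12.5)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        vol = SpineVolume(rng.normal(100, 10, (1, 3, 14)))
        roi = self._roi()
        once = normalize_by_disk(vol, roi)
        twice = normalize_by_disk(once, roi)
        assert np.allclose(once.voxels, twice.voxels)

    def test_annulus_mean_is_zero_after_normalization(self, small_subject):
        roi = select_reference_disk(small_subject.labels)
        out = normalize_by_disk(small_subject.volume, roi)
        from marrowtex.preprocess import annulus_mask

        assert abs(out.voxels[annulus_mask(roi)].mean()) < 1e-6


class TestAutoSeeds:
    def test_radius_zero_foreground_equals_marrow(self, small_subject):
        seeds = auto_seeds(small_subject.labels, erosion_radius=0)
        fg = seeds.coordinates[seeds.labels == FOREGROUND]
        marrow = np.argwhere(small_subject.labels.marrow_mask())
        assert {tuple(c) for c in fg} == {tuple(c) for c in marrow}

    def test_foreground_seeds_inside_marrow_and_both_labels_present(
        self, small_subject
    ):
        seeds = auto_seeds(small_subject.labels, erosion_radius=1)
        marrow = small_subject.labels.marrow_mask()
        fg = seeds.coordinates[seeds.labels == FOREGROUND]
        assert marrow[fg[:, 0], fg[:, 1], fg[:, 2]].all()
        assert (seeds.labels == BACKGROUND_SEED).any()

    def test_vanishing_level_raises_with_level_name(self, small_subject):
        with pytest.raises(ValueError, match="level"):
            auto_seeds(small_subject.labels, erosion_radius=30)


class TestGrowCut:
    def test_two_homogeneous_regions_partition_exactly(self):
        vol = np.zeros((2, 6, 6))
        vol[:, :, 3:] = 100.0
        seeds = SeedSet(
            np.array([[0, 2, 0], [0, 2, 5]]),
            np.array([FOREGROUND, BACKGROUND_SEED]),
        )
        out = growcut_segment(SpineVolume(vol), seeds, max_iters=100)
        assert out.converged
        assert np.array_equal(out.mask, vol == 0)

    def test_matches_bruteforce_on_toy_volume(self):
        rng = np.random.default_rng(7)
        vol = rng.uniform(0, 100, (2, 4, 4))
        coords = np.array([[0, 0, 0], [1, 3, 3], [0, 3, 0], [1, 0, 3]])
        labs = np.array(
            [FOREGROUND, FOREGROUND, BACKGROUND_SEED, BACKGROUND_SEED]
        )
        out = growcut_segment(
            SpineVolume(vol), SeedSet(coords, labs), max_iters=100
        )
        ref_label, ref_iters = growcut_bruteforce(vol, coords, labs, max_iters=100)
        assert np.array_equal(out.mask, ref_label == FOREGROUND)
        assert out.iterations == ref_iters

    def test_all_voxels_seeded_is_a_fixpoint(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        coords = np.argwhere(np.ones_like(vol, dtype=bool))
        labs = np.full(coords.shape[0], FOREGROUND)
        # SeedSet requires both labels; bypass via a single bg seed outside?
        # use one background corner instead: everything else foreground
        labs[-1] = BACKGROUND_SEED
        out = growcut_segment(SpineVolume(vol), SeedSet(coords, labs), max_iters=10)
        assert out.converged
        assert out.iterations == 1  # first pass already changes nothing
        assert out.mask.sum() == 7

    def test_seeded_voxels_never_change_label(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(0, 1, (2, 5, 5))
        coords = np.array([[0, 0, 0], [1, 4, 4]])
        labs = np.array([FOREGROUND, BACKGROUND_SEED])
        out = growcut_segment(SpineVolume(vol), SeedSet(coords, labs), max_iters=200)
        assert out.mask[0, 0, 0]
        assert not out.mask[1, 4, 4]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_terminates_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.uniform(0, 1, (8, 8, 8))
        coords = np.array([[0, 0, 0], [7, 7, 7]])
        labs = np.array([FOREGROUND, BACKGROUND_SEED])
        out = growcut_segment(SpineVolume(vol), SeedSet(coords, labs), max_iters=500)
        assert out.converged

    def test_zero_intensity_range_raises(self):
        vol = np.zeros((2, 3, 3))
        seeds = SeedSet(
            np.array([[0, 0, 0], [1, 2, 2]]),
            np.array([FOREGROUND, BACKGROUND_SEED]),
        )
        with pytest.raises(ValueError, match="intensity range"):
            growcut_segment(SpineVolume(vol), seeds)

    def test_nonconvergence_flagged_not_fatal(self):
        rng = np.random.default_rng(5)
        vol = rng.uniform(0, 1, (4, 6, 6))
        seeds = SeedSet(
            np.array([[0, 0, 0], [3, 5, 5]]),
            np.array([FOREGROUND, BACKGROUND_SEED]),
        )
        out = growcut_segment(SpineVolume(vol), seeds, max_iters=1)
        assert not out.converged


def test_dice_coefficient_basics():
    a = np.zeros((2, 2, 2), dtype=bool)
    b = np.zeros((2, 2, 2), dtype=bool)
    assert dice_coefficient(a, b) == 1.0
    a[0, 0, 0] = True
    assert dice_coefficient(a, b) == 0.0
    b[0, 0, 0] = True
    assert dice_coefficient(a, b) == 1.0


def test_seed_set_json_round_trip(tmp_path, small_subject):
    from marrowtex.preprocess import load_seeds, save_seeds

    seeds = auto_seeds(small_subject.labels, erosion_radius=1)
    path = tmp_path / "seeds.json"
    save_seeds(seeds, path)
    back = load_seeds(path)
    assert np.array_equal(back.coordinates, seeds.coordinates)
    assert np.array_equal(back.labels, seeds.labels)
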