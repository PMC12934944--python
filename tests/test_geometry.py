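"""Searchlights, ROIs, masks, pattern normalization, and reliability."""

import numpy as np
import pytest

from socialrsa.geometry import (
    VolumeGrid,
    VoxelMask,
    define_roi_top_percent,
    define_searchlights,
    dice,
    load_mask_nifti,
    neural_rdm,
    normalize_and_average,
    remove_overlap,
    save_mask_nifti,
    save_map_nifti,
    spearman_brown,
    sphere_offsets,
    split_half_rsa_reliability,
    split_half_voxel_reliability,
)
from socialrsa.rdm import DegenerateRepresentationError


def _solid_mask(extent=9):
    grid = VolumeGrid((extent,) * 3)
    return VoxelMask(grid, np.ones(grid.shape, dtype=bool))


class TestSearchlights:
    @pytest.mark.parametrize("radius, expected", [(1, 7), (2, 33), (3, 123)])
    def test_sphere_sizes_match_lattice_enumeration(self, radius, expected):
        # independent oracle: exhaustive enumeration of x^2+y^2+z^2 <= r^2
        r = radius
        count = sum(
            1
            for x in range(-r, r + 1)
            for y in range(-r, r + 1)
            for z in range(-r, r + 1)
            if x * x + y * y + z * z <= r * r
        )
        assert count == expected
        assert len(sphere_offsets(radius)) == expected
        mask = _solid_mask(2 * radius + 3)
        lights = define_searchlights(mask, radius)
        center = tuple([radius + 1] * 3)
        deep = next(sl for sl in lights if sl.center == center)
        assert deep.n_voxels == expected

    def test_one_searchlight_per_mask_voxel_and_subset(self):
        grid = VolumeGrid((6, 6, 6))
        rng = np.random.default_rng(0)
        mask = VoxelMask(grid, rng.random(grid.shape) > 0.5)
        lights = define_searchlights(mask, 2)
        assert len(lights) == mask.size
        for sl in lights[::7]:
            assert mask.data[tuple(np.array(sl.members).T)].all()

    def test_members_monotone_in_radius(self):
        mask = _solid_mask(7)
        sizes = {}
        for radius in (1, 2, 3):
            sizes[radius] = [sl.n_voxels for sl in define_searchlights(mask, radius)]
        assert all(
            a <= b for a, b in zip(sizes[1], sizes[2])
        ) and all(a <= b for a, b in zip(sizes[2], sizes[3]))

    def test_single_voxel_mask(self):
        grid = VolumeGrid((4, 4, 4))
        mask = VoxelMask.from_indices(grid, [(2, 2, 2)])
        lights = define_searchlights(mask, 3)
        assert len(lights) == 1 and lights[0].n_voxels == 1 and lights[0].small

    def test_empty_mask_warns(self):
        grid = VolumeGrid((3, 3, 3))
        with pytest.warns(UserWarning, match="empty"):
            assert define_searchlights(
                VoxelMask(grid, np.zeros(grid.shape, bool)), 2
            ) == []


class TestNormalizeAndAverage:
    def test_single_standardized_repeat_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 6))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        np.testing.assert_allclose(normalize_and_average([x]), x, atol=1e-12)

    def test_opposite_repeats_cancel(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 4))
        np.testing.assert_allclose(
            normalize_and_average([x, -x]), np.zeros_like(x), atol=1e-12
        )

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        reps = [rng.standard_normal((8, 5)) for _ in range(2)]
        got = normalize_and_average(reps)
        stacked = np.vstack(reps)
        expected = np.zeros((8, 5))
        for v in range(5):
            mu, sd = stacked[:, v].mean(), stacked[:, v].std()
            z = [(r[:, v] - mu) / sd for r in reps]
            expected[:, v] = np.mean(z, axis=0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_zero_variance_voxel_zeroed_not_fatal(self):
        x = np.ones((5, 2))
        x[:, 1] = np.arange(5.0)
        avg, excluded = normalize_and_average([x], return_excluded=True)
        assert list(excluded) == [0]
        np.testing.assert_array_equal(avg[:, 0], 0.0)


class TestNeuralRDM:
    def test_identical_and_signflipped_patterns(self):
        rng = np.random.default_rng(4)
        p = rng.standard_normal(10)
        patterns = np.stack([p, p, -p])
        d = neural_rdm(patterns).values
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_pairwise_pearson_oracle(self):
        rng = np.random.default_rng(5)
        patterns = rng.standard_normal((4, 10))
        d = neural_rdm(patterns).values
        for i in range(4):
            for j in range(4):
                r = np.corrcoef(patterns[i], patterns[j])[0, 1]
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_affine_rescale_invariance(self):
        # a common positive-slope affine transform leaves 1 - Pearson
        # unchanged; per-voxel gains would not (mean-pattern sensitivity
        # is a known property of correlation distance)
        rng = np.random.default_rng(6)
        patterns = rng.standard_normal((5, 12))
        np.testing.assert_allclose(
            neural_rdm(1.7 * patterns + 0.3).values,
            neural_rdm(patterns).values, atol=1e-9,
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="voxels"):
            neural_rdm(np.random.default_rng(0).standard_normal((4, 3)),
                       voxel_cols=[0])
        with pytest.raises(DegenerateRepresentationError, match="flat"):
            patterns = np.random.default_rng(1).standard_normal((3, 5))
            patterns[1] = 2.0
            neural_rdm(patterns, labels=("a", "flat", "c"))


class TestReliability:
    def test_identical_and_negated_halves(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((12, 6))
        r, mask = split_half_voxel_reliability([x, x])
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert mask.all()
        r2, mask2 = split_half_voxel_reliability([x, -x])
        np.testing.assert_allclose(r2, -1.0, atol=1e-12)
        assert not mask2.any()

    def test_attenuation_matches_analytic_expectation(self):
        # halves share signal of variance 1 with independent noise of
        # variance s2: E[r] ~ 1 / (1 + s2)
        rng = np.random.default_rng(8)
        n_cond, n_vox, s2 = 60, 1000, 0.5
        signal = rng.standard_normal((n_cond, n_vox))
        reps = [signal + np.sqrt(s2) * rng.standard_normal((n_cond, n_vox))
                for _ in range(2)]
        r, _ = split_half_voxel_reliability(reps)
        assert r.mean() == pytest.approx(1 / (1 + s2), abs=0.02)

    def test_odd_repeat_joins_even_split(self):
        a, b, c = (np.full((3, 2), v) for v in (1.0, 2.0, 3.0))
        from socialrsa.geometry import split_repeats

        even, odd = split_repeats([a, b, c])
        np.testing.assert_allclose(even, 2.0)  # repeats 0 and 2
        np.testing.assert_allclose(odd, 2.0)

    @pytest.mark.parametrize("r, expected", [(0.0, 0.0), (0.5, 2 / 3), (1.0, 1.0)])
    def test_spearman_brown_closed_form(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_spearman_brown_undefined_at_minus_one(self):
        assert np.isnan(spearman_brown(-1.0))

    def test_split_half_rsa_perfect_data(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((10, 8))
        assert split_half_rsa_reliability([x, x]) == pytest.approx(1.0)


class TestROIs:
    def test_top_percent_picks_largest_contrast(self):
        grid = VolumeGrid((20, 1, 1))
        parcel = VoxelMask(grid, np.ones(grid.shape, bool))
        contrast = np.arange(1.0, 21.0).reshape(grid.shape)
        roi = define_roi_top_percent(contrast, parcel, 0.10)
        assert roi.size == 2
        picked = sorted(contrast[tuple(roi.members.T)])
        assert picked == [19.0, 20.0]

    def test_tie_break_is_lexicographic(self):
        grid = VolumeGrid((3, 3, 1))
        parcel = VoxelMask(grid, np.ones(grid.shape, bool))
        roi = define_roi_top_percent(np.ones(grid.shape), parcel, 0.34)
        # ceil(0.34 * 9) = 4 voxels, in index order
        assert [tuple(m) for m in roi.members] == [
            (0, 0, 0), (0, 1, 0), (0, 2, 0), (1, 0, 0)
        ]

    def test_full_percent_returns_parcel(self):
        grid = VolumeGrid((4, 4, 1))
        parcel = VoxelMask(grid, np.random.default_rng(0).random(grid.shape) > 0.4)
        roi = define_roi_top_percent(
            np.random.default_rng(1).random(grid.shape), parcel, 1.0
        )
        assert roi == parcel

    def test_undefined_contrast_rejected(self):
        grid = VolumeGrid((3, 3, 1))
        parcel = VoxelMask(grid, np.ones(grid.shape, bool))
        contrast = np.full(grid.shape, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            define_roi_top_percent(contrast, parcel, 0.5)


class TestOverlap:
    def test_dice_cases(self):
        grid = VolumeGrid((30, 1, 1))
        a = VoxelMask.from_indices(grid, [(i, 0, 0) for i in range(10)])
        b = VoxelMask.from_indices(grid, [(i, 0, 0) for i in range(8, 18)])
        c = VoxelMask.from_indices(grid, [(i, 0, 0) for i in range(20, 25)])
        assert dice(a, a) == 1.0
        assert dice(a, c) == 0.0
        assert dice(a, b) == pytest.approx(2 * 2 / 20)  # |overlap| = 2
        assert dice(a, b) == dice(b, a)
        with pytest.raises(ValueError, match="empty"):
            empty = VoxelMask(grid, np.zeros(grid.shape, bool))
            dice(empty, empty)

    def test_remove_overlap_set_arithmetic(self):
        grid = VolumeGrid((30, 1, 1))
        a = VoxelMask.from_indices(grid, [(i, 0, 0) for i in range(10)])
        b = VoxelMask.from_indices(grid, [(i, 0, 0) for i in range(7, 15)])
        out_a, out_b = remove_overlap(a, b)
        assert out_a.size == 10 - 3 and out_b.size == 8 - 3
        assert out_a.intersect(out_b).size == 0
        # disjoint inputs unchanged
        c = VoxelMask.from_indices(grid, [(20, 0, 0)])
        out_a2, out_c = remove_overlap(a, c)
        assert out_a2 == a and out_c == c
        with pytest.warns(UserWarning, match="emptied"):
            remove_overlap(a, a)


def test_nifti_mask_and_map_roundtrip(tmp_path):
    grid = VolumeGrid((5, 6, 7), voxel_size=(3.0, 3.0, 3.0))
    rng = np.random.default_rng(10)
    mask = VoxelMask(grid, rng.random(grid.shape) > 0.5)
    save_mask_nifti(mask, tmp_path / "mask.nii.gz")
    loaded = load_mask_nifti(tmp_path / "mask.nii.gz")
    assert loaded == mask
    assert loaded.grid.voxel_size == (3.0, 3.0, 3.0)
    values = rng.standard_normal(mask.size)
    save_map_nifti(values, mask, tmp_path / "map.nii.gz")
    import nibabel as nib

    vol = np.asarray(nib.load(str(tmp_path / "map.nii.gz")).dataobj)
    np.testing.assert_allclose(vol[tuple(mask.members.T)], values, atol=1e-6)
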