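"""3D seeded growth: visibility seeding, synchronous BFS semantics,
component confinement, and the simple-projection baseline."""

import numpy as np
import pytest
from scipy import ndimage

from leaf3d.expand import (
    expand_attributes,
    neighbor_offsets,
    project_seeds,
    simple_projection_segment,
)
from leaf3d.voxel import VoxelGrid


def _grid(occ):
    occ = np.asarray(occ, dtype=np.uint8)
    return VoxelGrid(np.zeros(3), np.ones(3), occ)


def _erosion_growth_oracle(occ, seeds, connectivity):
    """Independent synchronous-round implementation via whole-grid min
    filtering: each round, every unlabeled occupied voxel takes the minimum
    label among its labeled neighbors."""
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    struct = ndimage.generate_binary_structure(3, rank)
    sent = np.int64(2**31)
    occ = occ.astype(bool)
    labels = np.where(occ & (seeds > 0), seeds.astype(np.int64), 0)
    while True:
        padded = np.where(labels > 0, labels, sent)
        nb_min = ndimage.grey_erosion(padded, footprint=struct,
                                      mode="constant", cval=sent)
        newly = occ & (labels == 0) & (nb_min < sent)
        if not newly.any():
            return labels
        labels[newly] = nb_min[newly]


class TestProjectSeeds:
    def test_topmost_occupied_voxel_seeded(self):
        occ = np.zeros((1, 1, 9), dtype=np.uint8)
        occ[0, 0, 2] = occ[0, 0, 7] = 1
        seeds2d = np.array([[5]], dtype=np.int32)
        out = project_seeds(seeds2d, _grid(occ))
        assert out[0, 0, 7] == 5 and out[0, 0, 2] == 0

    def test_empty_column_contributes_nothing(self):
        occ = np.zeros((2, 1, 3), dtype=np.uint8)
        occ[0, 0, 1] = 1
        seeds2d = np.array([[1], [2]], dtype=np.int32)
        out = project_seeds(seeds2d, _grid(occ))
        assert out[0, 0, 1] == 1
        assert np.count_nonzero(out) == 1

    def test_distinct_labels_stay_disjoint(self):
        occ = np.ones((3, 3, 2), dtype=np.uint8)
        seeds2d = np.arange(9, dtype=np.int32).reshape(3, 3)
        out = project_seeds(seeds2d, _grid(occ))
        nz = out[out > 0]
        assert sorted(nz.tolist()) == list(range(1, 9))

    def test_no_seed_on_voxel_raises(self):
        occ = np.zeros((2, 2, 2), dtype=np.uint8)
        occ[0, 0, 0] = 1
        seeds2d = np.zeros((2, 2), dtype=np.int32)
        seeds2d[1, 1] = 3  # only over an empty column
        with pytest.raises(ValueError, match="no seed"):
            project_seeds(seeds2d, _grid(occ))


class TestExpandAttributes:
    def test_rod_split_five_four_with_min_label_tiebreak(self):
        occ = np.ones((1, 1, 9), dtype=np.uint8)
        seeds = np.zeros((1, 1, 9), dtype=np.int32)
        seeds[0, 0, 0], seeds[0, 0, 8] = 1, 2
        grid, unreached = expand_attributes(_grid(occ), seeds, 6)
        labels = grid.labels[0, 0]
        assert unreached == 0
        # middle voxel equidistant -> smaller label wins: 5 ones, 4 twos
        np.testing.assert_array_equal(labels, [1, 1, 1, 1, 1, 2, 2, 2, 2])

    def test_two_components_take_their_own_seed(self):
        occ = np.zeros((5, 1, 1), dtype=np.uint8)
        occ[:2, 0, 0] = 1
        occ[3:, 0, 0] = 1
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[0, 0, 0], seeds[4, 0, 0] = 7, 3
        grid, _ = expand_attributes(_grid(occ), seeds, 26)
        assert set(grid.labels[occ.astype(bool)]) == {7, 3}
        assert grid.labels[1, 0, 0] == 7 and grid.labels[3, 0, 0] == 3

    def test_single_seed_fills_connected_component(self):
        rng = np.random.default_rng(0)
        occ = (rng.uniform(size=(8, 8, 8)) < 0.7).astype(np.uint8)
        occ[4, 4, 4] = 1
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[4, 4, 4] = 1
        grid, unreached = expand_attributes(_grid(occ), seeds, 26)
        struct = ndimage.generate_binary_structure(3, 3)
        comp, _ = ndimage.label(occ, structure=struct)
        inside = comp == comp[4, 4, 4]
        assert np.all(grid.labels[inside] == 1)
        assert np.all(grid.labels[~inside] == 0)
        assert unreached == int((occ.astype(bool) & ~inside).sum())

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_erosion_round_oracle(self, connectivity):
        rng = np.random.default_rng(5)
        occ = (rng.uniform(size=(12, 12, 12)) < 0.6).astype(np.uint8)
        occupied = np.argwhere(occ)
        seeds = np.zeros_like(occ, dtype=np.int32)
        for k, pos in enumerate(occupied[rng.choice(len(occupied), 5, replace=False)]):
            seeds[tuple(pos)] = k + 1
        grid, _ = expand_attributes(_grid(occ), seeds, connectivity)
        oracle = _erosion_growth_oracle(occ, seeds, connectivity)
        np.testing.assert_array_equal(grid.labels, oracle)

    def test_labeled_set_equals_components_containing_seeds(self):
        rng = np.random.default_rng(9)
        occ = (rng.uniform(size=(15, 15, 15)) < 0.4).astype(np.uint8)
        occupied = np.argwhere(occ)
        seeds = np.zeros_like(occ, dtype=np.int32)
        chosen = occupied[rng.choice(len(occupied), 3, replace=False)]
        for k, pos in enumerate(chosen):
            seeds[tuple(pos)] = k + 1
        grid, unreached = expand_attributes(_grid(occ), seeds, 26)
        struct = ndimage.generate_binary_structure(3, 3)
        comp, _ = ndimage.label(occ, structure=struct)
        seeded_comps = {comp[tuple(pos)] for pos in chosen}
        expected = np.isin(comp, list(seeded_comps)) & occ.astype(bool)
        np.testing.assert_array_equal(grid.labels > 0, expected)
        assert unreached == int(occ.sum() - expected.sum())

    def test_seed_voxels_never_relabeled(self):
        occ = np.ones((4, 4, 1), dtype=np.uint8)
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[0, 0, 0], seeds[3, 3, 0], seeds[0, 3, 0] = 3, 1, 2
        grid, _ = expand_attributes(_grid(occ), seeds, 26)
        assert grid.labels[0, 0, 0] == 3
        assert grid.labels[3, 3, 0] == 1
        assert grid.labels[0, 3, 0] == 2

    def test_result_invariant_to_seed_insertion_order(self):
        rng = np.random.default_rng(2)
        occ = (rng.uniform(size=(10, 10, 10)) < 0.8).astype(np.uint8)
        occupied = np.argwhere(occ)
        picks = occupied[rng.choice(len(occupied), 4, replace=False)]
        seeds_a = np.zeros_like(occ, dtype=np.int32)
        seeds_b = np.zeros_like(occ, dtype=np.int32)
        for k, pos in enumerate(picks):
            seeds_a[tuple(pos)] = k + 1
        for k, pos in enumerate(picks[::-1]):
            seeds_b[tuple(pos)] = len(picks) - k
        grid_a, _ = expand_attributes(_grid(occ), seeds_a, 26)
        grid_b, _ = expand_attributes(_grid(occ), seeds_b, 26)
        np.testing.assert_array_equal(grid_a.labels, grid_b.labels)

    def test_growth_cannot_jump_empty_space(self):
        occ = np.zeros((5, 1, 1), dtype=np.uint8)
        occ[0, 0, 0] = occ[4, 0, 0] = 1  # two voxels separated by a gap
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[0, 0, 0] = 1
        grid, unreached = expand_attributes(_grid(occ), seeds, 26)
        assert grid.labels[4, 0, 0] == 0 and unreached == 1

    def test_neighbor_offsets_counts(self):
        assert len(neighbor_offsets(6)) == 6
        assert len(neighbor_offsets(18)) == 18
        assert len(neighbor_offsets(26)) == 26


class TestSimpleProjection:
    def test_column_inherits_pixel_label(self):
        occ = np.zeros((1, 1, 5), dtype=np.uint8)
        occ[0, 0, [0, 2, 4]] = 1
        initial = np.array([[2]], dtype=np.int32)
        grid = simple_projection_segment(initial, _grid(occ))
        assert all(grid.labels[0, 0, z] == 2 for z in (0, 2, 4))
        assert grid.labels[0, 0, 1] == 0

    def test_occluded_lower_leaf_inherits_upper_label(self):
        # two stacked sheets; top view sees only the upper one
        occ = np.zeros((3, 3, 6), dtype=np.uint8)
        occ[:, :, 1] = 1  # lower leaf
        occ[:, :, 4] = 1  # upper leaf
        initial = np.full((3, 3), 1, dtype=np.int32)  # watershed saw one region
        grid = simple_projection_segment(initial, _grid(occ))
        assert np.all(grid.labels[occ.astype(bool)] == 1)  # lower leaf mislabeled

    def test_equivalent_to_expansion_for_single_label_connected_grid(self):
        rng = np.random.default_rng(4)
        occ = np.zeros((10, 10, 4), dtype=np.uint8)
        occ[2:8, 2:8, 1] = 1  # one connected slab
        initial = np.zeros((10, 10), dtype=np.int32)
        initial[occ.any(axis=2)] = 1
        simple = simple_projection_segment(initial, _grid(occ))
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[4, 4, 1] = 1
        expanded, _ = expand_attributes(_grid(occ), seeds, 26)
        np.testing.assert_array_equal(simple.labels, expanded.labels)


class TestMergeSeedsByComponent:
    def test_seeds_on_one_component_fuse_to_smallest(self):
        from leaf3d.expand import merge_seeds_by_component

        occ = np.ones((5, 1, 1), dtype=np.uint8)
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[0, 0, 0], seeds[4, 0, 0] = 3, 5
        merged = merge_seeds_by_component(_grid(occ), seeds, 26)
        assert merged[0, 0, 0] == 3 and merged[4, 0, 0] == 3

    def test_seeds_on_separate_components_untouched(self):
        from leaf3d.expand import merge_seeds_by_component

        occ = np.zeros((5, 1, 1), dtype=np.uint8)
        occ[:2, 0, 0] = 1
        occ[3:, 0, 0] = 1
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[0, 0, 0], seeds[4, 0, 0] = 3, 5
        merged = merge_seeds_by_component(_grid(occ), seeds, 26)
        np.testing.assert_array_equal(merged, seeds)

    def test_oversegmented_leaf_heals_end_to_end(self):
        """A single connected slab given two seeds ends up as one leaf."""
        from leaf3d.expand import merge_seeds_by_component

        occ = np.zeros((10, 10, 2), dtype=np.uint8)
        occ[:, :, 0] = 1
        seeds = np.zeros_like(occ, dtype=np.int32)
        seeds[1, 1, 0], seeds[8, 8, 0] = 1, 2
        merged = merge_seeds_by_component(_grid(occ), seeds, 26)
        grid, _ = expand_attributes(_grid(occ), merged, 26)
        assert set(np.unique(grid.labels[occ.astype(bool)])) == {1}
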