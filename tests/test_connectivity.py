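"""Component labelling and the structural-vein attachment metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from venation.connectivity import attached_fraction, count_loops, label_components

from conftest import flood_fill_holes, flood_fill_labels


def mask_from_pixels(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


class TestLabelComponents:
    def test_empty_mask_has_zero_components(self):
        lab = label_components(np.zeros((3, 3), dtype=bool))
        assert lab.n_components == 0
        assert (lab.grid == 0).all()

    @pytest.mark.parametrize(
        "pixels, connectivity, expected",
        [
            ([(0, 0), (1, 1)], 8, 1),  # diagonal touch joins under 8-connectivity
            ([(0, 0), (1, 1)], 4, 2),
            ([(0, 0), (0, 2)], 8, 2),  # gap of one column separates
            ([(0, 0), (0, 2)], 4, 2),
        ],
    )
    def test_small_examples(self, pixels, connectivity, expected):
        mask = mask_from_pixels((3, 3), pixels)
        assert label_components(mask, connectivity).n_components == expected

    def test_row_major_first_encounter_order(self):
        # Component containing the row-major-first foreground pixel gets label 1.
        mask = mask_from_pixels((4, 6), [(0, 4), (2, 0), (3, 0), (3, 5)])
        lab = label_components(mask)
        assert lab.grid[0, 4] == 1
        assert lab.grid[2, 0] == lab.grid[3, 0] == 2
        assert lab.grid[3, 5] == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(20_24)
        for _ in range(150):
            h, w = rng.integers(1, 15, size=2)
            mask = rng.random((h, w)) < rng.uniform(0.2, 0.8)
            lab = label_components(mask, connectivity)
            oracle_grid, oracle_n = flood_fill_labels(mask, connectivity)
            assert lab.n_components == oracle_n
            assert (lab.grid == oracle_grid).all()

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        mask=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, max_side=9)),
        connectivity=st.sampled_from([4, 8]),
    )
    def test_label_grid_properties(self, mask, connectivity):
        lab = label_components(mask, connectivity)
        labels = np.unique(lab.grid)
        labels = labels[labels > 0]
        # labels are 1..n with no gaps, and exactly cover the foreground
        assert list(labels) == list(range(1, lab.n_components + 1))
        assert ((lab.grid > 0) == mask).all()
        oracle_grid, oracle_n = flood_fill_labels(mask, connectivity)
        assert lab.n_components == oracle_n
        assert (lab.grid == oracle_grid).all()

    def test_rejects_bad_connectivity_and_values(self):
        with pytest.raises(ValueError):
            label_components(np.zeros((2, 2), dtype=bool), connectivity=6)
        with pytest.raises(ValueError):
            label_components(np.array([[0, 2], [1, 0]]))


class TestAttachedFraction:
    def test_pristine_fully_connected_leaf(self, default_leaves):
        leaf = default_leaves["net"]
        f_remain, f_connected = attached_fraction(
            leaf.network, leaf.structural, leaf.n_original
        )
        assert f_remain == 1.0
        assert f_connected == 1.0

    def test_seven_by_seven_fixture(self):
        # Structural spine down column 3; network along row 0 on both sides.
        structural = np.zeros((7, 7), dtype=bool)
        structural[:, 3] = True
        network = mask_from_pixels((7, 7), [(0, c) for c in (0, 1, 2, 4, 5, 6)])
        damaged = network.copy()
        damaged[0, 1] = False  # isolates pixel (0, 0) from the spine
        f_remain, f_connected = attached_fraction(damaged, structural, 6)
        assert f_remain == pytest.approx(5 / 6)
        assert f_connected == pytest.approx(4 / 6)

    def test_monotone_under_additional_removal(self):
        # Removing more pixels can never re-attach anything.
        rng = np.random.default_rng(7)
        for _ in range(20):
            structural = np.zeros((12, 12), dtype=bool)
            structural[:, 0] = True
            network = rng.random((12, 12)) < 0.45
            network &= ~structural
            n_original = max(int(network.sum()), 1)
            damaged = network.copy()
            prev_fc = attached_fraction(damaged, structural, n_original)[1]
            coords = np.argwhere(damaged)
            rng.shuffle(coords)
            for r, c in coords[:30]:
                damaged[r, c] = False
                f_remain, f_connected = attached_fraction(damaged, structural, n_original)
                assert f_connected <= prev_fc + 1e-12
                assert f_connected <= f_remain
                prev_fc = f_connected

    def test_equals_remain_when_all_components_touch_spine(self):
        structural = np.zeros((5, 5), dtype=bool)
        structural[2, :] = True
        network = np.zeros((5, 5), dtype=bool)
        network[1, :] = True  # adjacent to the spine everywhere
        f_remain, f_connected = attached_fraction(network, structural, 5)
        assert f_connected == f_remain

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            attached_fraction(np.zeros((3, 3), bool), np.zeros((3, 4), bool), 1)
        with pytest.raises(ValueError):
            attached_fraction(np.zeros((3, 3), bool), np.zeros((3, 3), bool), 0)


class TestCountLoops:
    def test_solid_square_is_simply_connected(self):
        assert count_loops(np.ones((3, 3), dtype=bool)) == 0

    def test_ring_has_one_hole(self):
        ring = np.ones((5, 5), dtype=bool)
        ring[1:4, 1:4] = False
        ring[2, 2] = False
        assert count_loops(ring) == 1

    def test_matches_background_oracle_on_random_masks(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            mask = rng.random((14, 14)) < 0.55
            assert count_loops(mask) == flood_fill_holes(mask)
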