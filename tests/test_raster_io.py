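"""Raster loading/saving, leaf validation and outcome persistence."""

import numpy as np
import pytest

from venation.experiment import AttackOutcome
from venation.raster_io import (
    LeafRaster,
    load_leaf,
    pristine_report,
    prune_small_components,
    read_outcomes,
    rescale_nearest,
    save_mask,
    write_outcomes,
)


@pytest.fixture
def small_pair(tmp_path):
    """A 5x5 image pair: 6 dark network pixels, a 3-px structural bar."""
    network = np.zeros((5, 5), dtype=bool)
    network[0, :3] = True
    network[1, :3] = True
    structural = np.zeros((5, 5), dtype=bool)
    structural[4, 1:4] = True
    net_path, struct_path = tmp_path / "net.png", tmp_path / "struct.png"
    save_mask(network, net_path)
    save_mask(structural, struct_path)
    return net_path, struct_path, network, structural


class TestLoadLeaf:
    def test_counts_and_masks_match(self, small_pair):
        net_path, struct_path, network, structural = small_pair
        leaf = load_leaf(net_path, struct_path, taxon="t", venation_class="net")
        assert leaf.network.sum() == 6
        assert (leaf.network == network).all()
        assert (leaf.structural == structural).all()
        assert leaf.n_original == 6

    @pytest.mark.parametrize("fmt", ["png", "gif"])
    @pytest.mark.parametrize("foreground", ["dark", "light"])
    def test_save_load_round_trip_is_idempotent(self, tmp_path, fmt, foreground):
        rng = np.random.default_rng(5)
        mask = rng.random((20, 30)) < 0.3
        mask[0, 0] = True
        path = tmp_path / f"m.{fmt}"
        save_mask(mask, path, foreground=foreground)
        structural = np.zeros_like(mask)
        structural[10, :] = True
        spath = tmp_path / f"s.{fmt}"
        save_mask(structural, spath, foreground=foreground)
        leaf = load_leaf(path, spath, taxon="t", venation_class="net",
                         foreground=foreground)
        assert (leaf.network == mask).all()
        assert (leaf.structural == structural).all()

    def test_dimension_mismatch_names_both_shapes(self, tmp_path):
        save_mask(np.ones((4, 5), dtype=bool), tmp_path / "a.png")
        save_mask(np.ones((6, 5), dtype=bool), tmp_path / "b.png")
        with pytest.raises(ValueError, match=r"\(4, 5\).*\(6, 5\)"):
            load_leaf(tmp_path / "a.png", tmp_path / "b.png", "t", "net")

    def test_empty_network_rejected(self, tmp_path):
        save_mask(np.zeros((4, 4), dtype=bool), tmp_path / "empty.png")
        save_mask(np.ones((4, 4), dtype=bool), tmp_path / "full.png")
        with pytest.raises(ValueError, match="empty venation network"):
            load_leaf(tmp_path / "empty.png", tmp_path / "full.png", "t", "net")

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises((OSError, ValueError)):
            load_leaf(tmp_path / "missing.png", tmp_path / "missing2.png", "t", "net")


class TestLeafRasterInvariants:
    def test_network_inside_structural_rejected(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        with pytest.raises(ValueError, match="attackable"):
            LeafRaster(taxon="t", venation_class="net", network=m, structural=m.copy())

    def test_bad_class_rejected(self):
        m = np.ones((3, 3), dtype=bool)
        s = np.zeros((3, 3), dtype=bool)
        s[0, 0] = True
        with pytest.raises(ValueError, match="venation_class"):
            LeafRaster(taxon="t", venation_class="loopy", network=m, structural=s)


class TestPristineReport:
    def test_stray_pixel_lowers_attached_fraction(self):
        # 10x10 leaf: spine column 0, a 9-px attached row, one isolated pixel.
        structural = np.zeros((10, 10), dtype=bool)
        structural[:, 0] = True
        network = np.zeros((10, 10), dtype=bool)
        network[0, 1:9] = True  # 8 px chain touching the spine
        network[5, 5] = True  # stray
        leaf = LeafRaster(taxon="t", venation_class="net",
                          network=network, structural=structural)
        with pytest.warns(UserWarning, match="disconnected"):
            report = pristine_report(leaf)
        n = leaf.n_original
        assert report.pristine_attached_fraction == pytest.approx((n - 1) / n)
        assert report.n_attackable == report.n_network - (network & structural).sum()

    def test_clean_leaf_reports_unity(self, default_leaves):
        report = pristine_report(default_leaves["branched"])
        assert report.pristine_attached_fraction == 1.0


class TestOutcomesRoundTrip:
    def make_outcomes(self, n):
        rng = np.random.default_rng(1)
        out = []
        for i in range(n):
            fr = float(rng.uniform())
            out.append(AttackOutcome(f_remain=fr, f_connected=fr * float(rng.uniform()),
                                     kind="vein", param=float(rng.uniform()),
                                     seed=int(rng.integers(2**31)), taxon="t"))
        return out

    def test_empty_list_gives_header_only_file(self, tmp_path):
        path = tmp_path / "o.csv"
        write_outcomes([], path)
        assert path.read_text().count("\n") == 1
        assert read_outcomes(path) == []

    def test_250_outcomes_round_trip_exactly(self, tmp_path):
        outcomes = self.make_outcomes(250)
        outcomes.append(AttackOutcome(0.75, 0.03, "vein", 0.25, 7, "t"))
        path = tmp_path / "o.csv"
        write_outcomes(outcomes, path)
        back = read_outcomes(path)
        assert len(back) == 251
        assert back == outcomes

    def test_malformed_file_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("taxon,attack_kind,param,seed,f_remain,f_connected\n"
                        "t,vein,0.5,3,0.9,0.5\n"
                        "t,vein,0.5,oops,0.9,0.5\n")
        with pytest.raises(ValueError, match="line 3"):
            read_outcomes(path)
        path.write_text("taxon,param\nt,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_outcomes(path)


class TestUtilities:
    def test_prune_small_components(self):
        m = np.zeros((6, 6), dtype=bool)
        m[0, 0:4] = True
        m[5, 5] = True
        pruned = prune_small_components(m, min_size=2)
        assert pruned.sum() == 4
        assert not pruned[5, 5]

    def test_rescale_nearest_preserves_binary_and_shape(self):
        m = np.zeros((10, 20), dtype=bool)
        m[4:6, :] = True
        up = rescale_nearest(m, 2.0)
        assert up.shape == (20, 40)
        assert up.dtype == bool
        down = rescale_nearest(up, 0.5)
        assert (down == m).all()
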