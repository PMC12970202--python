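"""Distance-to-structure, binning, grid occupancy, density, rich/poor split."""

import numpy as np
import pytest

from tmequant import (
    bin_distances,
    cell_density,
    grid_occupancy,
    nearest_structure_distances,
    split_rich_poor,
)

from conftest import make_cells, make_mask


def brute_force_distances(centroids, mask, pixel_scale):
    """O(cells x pixels) oracle with the same containment zero-rule."""
    pos = np.argwhere(mask)
    out = []
    for r, c in centroids:
        pr = min(max(int(np.floor(r + 0.5)), 0), mask.shape[0] - 1)
        pc = min(max(int(np.floor(c + 0.5)), 0), mask.shape[1] - 1)
        if mask[pr, pc]:
            out.append(0.0)
            continue
        d = np.sqrt(((pos - [r, c]) ** 2).sum(axis=1)).min()
        out.append(d / pixel_scale)
    return np.array(out)


class TestNearestStructureDistances:
    def test_three_four_five_triangle(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        cells = make_cells([(3.0, 4.0)])
        res = nearest_structure_distances(cells, make_mask(mask), pixel_scale=1.0)
        assert res.per_cell_um[0] == pytest.approx(5.0, abs=1e-12)

    def test_centroid_inside_structure_is_zero(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3:6, 3:6] = True
        cells = make_cells([(4.2, 4.7)])
        res = nearest_structure_distances(cells, make_mask(mask), pixel_scale=2.0)
        assert res.per_cell_um[0] == 0.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            nearest_structure_distances(make_cells([(1, 1)]),
                                        make_mask(np.zeros((4, 4))), 1.0)

    def test_empty_cellset_flagged_not_error(self):
        mask = np.ones((4, 4), dtype=bool)
        res = nearest_structure_distances(make_cells([]), make_mask(mask), 1.0)
        assert res.n_cells == 0
        assert np.isnan(res.mean_um)
        assert np.all(np.isnan(res.bin_fractions))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((128, 128)) < 0.01
        mask[0, 0] = True
        cents = rng.uniform(0, 127, (30, 2))
        res = nearest_structure_distances(make_cells(cents), make_mask(mask),
                                          pixel_scale=1.98)
        expect = brute_force_distances(cents, mask, 1.98)
        np.testing.assert_allclose(res.per_cell_um, expect, atol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:14, 20:25] = True
        cents = rng.uniform(15, 40, (12, 2))
        base = nearest_structure_distances(make_cells(cents), make_mask(mask), 1.0)
        shifted_mask = np.roll(np.roll(mask, 7, axis=0), 11, axis=1)
        shifted = nearest_structure_distances(make_cells(cents + [7, 11]),
                                              make_mask(shifted_mask), 1.0)
        np.testing.assert_allclose(shifted.per_cell_um, base.per_cell_um,
                                   atol=1e-9)

    def test_mask_dilation_never_increases_distance(self):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        mask = rng.random((80, 80)) < 0.005
        mask[40, 40] = True
        cents = rng.uniform(0, 79, (25, 2))
        base = nearest_structure_distances(make_cells(cents), make_mask(mask), 1.0)
        dil = ndimage.binary_dilation(mask, iterations=2)
        after = nearest_structure_distances(make_cells(cents), make_mask(dil), 1.0)
        assert np.all(after.per_cell_um <= base.per_cell_um + 1e-12)


class TestBinDistances:
    def test_default_edges_split_at_20um(self):
        fr = bin_distances([5, 15, 25, 40], [0, 20])
        np.testing.assert_allclose(fr, [0.5, 0.5])

    def test_all_zero_distances_in_first_bin(self):
        np.testing.assert_allclose(bin_distances([0, 0, 0], [0, 20]), [1.0, 0.0])

    def test_matches_independent_histogram(self, rng):
        d = rng.exponential(25, 1000)
        edges = [0, 10, 20, 50]
        fr = bin_distances(d, edges)
        full_edges = np.array([0, 10, 20, 50, np.inf])
        expect, _ = np.histogram(d, full_edges)
        np.testing.assert_allclose(fr, expect / d.size)
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bin_distances([], [0, 20])

    @pytest.mark.parametrize("edges", [[5, 20], [0, 20, 10], []])
    def test_bad_edges_rejected(self, edges):
        with pytest.raises(ValueError):
            bin_distances([1.0], edges)


def grid_oracle(centroids, mask, shape, side, mode):
    """Explicit double-loop grid enumeration."""
    import math

    H, W = shape
    nr, nc = math.ceil(H / side), math.ceil(W / side)
    n_pos = 0
    for gi in range(nr):
        for gj in range(nc):
            r0, r1 = gi * side, min((gi + 1) * side, H)
            c0, c1 = gj * side, min((gj + 1) * side, W)
            by_centroid = False
            for (r, c) in centroids:
                pr = min(max(int(np.floor(r + 0.5)), 0), H - 1)
                pc = min(max(int(np.floor(c + 0.5)), 0), W - 1)
                if r0 <= pr < r1 and c0 <= pc < c1:
                    by_centroid = True
                    break
            by_pixels = False
            if mask is not None:
                tile = mask[r0:r1, c0:c1]
                by_pixels = tile.sum() >= 0.5 * tile.size
            if mode == "centroid":
                n_pos += by_centroid
            elif mode == "pixel_fraction":
                n_pos += by_pixels
            else:
                n_pos += (by_centroid or by_pixels)
    return nr * nc, n_pos


class TestGridOccupancy:
    def test_one_centroid_per_grid_fully_occupied(self):
        cents = [(50 + 100 * i, 50 + 100 * j) for i in range(10) for j in range(10)]
        occ = grid_occupancy(make_cells(cents), None, (1000, 1000), 100, "centroid")
        assert occ.n_grids == 100 and occ.n_positive == 100
        assert occ.occupancy_fraction == 1.0

    def test_no_cells_zero_occupancy(self):
        occ = grid_occupancy(make_cells([]), None, (300, 300), 100, "centroid")
        assert occ.n_positive == 0 and occ.n_grids == 9

    def test_partial_edge_grids_counted(self):
        occ = grid_occupancy(make_cells([]), None, (250, 110), 100, "centroid")
        assert occ.n_grids == 3 * 2

    @pytest.mark.parametrize("mode", ["centroid", "pixel_fraction", "either"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_double_loop_oracle(self, mode, seed):
        rng = np.random.default_rng(seed)
        shape = (512, 512)
        cents = rng.uniform(0, 511, (200, 2))
        mask = rng.random(shape) < rng.uniform(0.3, 0.7)
        occ = grid_occupancy(make_cells(cents), make_mask(mask), shape, 100, mode)
        n_grids, n_pos = grid_oracle(cents, mask, shape, 100, mode)
        assert (occ.n_grids, occ.n_positive) == (n_grids, n_pos)

    def test_mode_needing_mask_without_mask_errors(self):
        with pytest.raises(ValueError, match="mask"):
            grid_occupancy(make_cells([]), None, (100, 100), 100, "pixel_fraction")

    def test_occupancy_nondecreasing_in_cell_count(self, rng):
        cents = rng.uniform(0, 399, (80, 2))
        prev = -1
        for n in (0, 10, 40, 80):
            occ = grid_occupancy(make_cells(cents[:n]), None, (400, 400), 100,
                                 "centroid")
            assert occ.n_positive >= prev
            prev = occ.n_positive

    def test_invariant_to_cell_ordering(self, rng):
        cents = rng.uniform(0, 299, (50, 2))
        a = grid_occupancy(make_cells(cents), None, (300, 300), 100, "centroid")
        b = grid_occupancy(make_cells(cents[::-1]), None, (300, 300), 100,
                           "centroid")
        assert a.n_positive == b.n_positive


class TestCellDensity:
    def test_one_cell_per_mm2_unit_construction(self):
        n = round(1.98e3)
        d = cell_density(make_cells([(1, 1)]), (n, n), 1.98)
        assert d == pytest.approx(1.0, rel=1e-3)

    def test_zero_cells(self):
        assert cell_density(make_cells([]), (100, 100), 1.98) == 0.0

    def test_zero_area_errors(self):
        with pytest.raises(ValueError):
            cell_density(make_cells([]), (0, 100), 1.98)

    def test_poisson_generator_density_recovered(self):
        from tmequant.synthetic import FieldSpec, generate_field

        spec = FieldSpec(shape=(512, 512), n_cells=200, structure=(), seed=9,
                         min_separation_px=0.0, pixel_scale=1.98)
        _, truth, _ = generate_field(spec)
        area_mm2 = 512 * 512 / 1.98**2 / 1e6
        lam = 200 / area_mm2
        est = cell_density(truth, (512, 512), 1.98)
        assert est == pytest.approx(lam)  # count is exact by construction


class TestSplitRichPoor:
    def test_two_fields(self):
        part = split_rich_poor({"a": 0.1, "b": 0.3})
        assert part.cutoff == pytest.approx(0.2)
        assert part.rich == ["b"] and part.poor == ["a"]

    def test_all_equal_all_poor(self):
        part = split_rich_poor({"a": 0.2, "b": 0.2, "c": 0.2})
        assert part.rich == [] and set(part.poor) == {"a", "b", "c"}

    def test_matches_direct_comparison(self, rng):
        fr = rng.random(20)
        part = split_rich_poor({i: f for i, f in enumerate(fr)})
        cutoff = fr.mean()
        assert set(part.rich) == {i for i, f in enumerate(fr) if f > cutoff}
        assert set(part.poor) == {i for i, f in enumerate(fr) if f <= cutoff}

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            split_rich_poor({"a": 0.5})
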