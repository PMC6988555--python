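"""Lattice construction, depth masking, adjacency, and surface I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import overlapshift as o


def _haversine(lon1, lat1, lon2, lat2, r=6371.0):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(h))


class TestBuildGrid:
    def test_two_by_two_row_major_ids(self):
        g = o.build_grid(2, 2, cell_size_km=7.0)
        assert g.n_cells == 4
        assert list(g.cell_ids) == [0, 1, 2, 3]
        # row-major: cell 1 is east of cell 0, cell 2 north of cell 0
        assert g.lon[1] > g.lon[0] and g.lat[1] == g.lat[0]
        assert g.lat[2] > g.lat[0] and g.lon[2] == g.lon[0]

    def test_interior_rook_neighbors_on_full_lattice(self):
        g = o.build_grid(30, 30)
        adj = o.build_adjacency(g, "rook")
        degrees = adj.degrees
        rows, cols = g.rowcol(g.active_ids)
        interior = (rows > 0) & (rows < 29) & (cols > 0) & (cols < 29)
        assert g.n_cells == 900
        assert np.all(degrees[interior] == 4)

    def test_adjacent_centers_are_cell_size_apart(self):
        g = o.build_grid(6, 6, origin_lonlat=(0.0, 56.0), cell_size_km=7.0)
        # east-west neighbour at origin latitude and north-south neighbour
        d_ew = _haversine(g.lon[0], g.lat[0], g.lon[1], g.lat[1])
        d_ns = _haversine(g.lon[0], g.lat[0], g.lon[6], g.lat[6])
        assert abs(d_ew - 7.0) / 7.0 < 0.01
        assert abs(d_ns - 7.0) / 7.0 < 0.01

    @pytest.mark.parametrize("shape", [(1, 5), (5, 1), (0, 0)])
    def test_rejects_degenerate_dimensions(self, shape):
        with pytest.raises(ValueError):
            o.build_grid(*shape)

    def test_nan_depth_names_offending_cell(self):
        depth = np.full(9, 50.0)
        depth[4] = np.nan
        with pytest.raises(ValueError, match="cell 4"):
            o.build_grid(3, 3, depth_field=depth)


class TestDepthMask:
    def test_shallow_grid_keeps_all_cells(self):
        g = o.build_grid(3, 3, depth_field=np.full(9, 100.0))
        assert o.apply_depth_mask(g).n_active == 9

    def test_three_deep_cells_removed(self):
        depth = np.full(9, 100.0)
        depth[[0, 4, 8]] = 600.0
        g = o.apply_depth_mask(o.build_grid(3, 3, depth_field=depth))
        assert g.n_active == 6
        assert set(g.active_ids) == set(range(9)) - {0, 4, 8}

    def test_cell_exactly_at_threshold_is_retained(self):
        depth = np.full(9, 100.0)
        depth[4] = 500.0
        g = o.apply_depth_mask(o.build_grid(3, 3, depth_field=depth))
        assert 4 in g.active_ids

    def test_removing_every_cell_is_an_error(self):
        g = o.build_grid(2, 2, depth_field=np.full(4, 900.0))
        with pytest.raises(ValueError):
            o.apply_depth_mask(g)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_masking_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        depth = rng.uniform(10, 900, 36)
        if not np.any(depth <= 500):
            depth[0] = 100.0
        g = o.build_grid(6, 6, depth_field=depth)
        once = o.apply_depth_mask(g)
        twice = o.apply_depth_mask(once)
        assert np.array_equal(once.active_mask, twice.active_mask)


class TestAdjacency:
    def test_queen_center_degree_eight(self):
        g = o.build_grid(3, 3)
        adj = o.build_adjacency(g, "queen")
        assert adj.degrees[4] == 8

    def test_rook_center_degree_four(self):
        g = o.build_grid(3, 3)
        adj = o.build_adjacency(g, "rook")
        assert adj.degrees[4] == 4

    def test_masked_center_matches_brute_force(self):
        depth = np.full(9, 100.0)
        depth[4] = 600.0
        g = o.apply_depth_mask(o.build_grid(3, 3, depth_field=depth))
        adj = o.build_adjacency(g, "rook")
        # brute force on the masked lattice
        active = list(g.active_ids)
        expected = {}
        for cid in active:
            r, c = divmod(cid, 3)
            nbrs = [nr * 3 + nc for nr, nc in
                    [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
                    if 0 <= nr < 3 and 0 <= nc < 3 and (nr * 3 + nc) in active]
            expected[cid] = len(nbrs)
        got = dict(zip(adj.active_ids, adj.degrees))
        assert got == expected

    def test_unknown_contiguity_keyword(self):
        with pytest.raises(ValueError):
            o.build_adjacency(o.build_grid(3, 3), "bishop")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_zero_diagonal_for_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        depth = np.where(rng.random(49) < 0.3, 700.0, 50.0)
        depth[rng.integers(49)] = 50.0
        g = o.apply_depth_mask(o.build_grid(7, 7, depth_field=depth))
        adj = o.build_adjacency(g, "queen")
        m = adj.matrix
        assert (m != m.T).nnz == 0
        assert m.diagonal().sum() == 0


class TestSurfaceIO:
    def test_csv_round_trip_is_bit_exact(self, tmp_path, grid10):
        rng = np.random.default_rng(5)
        surf = o.SpeciesSurface(grid=grid10, values=rng.gamma(2, 1, 100),
                                family="gamma", name="sp")
        path = tmp_path / "surf.csv"
        o.write_surface(surf, path)
        back = o.read_surface(path, grid10, family="gamma")
        assert np.max(np.abs(back.values - surf.values)) == 0.0

    def test_netcdf_round_trip_preserves_active_cells(self, tmp_path):
        depth = np.full(36, 100.0)
        depth[[1, 7]] = 800.0
        g = o.apply_depth_mask(o.build_grid(6, 6, depth_field=depth))
        rng = np.random.default_rng(6)
        surf = o.SpeciesSurface(grid=g, values=rng.gamma(2, 1, g.n_active),
                                family="gamma")
        path = tmp_path / "surf.nc"
        o.write_surface(surf, path)
        back = o.read_surface(path, g)
        assert back.values.shape == (g.n_active,)
        np.testing.assert_allclose(back.values, surf.values, rtol=0, atol=1e-12)

    def test_unknown_cell_id_rejected(self, tmp_path, grid10):
        surf = o.SpeciesSurface(grid=grid10, values=np.ones(100), family="gamma")
        path = tmp_path / "surf.csv"
        o.write_surface(surf, path)
        text = path.read_text().replace("\n5,", "\n500,")
        path.write_text(text)
        with pytest.raises(ValueError, match="unknown"):
            o.read_surface(path, grid10)

    def test_negative_density_names_cell(self, tmp_path, grid10):
        surf = o.SpeciesSurface(grid=grid10, values=np.ones(100), family="gamma")
        path = tmp_path / "surf.csv"
        o.write_surface(surf, path)
        text = path.read_text().replace("\n3,", "\n3,", 1)
        lines = text.splitlines()
        parts = lines[4].split(",")
        parts[-1] = "-1.0"
        lines[4] = ",".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="cell 3"):
            o.read_surface(path, grid10)

    def test_zero_values_force_hurdle_family(self, grid10):
        values = np.ones(100)
        values[0] = 0.0
        with pytest.raises(ValueError):
            o.SpeciesSurface(grid=grid10, values=values, family="gamma")
        surf = o.SpeciesSurface(grid=grid10, values=values, family="hurdle-gamma")
        assert surf.zero_fraction == pytest.approx(0.01)
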