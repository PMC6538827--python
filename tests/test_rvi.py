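"""RVI core: downstream pairs, interpolation methods, region quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_rvi_maps
from rvimap.geometry import LabeledMesh, RecordingGrid
from rvimap.markers import MarkerMap
from rvimap.rvi import (
    RVIConfig,
    build_map,
    downstream_pairs,
    quantify_vulnerable_region,
    rvi_pair,
    sweep,
)
from rvimap.synthetic import FieldSpec, planar_wave_field


@pytest.fixture()
def toy():
    """Three collinear electrodes at 0/2/4 mm with AT 0/10/40, RT 200/215/260."""
    grid = RecordingGrid.from_points([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
    markers = MarkerMap(beat="S2", at=[0.0, 10.0, 40.0], rt=[200.0, 215.0, 260.0])
    return grid, markers


class TestPairsAndPairwise:
    def test_toy_enumeration(self, toy):
        grid, markers = toy
        pairs = downstream_pairs(markers, grid, radius=4.0)
        assert sorted(map(tuple, pairs)) == [(0, 1), (0, 2), (1, 2)]

    def test_radius_below_minimum_spacing_gives_no_pairs(self, toy):
        grid, markers = toy
        assert downstream_pairs(markers, grid, radius=1.0).shape == (0, 2)

    def test_simultaneous_activation_excluded(self):
        grid = RecordingGrid.from_points([[0.0, 0.0], [1.0, 0.0]])
        markers = MarkerMap(beat="S2", at=[5.0, 5.0], rt=[100.0, 100.0])
        assert downstream_pairs(markers, grid, radius=2.0).size == 0

    def test_undefined_sites_never_appear(self, toy):
        grid, markers = toy
        markers.at[1] = np.nan
        pairs = downstream_pairs(markers, grid, radius=4.0)
        assert sorted(map(tuple, pairs)) == [(0, 2)]

    def test_pairwise_index_values(self):
        assert rvi_pair(300.0, 250.0) == 50.0
        assert rvi_pair(100.0, 100.0) == 0.0
        assert rvi_pair(400.0, 450.0) == -50.0  # negative: re-entry capable
        assert np.isnan(rvi_pair(np.nan, 250.0))


class TestInterpolationMethods:
    def test_toy_minimum_and_average_maps(self, toy):
        grid, markers = toy
        # pairwise RVIs: (0,1)->190, (0,2)->160, (1,2)->175
        mmin = build_map(markers, grid, RVIConfig(radius=4, method="minimum"))
        mavg = build_map(markers, grid, RVIConfig(radius=4, method="average"))
        assert np.allclose(mmin.values[:2], [160.0, 175.0])
        assert np.isnan(mmin.values[2])  # no downstream neighbor
        assert np.allclose(mavg.values[:2], [175.0, 175.0])
        assert np.isnan(mavg.values[2])

    def test_toy_nearest_neighbor_midpoint_assignment(self, toy):
        grid, markers = toy
        nodes = np.column_stack([np.arange(5.0), np.zeros(5)])
        mesh = LabeledMesh(nodes=nodes, elements=np.empty((0, 4), int),
                           region=np.zeros(5, np.int8), node_area=np.ones(5),
                           resolution=1.0, shape=(1, 5))
        m = build_map(markers, grid, RVIConfig(radius=4, method="nearest_neighbor"),
                      mesh=mesh)
        assert m.site_kind == "mesh_node"
        assert np.allclose(m.values[1:4], [190.0, 160.0, 175.0])
        assert np.isnan(m.values[0]) and np.isnan(m.values[4])

    def test_nearest_neighbor_requires_mesh(self, toy):
        grid, markers = toy
        with pytest.raises(ValueError, match="mesh"):
            build_map(markers, grid, RVIConfig(radius=4, method="nearest_neighbor"))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            RVIConfig(method="median")

    def test_minimum_below_average_pointwise(self, regular_grid_2d):
        spec = FieldSpec(cv=0.4, apd=180.0, rt_gradient=0.5)
        markers = planar_wave_field(spec, regular_grid_2d)
        mmin = build_map(markers, regular_grid_2d, RVIConfig(radius=3, method="minimum"))
        mavg = build_map(markers, regular_grid_2d, RVIConfig(radius=3, method="average"))
        both = mmin.defined & mavg.defined
        assert both.any()
        assert (mmin.values[both] <= mavg.values[both] + 1e-12).all()

    def test_rigid_transform_invariance(self, toy):
        grid, markers = toy
        cfg = RVIConfig(radius=4.5, method="minimum")
        base = build_map(markers, grid, cfg).values
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = RecordingGrid.from_points(grid.electrodes @ rot.T + [7.0, -3.0])
        assert np.allclose(build_map(markers, moved, cfg).values, base,
                           equal_nan=True)

    @pytest.mark.parametrize("n,radius", [(40, 2.5), (120, 4.0), (200, 7.0)])
    def test_equivalence_with_brute_force_oracle(self, n, radius):
        rng = np.random.default_rng(n)
        pts = rng.uniform(0, 20, size=(n, 2))
        at = rng.uniform(0, 120, n)
        rt = at + rng.uniform(50, 250, n)
        at[rng.random(n) < 0.1] = np.nan  # scar / no-capture sites
        grid = RecordingGrid.from_points(pts)
        markers = MarkerMap(beat="S2", at=at, rt=np.where(np.isnan(at), np.nan, rt))
        nodes = np.column_stack([np.repeat(np.arange(0, 21, 1.0), 21),
                                 np.tile(np.arange(0, 21, 1.0), 21)])
        mesh = LabeledMesh(nodes=nodes, elements=np.empty((0, 4), int),
                           region=np.zeros(len(nodes), np.int8),
                           node_area=np.ones(len(nodes)), resolution=1.0,
                           shape=(21, 21))
        ref_min, ref_avg, ref_nn = brute_force_rvi_maps(markers, grid, radius, mesh)
        got_min = build_map(markers, grid, RVIConfig(radius=radius, method="minimum"))
        got_avg = build_map(markers, grid, RVIConfig(radius=radius, method="average"))
        got_nn = build_map(markers, grid,
                           RVIConfig(radius=radius, method="nearest_neighbor"),
                           mesh=mesh)
        assert np.allclose(got_min.values, ref_min, equal_nan=True)
        assert np.allclose(got_avg.values, ref_avg, equal_nan=True)
        assert np.allclose(got_nn.values, ref_nn, equal_nan=True)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=25), st.integers(0, 10_000),
           st.floats(min_value=0.5, max_value=10.0))
    def test_property_minimum_matches_oracle_on_random_sets(self, n, seed, radius):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 2))
        at = rng.uniform(0, 50, n)
        rt = at + rng.uniform(10, 100, n)
        grid = RecordingGrid.from_points(pts)
        markers = MarkerMap(beat="S2", at=at, rt=rt)
        ref_min, ref_avg, _ = brute_force_rvi_maps(markers, grid, radius)
        got = build_map(markers, grid, RVIConfig(radius=radius, method="minimum"))
        assert np.allclose(got.values, ref_min, equal_nan=True)


class TestRadiusBehavior:
    def _planar(self, grid):
        return planar_wave_field(FieldSpec(cv=0.5, apd=200.0), grid)

    def test_planar_wave_minimum_map_closed_form(self, regular_grid_2d):
        # furthest downstream neighbor within R lies straight ahead, so the
        # minimum map approaches APD - R/CV at interior sites
        markers = self._planar(regular_grid_2d)
        m = build_map(markers, regular_grid_2d, RVIConfig(radius=4, method="minimum"))
        interior = ((regular_grid_2d.electrodes[:, 1] < 15.0)
                    & (np.abs(regular_grid_2d.electrodes[:, 0] - 10.0) < 5.0))
        expect = 200.0 - 4.0 / 0.5
        tol = 0.5 / 0.5  # one grid spacing of activation delay
        assert np.abs(m.values[interior] - expect).max() <= tol + 1e-9

    def test_minimum_monotone_in_radius(self, regular_grid_2d):
        markers = self._planar(regular_grid_2d)
        prev = None
        for r in (2.0, 4.0, 8.0):
            vals = build_map(markers, regular_grid_2d,
                             RVIConfig(radius=r, method="minimum")).values
            if prev is not None:
                both = ~np.isnan(prev) & ~np.isnan(vals)
                assert (vals[both] <= prev[both] + 1e-12).all()
            prev = vals

    def test_average_bounded_by_pairwise_extremes(self, toy):
        grid, markers = toy
        m = build_map(markers, grid, RVIConfig(radius=4, method="average"))
        # site 0 pairs have RVIs 190 and 160
        assert 160.0 <= m.values[0] <= 190.0


class TestQuantification:
    def test_all_above_threshold_gives_zero_size(self, toy):
        grid, markers = toy
        m = build_map(markers, grid, RVIConfig(radius=4, method="minimum"))
        q = quantify_vulnerable_region(m, threshold=50.0)
        assert q.size == 0.0 and q.count == 0
        assert q.lowest == 160.0

    def test_nodal_area_convention(self):
        # two sub-threshold nodes on a 0.2 mm grid contribute 2 x 0.04 mm^2
        nodes = np.column_stack([np.arange(4) * 0.2, np.zeros(4)])
        mesh = LabeledMesh(nodes=nodes, elements=np.empty((0, 4), int),
                           region=np.zeros(4, np.int8),
                           node_area=np.full(4, 0.04), resolution=0.2,
                           shape=(1, 4))
        from rvimap.rvi import RVIMap

        m = RVIMap(values=np.array([10.0, 20.0, 60.0, np.nan]),
                   site_kind="mesh_node", positions=nodes,
                   config=RVIConfig(radius=1.0, method="minimum"))
        q = quantify_vulnerable_region(m, mesh=mesh, threshold=50.0)
        assert q.size == pytest.approx(0.08)
        assert q.count == 2 and q.lowest == 10.0

    def test_no_defined_values(self):
        from rvimap.rvi import RVIMap

        m = RVIMap(values=np.array([np.nan, np.nan]), site_kind="electrode",
                   positions=np.zeros((2, 2)),
                   config=RVIConfig(radius=1.0, method="minimum"))
        q = quantify_vulnerable_region(m, threshold=50.0)
        assert q.size == 0.0 and q.count == 0 and np.isnan(q.lowest)

    def test_threshold_is_strict(self):
        from rvimap.rvi import RVIMap

        m = RVIMap(values=np.array([50.0, 49.999]), site_kind="electrode",
                   positions=np.zeros((2, 2)),
                   config=RVIConfig(radius=1.0, method="minimum"))
        assert quantify_vulnerable_region(m, threshold=50.0).count == 1


class TestSweep:
    def test_single_cell_matches_direct_call(self, regular_grid_2d):
        markers = planar_wave_field(FieldSpec(cv=0.5, apd=200.0), regular_grid_2d)
        table = sweep(markers, regular_grid_2d, methods=["minimum"], radii=[4.0])
        assert len(table) == 1
        m = build_map(markers, regular_grid_2d, RVIConfig(radius=4, method="minimum"))
        q = quantify_vulnerable_region(m, threshold=50.0)
        row = table.iloc[0]
        assert row["lowest_rvi_ms"] == pytest.approx(q.lowest)
        assert row["n_sites_below"] == q.count

    def test_minimum_method_columns_monotone_in_radius(self, regular_grid_2d):
        spec = FieldSpec(cv=0.5, apd=90.0)  # APD - R/CV crosses 50 ms threshold
        markers = planar_wave_field(spec, regular_grid_2d)
        table = sweep(markers, regular_grid_2d, methods=["minimum"],
                      radii=[2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
        t = table[table.method == "minimum"].sort_values("radius_mm")
        assert (np.diff(t["n_sites_below"]) >= 0).all()
        assert (np.diff(t["lowest_rvi_ms"]) <= 1e-12).all()
        # once R spans the extreme pair, the lowest value saturates
        assert t["lowest_rvi_ms"].iloc[-1] == t["lowest_rvi_ms"].iloc[-2]

    def test_row_count_is_methods_times_radii(self, regular_grid_2d):
        markers = planar_wave_field(FieldSpec(cv=0.5, apd=200.0), regular_grid_2d)
        table = sweep(markers, regular_grid_2d,
                      methods=["minimum", "average"], radii=[2.0, 4.0, 8.0])
        assert len(table) == 6
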