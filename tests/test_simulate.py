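import json

import numpy as np
import pytest

from flyway.environment import OceanMask, synth_environment
from flyway.grid import GridSpec, great_circle_distance
from flyway.potential import ModelParams
from flyway.simulate import (COLONIES, Colony, default_a_grid,
                             default_kt_grid, directional_split,
                             simulate_bird, simulate_ensemble, snap_to_ocean,
                             sweep_parameters, trajectories_to_dataframe,
                             write_trajectories_csv,
                             write_trajectories_geojson)

PARAMS = ModelParams(a=0.002, kT=0.1)


class TestColonyTable:
    def test_documented_colonies_present_with_coordinates(self):
        assert COLONIES["diego-ramirez"].lat == -56.5
        assert COLONIES["diego-ramirez"].lon == -68.7
        assert COLONIES["falklands"].lat == -51.0
        assert COLONIES["kerguelen"].lon == 70.0
        assert COLONIES["macquarie"].lon == 158.9
        assert COLONIES["south-georgia"].lat == -54.2
        assert len(COLONIES) == 5

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Colony("bad", -91.0, 0.0)


class TestSnapToOcean:
    def test_colony_at_ocean_cell_centre_maps_to_it(self, grid16):
        mask = OceanMask(grid16, np.ones(grid16.shape, bool))
        lat, lon = grid16.cell_center((10, 3))
        assert snap_to_ocean(Colony("c", lat, lon), mask) == (10, 3)

    def test_one_cell_island_snaps_to_adjacent_ocean(self, grid16):
        is_ocean = np.ones(grid16.shape, bool)
        is_ocean[10, 3] = False
        mask = OceanMask(grid16, is_ocean)
        lat, lon = grid16.cell_center((10, 3))
        cell = snap_to_ocean(Colony("island", lat, lon), mask)
        assert grid16.are_adjacent((10, 3), cell)
        # exhaustive scan oracle: no ocean cell is strictly closer
        rows, cols = np.nonzero(is_ocean)
        best = min(great_circle_distance((10, 3), (r, c), grid16)
                   for r, c in zip(rows, cols))
        assert great_circle_distance((10, 3), cell, grid16) == pytest.approx(best)

    def test_tie_broken_to_smallest_row_col(self, grid16):
        # east and west neighbours are exactly equidistant; west has lower col
        is_ocean = np.zeros(grid16.shape, bool)
        is_ocean[10, 2] = True
        is_ocean[10, 4] = True
        mask = OceanMask(grid16, is_ocean)
        lat, lon = grid16.cell_center((10, 3))
        assert snap_to_ocean(Colony("c", lat, lon), mask) == (10, 2)

    def test_falklands_snap_on_quarter_degree_ocean(self):
        grid = GridSpec(720, 1440, 0.25)
        mask = OceanMask(grid, np.ones(grid.shape, bool))
        cell = snap_to_ocean(COLONIES["falklands"], mask)
        assert cell == grid.cell_of(-51.0, -61.1)


class TestSimulateBird:
    def test_zero_duration_gives_start_only(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        traj = simulate_bird(colony_south, PARAMS, envs, duration_months=0,
                             seed=1)
        assert len(traj.steps) == 1
        assert traj.steps[0].clock_h == 0.0

    def test_reproducible_for_fixed_seed(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        a = simulate_bird(colony_south, PARAMS, envs, duration_months=1, seed=5)
        b = simulate_bird(colony_south, PARAMS, envs, duration_months=1, seed=5)
        assert a.steps == b.steps

    def test_run_covers_window_with_final_partial_step(self, grid32,
                                                       colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        traj = simulate_bird(colony_south, PARAMS, envs, duration_months=1,
                             seed=2)
        clocks = [s.clock_h for s in traj.steps]
        assert clocks[-1] >= 720.0  # April
        assert clocks[-2] < 720.0   # ended at the first crossing step
        assert all(b > a for a, b in zip(clocks, clocks[1:]))

    def test_missing_month_is_error(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        with pytest.raises(ValueError, match="month"):
            simulate_bird(colony_south, PARAMS, envs, duration_months=2)

    def test_trajectory_is_legal(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, {"u": 5.0}, months=(4,))
        mask = envs[0].mask.is_ocean
        traj = simulate_bird(colony_south, PARAMS, envs, duration_months=1,
                             seed=3)
        for s in traj.steps:
            assert mask[s.row, s.col]
        for a, b in zip(traj.steps, traj.steps[1:]):
            assert grid32.are_adjacent((a.row, a.col), (b.row, b.col))


class TestSimulateEnsemble:
    def test_single_bird_matches_simulate_bird(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs, n_birds=1,
                                   base_seed=9, duration_months=1)
        solo = simulate_bird(colony_south, PARAMS, envs, duration_months=1,
                             seed=9)
        assert result.trajectories[0].steps == solo.steps

    def test_default_ensemble_size_is_sixteen(self, grid16, colony_south):
        envs = synth_environment("ring_world", grid16, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs,
                                   duration_months=1)
        assert len(result.trajectories) == 16

    def test_same_base_seed_reproduces_result(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        r1 = simulate_ensemble(colony_south, PARAMS, envs, n_birds=4,
                               base_seed=77, duration_months=1)
        r2 = simulate_ensemble(colony_south, PARAMS, envs, n_birds=4,
                               base_seed=77, duration_months=1)
        for a, b in zip(r1.trajectories, r2.trajectories):
            assert a.steps == b.steps
        np.testing.assert_array_equal(r1.occupancy, r2.occupancy)

    def test_occupancy_and_endpoint_accounting(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs, n_birds=6,
                                   base_seed=1, duration_months=1)
        n_birds = len(result.trajectories)
        total_steps = sum(len(t.steps) - 1 for t in result.trajectories)
        assert result.endpoints.sum() == n_birds
        assert result.occupancy.sum() == total_steps + n_birds
        assert (result.occupancy >= 0).all()


class TestSweep:
    def test_default_grids_produce_thirty_two_pairs(self):
        assert len(default_a_grid()) == 8
        assert len(default_kt_grid()) == 4
        assert default_a_grid()[0] == 0.001 and default_a_grid()[-1] == 0.008
        assert default_kt_grid() == [0.05, 0.1, 0.15, 0.2]

    def test_single_pair_sweep(self, grid16, colony_south):
        envs = synth_environment("ring_world", grid16, months=(4,))
        results = sweep_parameters(colony_south, [0.002], [0.1], envs,
                                   n_birds=2, base_seed=1, duration_months=1)
        assert len(results) == 1
        assert results[0].params == ModelParams(a=0.002, kT=0.1)

    def test_empty_grid_rejected(self, grid16, colony_south):
        envs = synth_environment("ring_world", grid16, months=(4,))
        with pytest.raises(ValueError):
            sweep_parameters(colony_south, [], [0.1], envs)

    def test_pair_seeding_is_stable_under_extension(self, grid16,
                                                    colony_south):
        envs = synth_environment("ring_world", grid16, months=(4,))
        short = sweep_parameters(colony_south, [0.001], [0.05, 0.1], envs,
                                 n_birds=2, base_seed=3, duration_months=1)
        long = sweep_parameters(colony_south, [0.001, 0.002], [0.05, 0.1],
                                envs, n_birds=2, base_seed=3,
                                duration_months=1)
        for a, b in zip(short, long[:2]):
            for ta, tb in zip(a.trajectories, b.trajectories):
                assert ta.steps == tb.steps

    def test_lower_kT_has_lower_move_entropy(self, grid32, colony_south):
        # Boltzmann entropy over permitted moves shrinks as kT drops
        from flyway.movement import move_probabilities
        from flyway.potential import PotentialCache, local_potential
        envs = synth_environment("zonal_jet", grid32, seed=5, months=(4,))
        env = envs[0]
        cache = PotentialCache()
        rows, cols = np.nonzero(env.mask.is_ocean)
        rng = np.random.default_rng(0)
        idx = rng.choice(rows.size, size=30, replace=False)
        entropies = {}
        for kT in (0.05, 0.2):
            h = []
            for k in idx:
                lp = local_potential(env, (int(rows[k]), int(cols[k])),
                                     ModelParams(a=0.005, kT=kT), cache)
                p = move_probabilities(lp, kT).probabilities
                p = p[p > 0]
                h.append(float(-(p * np.log(p)).sum()))
            entropies[kT] = np.mean(h)
        assert entropies[0.05] < entropies[0.2]


class TestDirectionalSplit:
    def test_all_on_start_meridian_counts_east(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs, n_birds=3,
                                   base_seed=0, duration_months=0)
        fe, fw = directional_split(result)
        assert (fe, fw) == (1.0, 0.0)

    def test_fractions_sum_to_one(self, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs, n_birds=8,
                                   base_seed=4, duration_months=1)
        fe, fw = directional_split(result)
        assert fe + fw == pytest.approx(1.0)


class TestOutputs:
    def test_trajectory_dataframe_columns_and_coords(self, grid32,
                                                     colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs, n_birds=2,
                                   base_seed=0, duration_months=1)
        df = trajectories_to_dataframe(result.trajectories, grid32)
        assert list(df.columns) == ["bird_id", "step", "clock_h", "month",
                                    "row", "col", "lat", "lon"]
        assert df["lat"].between(-90, 90).all()
        assert df["lon"].between(-180, 180).all()
        assert set(df["bird_id"]) == {0, 1}

    def test_geojson_lines_split_at_dateline(self, tmp_path, grid32):
        envs = synth_environment("ring_world", grid32, {"u": 20.0},
                                 months=(4,))
        colony = Colony("dateline", -50.0, 178.0)
        result = simulate_ensemble(colony, ModelParams(a=0.02, kT=0.05), envs,
                                   n_birds=1, base_seed=0, duration_months=1)
        path = tmp_path / "t.geojson"
        write_trajectories_geojson(path, result.trajectories, grid32)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        geom = doc["features"][0]["geometry"]
        coords = (geom["coordinates"] if geom["type"] == "MultiLineString"
                  else [geom["coordinates"]])
        for segment in coords:
            lons = [c[0] for c in segment]
            assert all(abs(b - a) <= 180.0 for a, b in zip(lons, lons[1:]))

    def test_csv_writer_runs(self, tmp_path, grid32, colony_south):
        envs = synth_environment("ring_world", grid32, months=(4,))
        result = simulate_ensemble(colony_south, PARAMS, envs, n_birds=1,
                                   base_seed=0, duration_months=1)
        path = tmp_path / "t.csv"
        write_trajectories_csv(path, result.trajectories, grid32)
        assert path.read_text().startswith("bird_id,")
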