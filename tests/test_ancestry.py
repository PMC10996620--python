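"""Spatiotemporal ancestry coefficients and flux against path-walk oracles."""

import numpy as np
import pandas as pd
import pytest

from geoanc.ancestry import (ancestry_coefficients, ancestry_flux,
                             replicate_and_average)
from geoanc.errors import ParameterError
from geoanc.geography import build_planar_grid
from geoanc.history import HistorySampler, MigrationHistory, location_at, \
    sample_histories_for_ts
from geoanc.locate import average_cost_functions
from geoanc.workflow import draw_node_cells, replicate_summaries

from conftest import build_ts, georeferenced, msprime_tree_sequence, \
    random_connected_grid


def single_branch_tsw():
    """One sample under one root: a single lineage from t=0 to t=10."""
    return build_ts([0, 10], [1, 0], [(0, 100, 1, 0)], 100.0, {0: 0})


class TestCoefficients:
    def test_single_branch_hand_trace(self):
        # the lineage sits in cell 0 for t in [0,4) and in cell 1 afterwards
        tsw = single_branch_tsw()
        h = MigrationHistory(0, 0.0, 10.0, [0, 1], [4.0])
        z = ancestry_coefficients(tsw, {0: h}, {"i": [0]},
                                  times=[2.0, 6.0])
        zi = z.set_index(["region", "time"])["z"]
        assert zi.loc[(0, 2.0)] == 1.0
        assert zi.loc[(1, 6.0)] == 1.0

    def test_all_ancestors_one_region_gives_unity(self, rng):
        ts = msprime_tree_sequence(5, n=5, recombination_rate=1e-3)
        grid, _cm = random_connected_grid(rng, 4)
        tsw = georeferenced(ts, rng, mode="discrete", n_cells=4)
        cells = {u: 2 for u in range(ts.num_nodes)}
        sampler = HistorySampler(grid, seed=0)
        hist = sample_histories_for_ts(tsw, cells, sampler)
        times = np.linspace(0, ts.max_root_time * 0.95, 6)
        z = ancestry_coefficients(tsw, hist, {"i": list(tsw.samples())},
                                  times=times)
        ok = z[z["A"] > 0]
        assert set(ok["region"]) == {2}
        assert np.allclose(ok["z"], 1.0)

    def test_beyond_oldest_root_is_missing(self):
        tsw = single_branch_tsw()
        h = MigrationHistory(0, 0.0, 10.0, [0], [])
        z = ancestry_coefficients(tsw, {0: h}, {"i": [0]}, times=[12.0])
        assert list(z["A"]) == [0.0]
        assert z["z"].isna().all()

    def test_present_day_composition_matches_sampling(self, rng):
        ts = msprime_tree_sequence(9, n=8, recombination_rate=1e-3)
        grid, _cm = random_connected_grid(rng, 5)
        tsw = georeferenced(ts, rng, mode="discrete", n_cells=5)
        F = average_cost_functions(tsw, _cm)
        cells = draw_node_cells(F, np.random.default_rng(1))
        hist = sample_histories_for_ts(tsw, cells,
                                       HistorySampler(grid, seed=2))
        subset = list(tsw.samples())
        z = ancestry_coefficients(tsw, hist, {"i": subset}, times=[0.0])
        expect = pd.Series([tsw.locations[s] for s in subset]
                           ).value_counts(normalize=True)
        got = z.set_index("region")["z"]
        for cell, frac in expect.items():
            assert abs(got.loc[cell] - frac) < 1e-12


class TestFlux:
    def test_single_branch_window_indicator(self):
        tsw = single_branch_tsw()
        h = MigrationHistory(0, 0.0, 10.0, [0, 1], [4.0])
        fl = ancestry_flux(tsw, {0: h}, {"i": [0]}, windows=[(0.0, 10.0)])
        fl = fl.set_index(["region_from", "region_to"])
        # forward in time the ancestor moved from region 1 into region 0
        assert fl.loc[(1, 0), "phi"] == 1.0
        assert len(fl) == 1

    def test_no_events_in_window_gives_zero(self):
        tsw = single_branch_tsw()
        h = MigrationHistory(0, 0.0, 10.0, [0, 1], [4.0])
        fl = ancestry_flux(tsw, {0: h}, {"i": [0]}, windows=[(5.0, 10.0)])
        assert np.all(fl["phi"] == 0.0)

    def test_two_moves_count_once(self):
        # 0 -> 1 -> 0 -> 1: two forward-time 1->0 moves in one window still
        # contribute the indicator once
        tsw = single_branch_tsw()
        h = MigrationHistory(0, 0.0, 10.0, [0, 1, 0, 1], [2.0, 5.0, 8.0])
        fl = ancestry_flux(tsw, {0: h}, {"i": [0]}, windows=[(0.0, 10.0)])
        fl = fl.set_index(["region_from", "region_to"])
        assert fl.loc[(1, 0), "phi"] == 1.0
        assert fl.loc[(0, 1), "phi"] == 1.0

    def test_single_region_flux_is_zero(self, rng):
        ts = msprime_tree_sequence(5, n=5, recombination_rate=1e-3)
        grid, _cm = random_connected_grid(rng, 4)
        tsw = georeferenced(ts, rng, mode="discrete", n_cells=4)
        F = average_cost_functions(tsw, _cm)
        cells = draw_node_cells(F, np.random.default_rng(3))
        hist = sample_histories_for_ts(tsw, cells,
                                       HistorySampler(grid, seed=4))
        regions = {c: "world" for c in range(grid.num_cells)}
        fl = ancestry_flux(tsw, hist, {"i": list(tsw.samples())},
                           regions=regions,
                           windows=[(0.0, ts.max_root_time)])
        assert np.all(fl["phi"] == 0.0)

    def test_overlapping_windows_rejected(self):
        tsw = single_branch_tsw()
        with pytest.raises(ParameterError):
            ancestry_flux(tsw, {}, {"i": [0]},
                          windows=[(0.0, 5.0), (4.0, 8.0)])

    def test_matches_brute_force_path_walk(self, rng):
        # exhaustive per-(sample, tree, window) walk over the same histories
        ts = msprime_tree_sequence(13, n=5, recombination_rate=2e-3)
        grid, _cm = random_connected_grid(rng, 4)
        tsw = georeferenced(ts, rng, mode="discrete", n_cells=4)
        F = average_cost_functions(tsw, _cm)
        cells = draw_node_cells(F, np.random.default_rng(5))
        hist = sample_histories_for_ts(tsw, cells,
                                       HistorySampler(grid, seed=6))
        samples = list(tsw.samples())
        windows = [(0.0, 1.0), (1.0, 3.0)]
        times = [0.0, 0.5, 1.5]
        z = ancestry_coefficients(tsw, hist, {"i": samples}, times=times)
        fl = ancestry_flux(tsw, hist, {"i": samples}, windows=windows)
        # oracle: walk every sample's path in every tree independently
        zA = {t: {} for t in times}
        zden = {t: 0.0 for t in times}
        flA, flden = {w: {} for w in windows}, {w: 0.0 for w in windows}
        for tree in tsw.ts.trees():
            span = tree.interval.right - tree.interval.left
            for s in samples:
                path = []
                u = s
                while tree.parent(u) != -1:
                    path.append((tree.edge(u), tree.time(u),
                                 tree.time(tree.parent(u))))
                    u = tree.parent(u)
                for t in times:
                    for eid, lo, hi in path:
                        if lo <= t < hi:
                            zden[t] += span
                            c = location_at(hist[eid], t)
                            zA[t][c] = zA[t].get(c, 0.0) + span
                for w in windows:
                    if not path:
                        continue
                    lo0 = min(p[1] for p in path)
                    hi0 = max(p[2] for p in path)
                    if not (lo0 < w[1] and hi0 > w[0]):
                        continue
                    flden[w] += span
                    seen = set()
                    for eid, lo, hi in path:
                        for tau, a, b in hist[eid].forward_moves():
                            if w[0] <= tau < w[1] and a != b:
                                seen.add((a, b))
                    for pair in seen:
                        flA[w][pair] = flA[w].get(pair, 0.0) + span
        for _, row in z[z["A"] > 0].iterrows():
            t = row["time"]
            assert abs(row["z"] - zA[t].get(row["region"], 0) / zden[t]) < 1e-12
        for _, row in fl.iterrows():
            w = (row["t_left"], row["t_right"])
            if row["region_from"] is None:
                continue
            expect = flA[w].get((row["region_from"], row["region_to"]), 0.0)
            assert abs(row["phi"] - expect / flden[w]) < 1e-12


class TestReplicates:
    def test_single_replicate_identity(self):
        tsw = single_branch_tsw()
        h = MigrationHistory(0, 0.0, 10.0, [0, 1], [4.0])

        def pipeline(rng):
            return ancestry_coefficients(tsw, {0: h}, {"i": [0]},
                                         times=[2.0, 6.0])

        out = replicate_and_average(pipeline, 1, 3,
                                    ["subset", "region", "time"])
        zi = out.set_index(["region", "time"])["z_mean"]
        assert zi.loc[(0, 2.0)] == 1.0 and zi.loc[(1, 6.0)] == 1.0

    def test_deterministic_pipeline_zero_spread(self, rng):
        ts = msprime_tree_sequence(5, n=5, recombination_rate=1e-3)
        grid, cm = random_connected_grid(rng, 4)
        tsw = georeferenced(ts, rng, mode="discrete", n_cells=4)
        tsw.locations = {k: 1 for k in tsw.locations}
        times = np.linspace(0, ts.max_root_time * 0.9, 4)
        z, _ = replicate_summaries(tsw, cm, grid, {"i": list(tsw.samples())},
                                   times=times, n_replicates=4, seed=9)
        assert np.allclose(z["z_mean"], z["z_min"])
        assert np.allclose(z["z_mean"], z["z_max"])

    def test_tie_average_converges_to_mixture(self):
        # two samples in cells 0 and 2 of a path grid: the root ties between
        # all three cells... construct instead a clean 2-way tie with two
        # cells: samples at the two ends of a 2-cell grid
        grid = build_planar_grid((0, 0, 2, 1), 1.0, "square")
        from geoanc.geography import cost_matrix_from_adjacency
        cm = cost_matrix_from_adjacency(grid)
        tsw = build_ts([0, 0, 1], [1, 1, 0],
                       [(0, 10, 2, 0), (0, 10, 2, 1)], 10.0, {0: 0, 1: 1})
        n = 400
        times = [0.5]
        z, _ = replicate_summaries(tsw, cm, grid, {"i": [0, 1]},
                                   times=times, n_replicates=n, seed=11)
        # at t=0.5 each sample lineage is at its own end regardless of the
        # root draw, so spread comes only through history sampling: instead
        # check the root tie via direct draws
        F = average_cost_functions(tsw, cm)
        draws = [draw_node_cells(F, np.random.default_rng(s))[2]
                 for s in range(n)]
        frac = np.mean(np.array(draws) == 0)
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)
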