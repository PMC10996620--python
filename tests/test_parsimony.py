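"""Parsimony fits against enumeration oracles and closed forms."""

import numpy as np
import pytest

from geoanc.costfuncs import DiscreteCost, PointCost
from geoanc.errors import DataError, DisconnectedGridError
from geoanc.geography import build_planar_grid, cost_matrix_from_adjacency
from geoanc.parsimony import brute_force_fit, fit_tree, minimize
from geoanc.trees import LocalTree

from conftest import random_connected_grid, random_local_tree


def star_tree(n_leaves, root_time=1.0):
    parent = {u: n_leaves for u in range(n_leaves)} | {n_leaves: -1}
    children = {u: [] for u in range(n_leaves)} | {
        n_leaves: list(range(n_leaves))}
    time = {u: 0.0 for u in range(n_leaves)} | {n_leaves: root_time}
    return LocalTree(0, 1, parent, children, time,
                     list(range(n_leaves + 1)), [n_leaves],
                     samples=set(range(n_leaves)))


def cherry(times=(0.0, 0.0, 1.0)):
    return LocalTree(0, 1, {0: 2, 1: 2, 2: -1}, {0: [], 1: [], 2: [0, 1]},
                     {0: times[0], 1: times[1], 2: times[2]}, [0, 1, 2], [2],
                     samples={0, 1})


def path_grid_costs(n):
    grid = build_planar_grid((0, 0, n, 1), 1.0, "square")
    return cost_matrix_from_adjacency(grid)


class TestDiscreteExamples:
    def test_star_tree_on_path_grid(self):
        # samples at cells A, A, B of the path A-B-C; enumeration gives the
        # root vector (1, 2, 5) with its minimum 1 at A
        cm = path_grid_costs(3)
        tree = star_tree(3)
        f = fit_tree(tree, {0: 0, 1: 0, 2: 1}, cm)
        np.testing.assert_array_equal(f[3].values, [1.0, 2.0, 5.0])
        val, cells = minimize(f[3])
        assert val == 1.0 and list(cells) == [0]

    def test_missing_sample_state_raises(self):
        with pytest.raises(DataError):
            fit_tree(star_tree(3), {0: 0, 1: 0}, path_grid_costs(3))

    def test_disconnected_grid_raises(self):
        C = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(DisconnectedGridError):
            fit_tree(cherry(), {0: 0, 1: 1}, C)


class TestContinuousExamples:
    def test_unweighted_cherry_midpoint(self):
        f = fit_tree(cherry(), {0: (0, 0), 1: (2, 0)}, "quadratic")
        val, ((xl, xh), (yl, yh)) = minimize(f[2])
        assert val == 2.0 and xl == xh == 1.0 and yl == yh == 0.0

    def test_weighted_cherry_is_weighted_mean(self):
        # branch lengths 3 (leaf at x=0) and 1 (leaf at x=2): weights 1/3, 1
        tree = cherry(times=(0.0, 2.0, 3.0))
        f = fit_tree(tree, {0: (0, 0), 1: (2, 0)}, "quadratic",
                     weighting="inverse")
        _, ((x, _), _) = minimize(f[2])
        w1, w2 = 1.0 / 3.0, 1.0
        assert abs(x - (w1 * 0 + w2 * 2) / (w1 + w2)) < 1e-12

    @pytest.mark.parametrize("w1,w2,x1,x2", [
        (1.0, 1.0, 0.0, 2.0), (0.25, 4.0, -1.5, 3.0), (2.0, 0.5, 1.0, 7.0)])
    def test_two_leaf_closed_form(self, w1, w2, x1, x2):
        tree = cherry(times=(1.0 - 1.0 / w1, 1.0 - 1.0 / w2, 1.0))
        f = fit_tree(tree, {0: (x1, 0), 1: (x2, 0)}, "quadratic",
                     weighting="inverse")
        _, ((x, _), _) = minimize(f[2])
        assert abs(x - (w1 * x1 + w2 * x2) / (w1 + w2)) < 1e-12

    def test_manhattan_star_median(self):
        f = fit_tree(star_tree(3), {0: (0, 0), 1: (1, 0), 2: (5, 0)},
                     "manhattan")
        val, ((xl, xh), _) = minimize(f[3])
        assert val == 5.0 and xl == xh == 1.0


class TestDiscreteOracle:
    def test_matches_enumeration_exactly(self, rng):
        for trial in range(40):
            n_leaves = int(rng.integers(3, 8))
            n_cells = int(rng.integers(2, 6))
            tree = random_local_tree(rng, n_leaves)
            _grid, cm = random_connected_grid(rng, n_cells)
            states = {u: int(rng.integers(0, n_cells))
                      for u in range(n_leaves)}
            weighting = ("inverse_branch_length" if trial % 2 else "none")
            f = fit_tree(tree, states, cm, weighting)
            bf = brute_force_fit(tree, states, cm, weighting)
            for u in tree.nodes:
                np.testing.assert_array_equal(f[u].values, bf[u].values)


class TestContinuousOracle:
    def _check(self, rng, mode):
        n_leaves = int(rng.integers(3, 6))
        tree = random_local_tree(rng, n_leaves, polytomies=True)
        states = {u: tuple(rng.uniform(0, 3, size=2))
                  for u in range(n_leaves)}
        weighting = "inverse_branch_length" if rng.integers(2) else "none"
        f = fit_tree(tree, states, mode, weighting)
        W = sum(1.0 / tree.branch_length(u) if weighting != "none" else 1.0
                for u in tree.nodes if tree.parent[u] != -1)
        if mode == "manhattan":
            # optima lie on leaf coordinates: the leaf-coordinate grid oracle
            # is exact there
            for axis in (0, 1):
                grid = np.unique([states[u][axis] for u in tree.samples])
                bf = brute_force_fit(tree, states, mode, weighting, grid=grid)
                for u in tree.nodes:
                    if u in tree.samples:
                        continue
                    mine = (f[u].fx if axis == 0 else f[u].fy).evaluate(grid)
                    np.testing.assert_allclose(mine, bf[u][axis], atol=1e-9)
        else:
            lo = min(min(s) for s in states.values()) - 0.5
            hi = max(max(s) for s in states.values()) + 0.5
            grid = np.linspace(lo, hi, 25)
            h = grid[1] - grid[0]
            bf = brute_force_fit(tree, states, mode, weighting, grid=grid)
            for u in tree.nodes:
                if u in tree.samples:
                    continue
                for axis in (0, 1):
                    mine = (f[u].fx if axis == 0 else f[u].fy).evaluate(grid)
                    gap = bf[u][axis] - mine
                    # rounding an optimal assignment to the grid costs at
                    # most 2h*sqrt(W*f) + W*h^2
                    bound = 2 * h * np.sqrt(W * np.maximum(mine, 0)) + W * h * h
                    assert np.all(gap >= -1e-9)
                    assert np.all(gap <= bound + 1e-9)

    def test_quadratic_matches_grid_oracle(self, rng):
        for _ in range(15):
            self._check(rng, "quadratic")

    def test_manhattan_matches_leaf_grid_oracle(self, rng):
        for _ in range(15):
            self._check(rng, "manhattan")


class TestProperties:
    def test_translation_equivariance(self, rng):
        tree = random_local_tree(rng, 5)
        states = {u: tuple(rng.uniform(0, 3, size=2)) for u in range(5)}
        v = (2.5, -1.25)
        for mode in ("quadratic", "manhattan"):
            f0 = fit_tree(tree, states, mode)
            f1 = fit_tree(tree, {u: (s[0] + v[0], s[1] + v[1])
                                 for u, s in states.items()}, mode)
            for u in tree.nodes:
                if u in tree.samples:
                    continue
                v0, ((a0, b0), (c0, d0)) = minimize(f0[u])
                v1, ((a1, b1), (c1, d1)) = minimize(f1[u])
                assert abs(v0 - v1) < 1e-9
                assert abs(a1 - a0 - v[0]) < 1e-9
                assert abs(c1 - c0 - v[1]) < 1e-9

    def test_identical_samples_give_zero_cost(self, rng):
        tree = random_local_tree(rng, 6)
        for mode, state in (("quadratic", (1.5, 2.5)),
                            ("manhattan", (1.5, 2.5))):
            f = fit_tree(tree, {u: state for u in range(6)}, mode)
            for u in tree.nodes:
                val, _ = minimize(f[u])
                assert abs(val) < 1e-12
        _grid, cm = random_connected_grid(rng, 4)
        f = fit_tree(tree, {u: 2 for u in range(6)}, cm)
        for u in tree.nodes:
            if u not in tree.samples:
                val, cells = minimize(f[u])
                assert val == 0.0 and 2 in cells

    def test_adding_a_leaf_never_decreases_cost(self, rng):
        # grafting an extra sampled leaf onto the root adds constraints
        for _ in range(10):
            n = int(rng.integers(3, 6))
            n_cells = int(rng.integers(2, 5))
            tree = random_local_tree(rng, n)
            _grid, cm = random_connected_grid(rng, n_cells)
            states = {u: int(rng.integers(0, n_cells)) for u in range(n)}
            root = tree.roots[0]
            f0 = fit_tree(tree, states, cm)
            extra = max(tree.nodes) + 1
            tree.parent[extra] = root
            tree.children[extra] = []
            tree.children[root] = sorted(tree.children[root] + [extra])
            tree.time[extra] = 0.0
            tree.nodes.insert(0, extra)
            tree.samples.add(extra)
            states[extra] = int(rng.integers(0, n_cells))
            f1 = fit_tree(tree, states, cm)
            for u in f0:
                if isinstance(f0[u], DiscreteCost):
                    assert np.all(f1[u].values >= f0[u].values - 1e-12)

    def test_sample_nodes_get_degenerate_functions(self, rng):
        tree = random_local_tree(rng, 4)
        f = fit_tree(tree, {u: (float(u), 0.0) for u in range(4)},
                     "quadratic")
        assert isinstance(f[0], PointCost) and f[0].x == 0.0
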