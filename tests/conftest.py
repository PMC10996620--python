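"""Shared generators for random trees, grids, and tree sequences."""

import msprime
import numpy as np
import pytest

from geoanc.geography import GeoGrid, cost_matrix_from_adjacency
from geoanc.trees import LocalTree, TreeSeq

# Power-of-two branch lengths make every branch weight (1 or 1/t) and every
# weighted cost sum exactly representable in binary floating point, so
# DP-vs-enumeration comparisons can assert bitwise equality.
POW2_LENGTHS = (0.25, 0.5, 1.0, 2.0, 4.0)


def random_local_tree(rng, n_leaves, polytomies=True):
    """A random rooted tree with power-of-two branch lengths.

    Topology is built by randomly merging 2-3 roots at a time; times are
    then assigned top-down so every branch length is an exact power of two
    (leaves end at unequal, possibly negative, times — only time
    differences enter the fits).
    """
    next_id = n_leaves
    parent = {u: -1 for u in range(n_leaves)}
    children = {u: [] for u in range(n_leaves)}
    roots = list(range(n_leaves))
    while len(roots) > 1:
        k = int(rng.integers(2, 4)) if polytomies and len(roots) > 2 else 2
        k = min(k, len(roots))
        picks = sorted(rng.choice(len(roots), size=k, replace=False),
                       reverse=True)
        kids = [roots.pop(i) for i in picks]
        u = next_id
        next_id += 1
        children[u] = sorted(kids)
        parent[u] = -1
        for c in kids:
            parent[c] = u
        roots.append(u)
    time = {}
    stack = [(roots[0], 8.0)]
    while stack:
        u, t = stack.pop()
        time[u] = t
        for c in children[u]:
            stack.append((c, t - float(rng.choice(POW2_LENGTHS))))
    nodes = sorted(time, key=lambda u: (time[u], u))
    return LocalTree(0.0, 1.0, parent, children, time, nodes, roots,
                     samples=set(range(n_leaves)))


def random_connected_grid(rng, n_cells):
    """Random connected unit-cost grid: a spanning tree plus extra edges."""
    order = rng.permutation(n_cells)
    edges = set()
    for i in range(1, n_cells):
        a = int(order[i])
        b = int(order[rng.integers(0, i)])
        edges.add((min(a, b), max(a, b)))
    n_extra = int(rng.integers(0, n_cells))
    for _ in range(n_extra):
        a, b = rng.integers(0, n_cells, size=2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    centers = rng.uniform(0, 10, size=(n_cells, 2))
    grid = GeoGrid(centers, sorted(edges))
    return grid, cost_matrix_from_adjacency(grid)


def msprime_tree_sequence(seed, n=6, sequence_length=1000,
                          recombination_rate=2e-3, min_trees=2):
    """A small multi-tree coalescent simulation."""
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, sequence_length=sequence_length,
        recombination_rate=recombination_rate, population_size=1.0,
        random_seed=seed)
    assert ts.num_trees >= min_trees
    return ts


def georeferenced(ts, rng, mode="continuous", n_cells=None):
    """Wrap a tskit tree sequence with random sample locations."""
    if mode == "continuous":
        locs = {int(s): tuple(rng.uniform(0, 3, size=2)) for s in ts.samples()}
    else:
        locs = {int(s): int(rng.integers(0, n_cells)) for s in ts.samples()}
    return TreeSeq(ts, locs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


def build_ts(times, sample_flags, edge_rows, sequence_length, locations):
    """Hand-build a TreeSeq from node times, flags, and edge tuples."""
    import tskit

    tc = tskit.TableCollection(sequence_length=float(sequence_length))
    for t, s in zip(times, sample_flags):
        tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE if s else 0, time=float(t))
    for left, right, parent, child in edge_rows:
        tc.edges.add_row(float(left), float(right), int(parent), int(child))
    tc.sort()
    return TreeSeq(tc.tree_sequence(), dict(locations))
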