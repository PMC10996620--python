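"""Generalized-parsimony migration-cost fits on a single local tree.

For node ``u`` in a local tree, the minimum migration cost function
``f_u(x)`` is the smallest achievable sum of per-branch migration costs over
the whole tree when ``u`` is held at location ``x`` and every sampled leaf is
held at its observed location.  The fit runs in two sweeps:

* an *inside* (postorder) pass: ``inside_u`` is the optimal cost of the
  subtree below ``u`` as a function of u's location, computed by min-plus
  convolving each child's inside function through its branch kernel and
  summing over children;
* an *outside* (preorder) pass: ``outside_u`` folds the rest of the tree in
  across u's parent branch, using prefix/suffix sums of sibling
  contributions so no subtraction of cost functions is ever needed.

``f_u = inside_u + outside_u`` then carries whole-tree semantics at every
node, not just at the roots.  Branch weights are either 1 or the inverse
branch length (lengths floored at ``eps`` to keep weights finite).

Three cost models are supported: an arbitrary transition-cost matrix over
grid cells (Sankoff), squared Euclidean distance (convex quadratics), and
Manhattan distance (convex piecewise-linear functions); see
:mod:`geoanc.costfuncs` for the function families and kernel operations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .costfuncs import (DiscreteCost, PWL1D, PointCost, Quadratic1D,
                        SeparableCost, discrete_pin)
from .errors import DataError, DisconnectedGridError, ParameterError, SizeError
from .geography import CostMatrix

__all__ = ["CostModel", "make_model", "fit_tree", "minimize", "brute_force_fit"]

DEFAULT_EPS = 1e-8


# ---------------------------------------------------------------------------
# Cost-model strategies


class CostModel:
    """Kernel operations of one migration cost model."""

    def pin(self, state):
        raise NotImplementedError

    def zero(self):
        raise NotImplementedError

    def convolve_up(self, f, w):
        """Min-plus convolution through a branch, child function -> parent."""
        raise NotImplementedError

    def convolve_down(self, f, w):
        """Min-plus convolution in the parent -> child direction."""
        raise NotImplementedError

    def branch_cost(self, parent_state, child_state, w):
        raise NotImplementedError


class DiscreteModel(CostModel):
    def __init__(self, cost_matrix):
        if isinstance(cost_matrix, CostMatrix):
            self.metric_closed = cost_matrix.metric_closed
            cost_matrix = cost_matrix.values
        else:
            self.metric_closed = True
        C = np.asarray(cost_matrix, dtype=float)
        if np.isinf(C).any():
            raise DisconnectedGridError(
                "cost matrix has infinite entries (disconnected grid)")
        if np.any(np.diag(C) != 0) or np.any(C < 0):
            raise ParameterError(
                "cost matrix must be nonnegative with zero diagonal")
        self.C = C
        self.n_states = C.shape[0]

    def pin(self, state):
        return discrete_pin(int(state), self.n_states)

    def zero(self):
        return DiscreteCost(np.zeros(self.n_states))

    def convolve_up(self, f, w):
        # parent at x: min over child position y of w*C[x, y] + f(y)
        return f.convolve(self.C, w, transpose=False)

    def convolve_down(self, f, w):
        return f.convolve(self.C, w, transpose=True)

    def branch_cost(self, parent_state, child_state, w):
        return w * self.C[int(parent_state), int(child_state)]


class _ContinuousModel(CostModel):
    def pin(self, state):
        x, y = state
        return PointCost(float(x), float(y))

    def convolve_up(self, f, w):
        if isinstance(f, PointCost):
            return self.kernel_to_point(f, w)
        return f.convolve(w)

    convolve_down = convolve_up  # symmetric distance kernels


class QuadraticModel(_ContinuousModel):
    def zero(self):
        return SeparableCost(Quadratic1D(0.0, 0.0, 0.0), Quadratic1D(0.0, 0.0, 0.0))

    def kernel_to_point(self, p, w):
        return SeparableCost(Quadratic1D(w, p.x, 0.0), Quadratic1D(w, p.y, 0.0))

    def branch_cost(self, ps, cs, w):
        return w * ((ps[0] - cs[0]) ** 2 + (ps[1] - cs[1]) ** 2)


class ManhattanModel(_ContinuousModel):
    def zero(self):
        return SeparableCost(PWL1D.constant(0.0), PWL1D.constant(0.0))

    def kernel_to_point(self, p, w):
        return SeparableCost(PWL1D.abs_kernel(w, p.x), PWL1D.abs_kernel(w, p.y))

    def branch_cost(self, ps, cs, w):
        return w * (abs(ps[0] - cs[0]) + abs(ps[1] - cs[1]))


def make_model(cost_model) -> CostModel:
    """Resolve a user-facing cost-model argument to a strategy object."""
    if isinstance(cost_model, CostModel):
        return cost_model
    if isinstance(cost_model, str):
        if cost_model == "quadratic":
            return QuadraticModel()
        if cost_model == "manhattan":
            return ManhattanModel()
        raise ParameterError(f"unknown cost model {cost_model!r}")
    return DiscreteModel(cost_model)


def branch_weight(parent_time, child_time, weighting, eps=DEFAULT_EPS):
    if weighting == "none":
        return 1.0
    if weighting == "inverse_branch_length" or weighting == "inverse":
        return 1.0 / max(parent_time - child_time, eps)
    raise ParameterError(f"unknown weighting {weighting!r}")


# ---------------------------------------------------------------------------
# Inside / outside passes


def _inside_pass(tree, sample_states, model, weighting, eps):
    """Postorder subtree costs plus per-child branch contributions."""
    inside, contrib = {}, {}
    for u in tree.nodes:  # ascending time: children before parents
        kids = tree.children[u]
        if not kids:
            if u in tree.samples:
                if u not in sample_states:
                    raise DataError(f"sample node {u} has no location")
                inside[u] = model.pin(sample_states[u])
            else:
                inside[u] = model.zero()  # childless non-sample: no information
        else:
            acc = None
            for c in kids:
                w = branch_weight(tree.time[u], tree.time[c], weighting, eps)
                contrib[c] = model.convolve_up(inside[c], w)
                acc = contrib[c] if acc is None else acc.add(contrib[c])
            inside[u] = acc
    return inside, contrib


def _outside_pass(tree, inside, contrib, model, weighting, eps):
    """Preorder: fold in everything outside each node's subtree."""
    outside = {}
    for u in reversed(tree.nodes):  # descending time: parents before children
        if tree.parent[u] == -1:
            outside[u] = model.zero()
        kids = tree.children[u]
        if not kids:
            continue
        n = len(kids)
        # prefix[i] = sum of contributions of kids[:i]; suffix likewise
        prefix = [None] * (n + 1)
        suffix = [None] * (n + 1)
        for i, c in enumerate(kids):
            prefix[i + 1] = contrib[c] if prefix[i] is None else prefix[i].add(contrib[c])
        for i in range(n - 1, -1, -1):
            c = kids[i]
            suffix[i] = contrib[c] if suffix[i + 1] is None else suffix[i + 1].add(contrib[c])
        for i, c in enumerate(kids):
            rest = outside[u]
            if prefix[i] is not None:
                rest = rest.add(prefix[i])
            if suffix[i + 1] is not None:
                rest = rest.add(suffix[i + 1])
            w = branch_weight(tree.time[u], tree.time[c], weighting, eps)
            outside[c] = model.convolve_down(rest, w)
    return outside


def fit_tree(tree, sample_states, cost_model, weighting="none",
             eps=DEFAULT_EPS):
    """Fit the minimum migration cost function of every node in one tree.

    Returns a dict mapping node id to its cost function.  Sampled nodes get
    the degenerate function that is zero at their own location.
    """
    model = make_model(cost_model)
    inside, contrib = _inside_pass(tree, sample_states, model, weighting, eps)
    outside = _outside_pass(tree, inside, contrib, model, weighting, eps)
    f = {}
    for u in tree.nodes:
        if u in tree.samples:
            f[u] = model.pin(sample_states[u])
        else:
            f[u] = inside[u].add(outside[u])
    return f


def minimize(f):
    """Minimum value and minimizer set/point/box of a cost function."""
    return f.minimize()


# ---------------------------------------------------------------------------
# Brute-force oracles


def _tree_edges(tree):
    return [(tree.parent[u], u) for u in tree.nodes if tree.parent[u] != -1]


def brute_force_fit(tree, sample_states, cost_model, weighting="none",
                    eps=DEFAULT_EPS, grid=None, max_assignments=20_000_000):
    """Exhaustive-enumeration oracle for :func:`fit_tree`.

    Discrete mode enumerates every assignment of cells to free (non-sample)
    nodes and minimizes directly; the returned functions are exact.
    Continuous modes require a 1-D candidate ``grid`` of coordinates and
    enumerate per axis (both continuous cost models separate by axis),
    returning per-node ``(values_x, values_y)`` arrays over the grid.
    """
    model = make_model(cost_model)
    free = [u for u in tree.nodes if u not in tree.samples]
    edges = _tree_edges(tree)
    weights = {(p, c): branch_weight(tree.time[p], tree.time[c], weighting, eps)
               for p, c in edges}

    if isinstance(model, DiscreteModel):
        G = model.n_states
        if G ** max(len(free), 1) > max_assignments:
            raise SizeError("discrete enumeration too large")
        idx = {u: i for i, u in enumerate(free)}
        assign = np.stack([g.ravel() for g in
                           np.meshgrid(*([np.arange(G)] * len(free)),
                                       indexing="ij")]) if free else \
            np.empty((0, 1), dtype=int)
        total = np.zeros(assign.shape[1])
        for p, c in edges:
            sp = assign[idx[p]] if p in idx else np.full(
                assign.shape[1], int(sample_states[p]))
            sc = assign[idx[c]] if c in idx else np.full(
                assign.shape[1], int(sample_states[c]))
            total += weights[(p, c)] * model.C[sp, sc]
        out = {}
        for u in tree.nodes:
            if u in tree.samples:
                out[u] = discrete_pin(int(sample_states[u]), G)
            else:
                vals = np.full(G, np.inf)
                np.minimum.at(vals, assign[idx[u]], total)
                out[u] = DiscreteCost(vals)
        return out

    # continuous: per-axis enumeration over the candidate grid
    if grid is None:
        raise ParameterError("continuous brute force needs a candidate grid")
    grid = np.asarray(grid, dtype=float)
    K = grid.size
    if K ** max(len(free), 1) > max_assignments:
        raise SizeError("continuous enumeration too large")
    dist = ((lambda a, b: (a - b) ** 2) if isinstance(model, QuadraticModel)
            else (lambda a, b: np.abs(a - b)))
    out = {u: [] for u in tree.nodes}
    for axis in (0, 1):
        coords = {u: float(sample_states[u][axis]) for u in tree.samples}
        idx = {u: i for i, u in enumerate(free)}
        assign = np.stack([g.ravel() for g in
                           np.meshgrid(*([np.arange(K)] * len(free)),
                                       indexing="ij")]) if free else \
            np.empty((0, 1), dtype=int)
        total = np.zeros(assign.shape[1])
        for p, c in edges:
            vp = grid[assign[idx[p]]] if p in idx else coords[p]
            vc = grid[assign[idx[c]]] if c in idx else coords[c]
            total += weights[(p, c)] * dist(vp, vc)
        for u in tree.nodes:
            if u in tree.samples:
                out[u].append(None)
            else:
                vals = np.full(K, np.inf)
                np.minimum.at(vals, assign[idx[u]], total)
                out[u].append(vals)
    return {u: tuple(v) for u, v in out.items()}
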