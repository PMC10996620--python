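"""Desk-scale spatial forward simulation with tree-sequence recording.

The individual-based model: semelparous, hermaphroditic diploids live on a
two-dimensional square arena with reflecting boundaries.  Each generation,
an individual produces a Poisson number of offspring with mean
``R / (1 + N_t (R - 1) / K)``, where ``N_t`` is the local density within a
circle of radius ``3 sigma``, ``R`` the low-density growth rate, and ``K``
the carrying-capacity density; it mates with an individual chosen uniformly
at random within radius ``3 sigma`` (selfing only when it has no
neighbour).  Offspring are displaced from the mother by a Gaussian or
double-exponential (Laplace) kernel with per-axis standard deviation
``sigma`` and survive with probability ``min(1, K / O_t)``, ``O_t`` being
the local offspring density.  Genomes recombine at a fixed per-bp rate and
the full genealogy is recorded in tskit tables, simplified at the end to
the extant individuals.

Two companions support testing at scale: a fast random-walk location
fixture that paints locations down the edges of an existing dated tree
sequence, and the oracle effective migration rate — the maximum-likelihood
dispersal ``sigma`` computed from the true locations of all ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tskit
from scipy.spatial import cKDTree

from .errors import DataError, GeoancError, ParameterError
from .trees import TreeSeq

__all__ = ["SimParams", "TruthSet", "ExtinctionError", "simulate_population",
           "walk_locations_on_tree_sequence", "oracle_sigma"]


class ExtinctionError(GeoancError):
    def __init__(self, generation: int):
        super().__init__(f"population went extinct in generation {generation}")
        self.generation = generation


@dataclass
class SimParams:
    """Parameters of the spatial forward model.

    ``K`` defaults to ``30 / (pi (3 sigma)^2)`` so the expected number of
    individuals inside an interaction circle is 30, matching the founder
    population size.
    """

    sigma: float = 1.0
    kernel: str = "gaussian"            # or "double_exponential"
    R: float = 2.0
    K: float | None = None
    side: float | None = None           # default 20 sigma
    n_generations: int = 300
    sequence_length: float = 1e6
    recombination_rate: float = 1e-8
    n_founders: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.side is None:
            self.side = 20.0 * self.sigma
        if self.sigma <= 0 or self.R <= 1 or self.side <= 0:
            raise ParameterError("need sigma > 0, R > 1, side > 0")
        if self.kernel not in ("gaussian", "double_exponential"):
            raise ParameterError(f"unknown kernel {self.kernel!r}")
        if self.K is None:
            self.K = 30.0 / (np.pi * (3.0 * self.sigma) ** 2)
        if self.K <= 0:
            raise ParameterError("K must be positive")


@dataclass
class TruthSet:
    """A simulated tree sequence with the true location of every node."""

    tsw: TreeSeq
    locations: dict                    # node id -> (x, y), all nodes
    params: object = None
    pop_sizes: list | None = None      # adult census per generation

    def __post_init__(self) -> None:
        for u in range(self.tsw.ts.num_nodes):
            if u not in self.locations:
                raise DataError(f"node {u} has no true location")


def _dispersal(rng, kernel, sigma, n):
    """Per-axis displacement draws with standard deviation sigma."""
    if kernel == "gaussian":
        return rng.normal(0.0, sigma, size=(n, 2))
    # Laplace with per-axis variance sigma^2 has scale sigma / sqrt(2)
    return rng.laplace(0.0, sigma / np.sqrt(2.0), size=(n, 2))


def _reflect(pos: np.ndarray, side: float) -> np.ndarray:
    pos = np.array(pos, dtype=float)
    for _ in range(100):
        out_low, out_high = pos < 0.0, pos > side
        if not (out_low.any() or out_high.any()):
            return pos
        pos[out_low] = -pos[out_low]
        pos[out_high] = 2.0 * side - pos[out_high]
    raise RuntimeError("reflection failed to converge")


def _gamete_edges(rng, rate, L, child, g0, g1, edges):
    """Append edges for one recombinant gamete transmitted to ``child``."""
    k = rng.poisson(rate * L)
    start = int(rng.integers(2))
    genomes = (g0, g1)
    if k == 0:
        edges.append((0.0, L, genomes[start], child))
        return
    breaks = np.sort(rng.uniform(0.0, L, size=k))
    bounds = np.concatenate([[0.0], breaks, [L]])
    for i in range(bounds.size - 1):
        left, right = bounds[i], bounds[i + 1]
        if right > left:
            edges.append((left, right, genomes[(start + i) % 2], child))


def simulate_population(params: SimParams) -> TruthSet:
    """Run the forward model and return the simplified genealogy with truth.

    Raises :class:`ExtinctionError` if the population dies out.
    """
    rng = np.random.default_rng(params.seed)
    sigma, R, K, side = params.sigma, params.R, params.K, params.side
    radius = 3.0 * sigma
    circle = np.pi * radius ** 2
    L = float(params.sequence_length)

    node_birth, node_loc, edges = [], [], []

    def new_individual(pos, gen):
        i0 = len(node_birth)
        node_birth.extend([gen, gen])
        node_loc.extend([pos, pos])
        return i0, i0 + 1

    X = rng.uniform(0.0, side, size=(params.n_founders, 2))
    genomes = np.array([new_individual(X[i], 0)
                        for i in range(params.n_founders)])
    pop_sizes = [params.n_founders]

    for gen in range(1, params.n_generations + 1):
        n = X.shape[0]
        tree = cKDTree(X)
        dens = tree.query_ball_point(X, radius, return_length=True) / circle
        lam = R / (1.0 + dens * (R - 1.0) / K)
        noff = rng.poisson(lam)
        total = int(noff.sum())
        if total == 0:
            raise ExtinctionError(gen)
        neighbor_lists = tree.query_ball_point(X, radius)
        mates = np.empty(n, dtype=int)
        for i in range(n):
            others = [j for j in neighbor_lists[i] if j != i]
            mates[i] = rng.choice(others) if others else i  # selfing fallback
        mothers = np.repeat(np.arange(n), noff)
        fathers = mates[mothers]
        Y = _reflect(X[mothers] + _dispersal(rng, params.kernel, sigma,
                                             total), side)
        otree = cKDTree(Y)
        odens = otree.query_ball_point(Y, radius, return_length=True) / circle
        surv = rng.random(total) < np.minimum(1.0, K / odens)
        if not surv.any():
            raise ExtinctionError(gen)
        new_genomes = []
        for off in np.flatnonzero(surv):
            m, f = mothers[off], fathers[off]
            c0, c1 = new_individual(Y[off], gen)
            _gamete_edges(rng, params.recombination_rate, L, c0,
                          genomes[m, 0], genomes[m, 1], edges)
            _gamete_edges(rng, params.recombination_rate, L, c1,
                          genomes[f, 0], genomes[f, 1], edges)
            new_genomes.append((c0, c1))
        X = Y[surv]
        genomes = np.array(new_genomes)
        pop_sizes.append(X.shape[0])

    # assemble tables: tskit time runs in generations before present
    T = params.n_generations
    tc = tskit.TableCollection(sequence_length=L)
    final_nodes = set(genomes.ravel().tolist())
    for u in range(len(node_birth)):
        flags = tskit.NODE_IS_SAMPLE if u in final_nodes else 0
        tc.nodes.add_row(flags=flags, time=float(T - node_birth[u]))
    for left, right, parent, child in edges:
        tc.edges.add_row(left=left, right=right, parent=parent, child=child)
    tc.sort()
    ts, node_map = tc.tree_sequence().simplify(
        sorted(final_nodes), map_nodes=True)
    locations = {}
    for old in range(len(node_birth)):
        new = int(node_map[old])
        if new != tskit.NULL:
            locations[new] = (float(node_loc[old][0]), float(node_loc[old][1]))
    sample_locs = {int(s): locations[int(s)] for s in ts.samples()}
    return TruthSet(TreeSeq(ts, sample_locs), locations, params, pop_sizes)


def walk_locations_on_tree_sequence(ts, sigma: float, kernel: str = "gaussian",
                                    seed=None, origin=(0.0, 0.0)) -> TruthSet:
    """Paint locations down a dated tree sequence by a random walk.

    Each non-root node is displaced from its parent (the parent edge with
    the largest genomic span, ties to the lowest parent id) with per-axis
    variance ``sigma^2 * branch_length``.  A fast fixture for testing
    estimators on tree sequences from any source.
    """
    if isinstance(ts, TreeSeq):
        ts = ts.ts
    if kernel not in ("gaussian", "double_exponential"):
        raise ParameterError(f"unknown kernel {kernel!r}")
    times = ts.nodes_time
    if np.any(~np.isfinite(times)):
        raise DataError("all nodes must be dated")
    rng = np.random.default_rng(seed)
    span_of: dict = {}
    for e in ts.edges():
        key = (int(e.child), int(e.parent))
        span_of[key] = span_of.get(key, 0.0) + (e.right - e.left)
    best_parent: dict = {}
    for (c, p), sp in sorted(span_of.items()):
        cur = best_parent.get(c)
        if cur is None or sp > cur[1]:
            best_parent[c] = (p, sp)
    locations = {}
    for u in np.argsort(-times, kind="stable"):
        u = int(u)
        if u not in best_parent:
            locations[u] = (float(origin[0]), float(origin[1]))
            continue
        p, _sp = best_parent[u]
        t = float(times[p] - times[u])
        px, py = locations[p]
        if sigma == 0.0 or t == 0.0:
            dx = dy = 0.0
        elif kernel == "gaussian":
            dx, dy = rng.normal(0.0, sigma * np.sqrt(t), size=2)
        else:
            dx, dy = rng.laplace(0.0, sigma * np.sqrt(t / 2.0), size=2)
        locations[u] = (px + dx, py + dy)
    sample_locs = {int(s): locations[int(s)] for s in ts.samples()}
    return TruthSet(TreeSeq(ts, sample_locs), locations)


def oracle_sigma(truth: TruthSet, kernel: str = "gaussian") -> float:
    """Maximum-likelihood dispersal sigma from the true ancestor locations.

    Treats each distinct parent-child link as an independent displacement
    with per-axis variance ``sigma^2 * t`` (``t`` the branch length).
    Gaussian: ``sigma^2 = mean(dx^2 / t)`` over links and axes.  Laplace:
    the per-axis scale is ``sigma sqrt(t/2)``, whose ML estimate gives
    ``sigma = sqrt(2) * mean(|dx| / sqrt(t))``.  Zero-length links are
    excluded (their count is reported at debug level by callers).
    """
    if kernel not in ("gaussian", "double_exponential"):
        raise ParameterError(f"unknown kernel {kernel!r}")
    ts = truth.tsw.ts
    times = ts.nodes_time
    pairs = {(int(e.child), int(e.parent)) for e in ts.edges()}
    disp, lens = [], []
    n_zero = 0
    for c, p in sorted(pairs):
        t = float(times[p] - times[c])
        if t <= 0:
            n_zero += 1
            continue
        cx, cy = truth.locations[c]
        px, py = truth.locations[p]
        disp.append((px - cx, py - cy))
        lens.append(t)
    if not disp:
        return 0.0
    d = np.asarray(disp)
    t = np.asarray(lens)[:, None]
    if kernel == "gaussian":
        return float(np.sqrt(np.mean(d ** 2 / t)))
    return float(np.sqrt(2.0) * np.mean(np.abs(d) / np.sqrt(t)))
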