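"""Minimum-cost migration histories along edges, and time interpolation.

Ancestor locations are estimated at node times only; the spatiotemporal
ancestry statistics need lineage locations at arbitrary times.  Conditional
on the two endpoint cells of an edge, a minimum-cost migration history under
the unit-cost neighbour model is a shortest path on the grid graph between
the endpoint cells, traversed at times drawn inside the branch interval.
This module samples such histories uniformly over all shortest paths (via
shortest-path-DAG predecessor counts) with event times distributed as the
order statistics of independent uniforms, and interpolates the resulting
piecewise-constant location path.

Time runs in generations before present: an edge's child end is the younger
endpoint.  Events are stored in increasing time order; event ``(tau, j, k)``
means that *in forward time* the ancestral lineage moved from cell ``j`` to
cell ``k`` at time ``tau`` — i.e. the lineage occupies ``j`` at times at or
above ``tau`` and ``k`` just below ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DisconnectedGridError, ParameterError
from .geography import GeoGrid, cost_matrix_from_adjacency

__all__ = ["MigrationHistory", "HistorySampler", "location_at",
           "sample_histories_for_ts", "histories_to_frame"]


@dataclass
class MigrationHistory:
    """A time-stamped piecewise-constant location path along one edge.

    ``path`` lists the visited cells from the child end to the parent end;
    ``times`` are the strictly increasing event times, one per step, so
    ``len(path) == len(times) + 1``.
    """

    edge_id: int
    child_time: float
    parent_time: float
    path: np.ndarray          # cells, child end first
    times: np.ndarray         # event times, strictly inside the interval

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.path.size != self.times.size + 1:
            raise ParameterError("need one more path cell than event times")

    @property
    def child_state(self) -> int:
        return int(self.path[0])

    @property
    def parent_state(self) -> int:
        return int(self.path[-1])

    @property
    def num_events(self) -> int:
        return int(self.times.size)

    def forward_moves(self):
        """Yield (time, source, dest) per event, in forward-time orientation.

        The lineage occupies ``path[i]`` on ``[times[i-1], times[i])``; the
        event at ``times[i]`` is a forward-time move from ``path[i]``
        (occupied at older times) to ``path[i-1]`` (occupied younger).
        """
        for i in range(self.times.size):
            yield float(self.times[i]), int(self.path[i + 1]), int(self.path[i])


def location_at(history: MigrationHistory, t: float) -> int:
    """Cell occupied by the lineage at time ``t`` (generations ago)."""
    if not (history.child_time <= t < history.parent_time):
        raise ParameterError(
            f"time {t} outside branch interval "
            f"[{history.child_time}, {history.parent_time})")
    idx = int(np.searchsorted(history.times, t, side="right"))
    return int(history.path[idx])


class HistorySampler:
    """Uniform sampling over minimum-cost (shortest) grid paths."""

    def __init__(self, grid: GeoGrid, seed=None):
        self.grid = grid
        self.neighbors = grid.neighbors()
        self.hops = cost_matrix_from_adjacency(grid, 1.0).values
        self._path_counts: dict[int, np.ndarray] = {}
        self.rng = np.random.default_rng(seed)

    def _counts_to(self, target: int) -> np.ndarray:
        """Number of shortest paths from each cell to ``target``."""
        if target in self._path_counts:
            return self._path_counts[target]
        d = self.hops[:, target]
        N = np.zeros(self.grid.num_cells)
        N[target] = 1.0
        for u in np.argsort(d):
            if u == target or not np.isfinite(d[u]):
                continue
            N[u] = sum(N[v] for v in self.neighbors[u] if d[v] == d[u] - 1)
        self._path_counts[target] = N
        return N

    def sample_path(self, source: int, target: int, rng=None) -> np.ndarray:
        """One shortest path, uniform over all shortest paths."""
        rng = rng or self.rng
        if not np.isfinite(self.hops[source, target]):
            raise DisconnectedGridError(
                f"cells {source} and {target} are not connected")
        N = self._counts_to(target)
        d = self.hops[:, target]
        path = [int(source)]
        u = int(source)
        while u != target:
            nxt = [v for v in self.neighbors[u] if d[v] == d[u] - 1]
            p = np.array([N[v] for v in nxt])
            u = int(rng.choice(nxt, p=p / p.sum()))
            path.append(u)
        return np.array(path, dtype=int)

    def sample_history(self, edge_id: int, child_time: float,
                       parent_time: float, child_state: int,
                       parent_state: int, rng=None) -> MigrationHistory:
        """History along one edge conditioned on its endpoint cells.

        The number of events always equals the geodesic distance between the
        endpoints; identical endpoints give an empty event list.
        """
        rng = rng or self.rng
        path = self.sample_path(int(child_state), int(parent_state), rng)
        d = path.size - 1
        times = np.sort(rng.uniform(child_time, parent_time, size=d))
        return MigrationHistory(edge_id, child_time, parent_time, path, times)


def sample_histories_for_ts(tsw, node_cells, sampler: HistorySampler,
                            rng=None) -> dict:
    """Sample one history per edge of the tree sequence.

    ``node_cells`` maps every node id to its located grid cell (samples at
    their assigned cells).  Returns ``{edge_id: MigrationHistory}``.
    """
    ts = tsw.ts
    times = ts.nodes_time
    histories = {}
    for e in range(ts.num_edges):
        edge = ts.edge(e)
        histories[e] = sampler.sample_history(
            e, float(times[edge.child]), float(times[edge.parent]),
            int(node_cells[edge.child]), int(node_cells[edge.parent]), rng)
    return histories


def histories_to_frame(histories: dict, replicate: int = 0):
    """Tidy dump of sampled histories: one row per migration event."""
    import pandas as pd

    rows = []
    for edge_id, h in sorted(histories.items()):
        for tau, src, dst in h.forward_moves():
            rows.append({"edge_id": edge_id, "event_time": tau,
                         "from_cell": src, "to_cell": dst,
                         "replicate": replicate})
    return pd.DataFrame(rows, columns=["edge_id", "event_time", "from_cell",
                                       "to_cell", "replicate"])
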