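"""Discrete geographic state spaces: grids, transition costs, assignment.

The discrete cost model works on an arbitrary set of geographic cells with a
matrix of pairwise transition costs.  The standard construction prices each
migration event between neighbouring cells at a unit cost; since a single
branch can carry any number of events, the effective branch transition cost
between two cells is the *geodesic* (minimum-hop) distance on the adjacency
graph times the unit cost, and that metric closure is what
:func:`cost_matrix_from_adjacency` returns.

Planar square/hex grid builders are provided for test- and desk-scale work;
externally built grids (e.g. equal-area global grids intersected with a
landmass) are consumed from their cell/adjacency tables as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .errors import ParameterError

__all__ = [
    "GeoGrid",
    "CostMatrix",
    "build_planar_grid",
    "cost_matrix_from_adjacency",
    "assign_samples_to_cells",
    "load_grid",
    "write_grid",
]


@dataclass
class GeoGrid:
    """Cells 0..G-1 with planar center coordinates and symmetric adjacency."""

    centers: np.ndarray            # (G, 2)
    adjacency: list                # list of (a, b) pairs with a < b

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if not np.all(np.isfinite(self.centers)):
            raise ParameterError("grid centers must be finite")
        pairs = set()
        for a, b in self.adjacency:
            a, b = int(a), int(b)
            if a == b:
                raise ParameterError("adjacency must be irreflexive")
            pairs.add((min(a, b), max(a, b)))
        self.adjacency = sorted(pairs)

    @property
    def num_cells(self) -> int:
        return self.centers.shape[0]

    def neighbors(self) -> list:
        nbr = [[] for _ in range(self.num_cells)]
        for a, b in self.adjacency:
            nbr[a].append(b)
            nbr[b].append(a)
        return [sorted(v) for v in nbr]


@dataclass
class CostMatrix:
    """G x G nonnegative transition costs with a zero diagonal."""

    values: np.ndarray
    disconnected: bool = False
    metric_closed: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diag(self.values) != 0):
            raise ParameterError("cost matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ParameterError("cost matrix entries must be nonnegative")


def build_planar_grid(extent, spacing: float, lattice: str = "square") -> GeoGrid:
    """Tile a rectangle ``(xmin, ymin, xmax, ymax)`` with a regular lattice.

    Square lattices use the 4-neighbourhood, hex lattices (offset rows) the
    6-neighbourhood.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    width, height = xmax - xmin, ymax - ymin
    if width <= 0 or height <= 0:
        raise ParameterError("extent is degenerate")
    if lattice == "square":
        nx, ny = int(width // spacing), int(height // spacing)
        if nx < 1 or ny < 1:
            raise ParameterError("extent smaller than one cell")
        centers, adjacency, idx = [], [], {}
        for r in range(ny):
            for c in range(nx):
                idx[(r, c)] = len(centers)
                centers.append((xmin + (c + 0.5) * spacing,
                                ymin + (r + 0.5) * spacing))
        for (r, c), i in idx.items():
            for dr, dc in ((0, 1), (1, 0)):
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    adjacency.append((i, j))
        return GeoGrid(np.array(centers), adjacency)
    if lattice == "hex":
        row_h = spacing * np.sqrt(3.0) / 2.0
        nx, ny = int(width // spacing), int(height // row_h)
        if nx < 1 or ny < 1:
            raise ParameterError("extent smaller than one cell")
        centers, adjacency, idx = [], [], {}
        for r in range(ny):
            for c in range(nx):
                idx[(r, c)] = len(centers)
                centers.append((xmin + (c + 0.5 + 0.5 * (r % 2)) * spacing,
                                ymin + (r + 0.5) * row_h))
        for (r, c), i in idx.items():
            if r % 2 == 0:
                ups = ((1, -1), (1, 0))
            else:
                ups = ((1, 0), (1, 1))
            for dr, dc in ((0, 1),) + ups:
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    adjacency.append((i, j))
        return GeoGrid(np.array(centers), adjacency)
    raise ParameterError(f"unknown lattice {lattice!r}")


def cost_matrix_from_adjacency(grid: GeoGrid, unit_cost: float = 1.0) -> CostMatrix:
    """Metric-closed branch costs: unit_cost x minimum neighbour-step count."""
    G = grid.num_cells
    if not grid.adjacency:
        data = np.full((G, G), np.inf)
        np.fill_diagonal(data, 0.0)
        if G > 1:
            warnings.warn("grid has no adjacencies; all pairs unreachable")
        return CostMatrix(data, disconnected=G > 1)
    a = np.array([p[0] for p in grid.adjacency])
    b = np.array([p[1] for p in grid.adjacency])
    adj = csr_matrix((np.ones(a.size), (a, b)), shape=(G, G))
    hops = shortest_path(adj, method="D", directed=False, unweighted=True)
    disconnected = bool(np.isinf(hops).any())
    if disconnected:
        warnings.warn("grid is disconnected; unreachable pairs have infinite cost")
    return CostMatrix(hops * unit_cost, disconnected=disconnected)


def assign_samples_to_cells(locations, grid: GeoGrid) -> np.ndarray:
    """Map coordinates to the nearest cell center; ties go to the lowest id."""
    if grid.num_cells == 0:
        raise ParameterError("cannot assign samples to an empty grid")
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if not np.all(np.isfinite(locations)):
        raise ParameterError("sample coordinates must be finite")
    d = cdist(locations, grid.centers)
    return np.argmin(d, axis=1)  # argmin takes the first (lowest) id on ties


def load_grid(grid_path: str, adjacency_path: str) -> GeoGrid:
    """Read ``grid.tsv`` (cell_id, x, y) and ``adjacency.tsv`` (cell_a, cell_b)."""
    gdf = pd.read_csv(grid_path, sep="\t", comment="#").sort_values("cell_id")
    if not np.array_equal(gdf["cell_id"].to_numpy(), np.arange(len(gdf))):
        raise ParameterError("cell ids must be consecutive integers from 0")
    adf = pd.read_csv(adjacency_path, sep="\t", comment="#")
    adjacency = list(zip(adf["cell_a"].astype(int), adf["cell_b"].astype(int)))
    return GeoGrid(gdf[["x", "y"]].to_numpy(), adjacency)


def write_grid(grid: GeoGrid, grid_path: str, adjacency_path: str) -> None:
    pd.DataFrame({
        "cell_id": np.arange(grid.num_cells),
        "x": grid.centers[:, 0], "y": grid.centers[:, 1],
    }).to_csv(grid_path, sep="\t", index=False)
    pd.DataFrame(grid.adjacency, columns=["cell_a", "cell_b"]).to_csv(
        adjacency_path, sep="\t", index=False)
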