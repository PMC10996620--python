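"""Tree-sequence loading, validation, filtering, and local-tree iteration.

A tree sequence stores the genealogies of a set of sampled genomes as a
single set of nodes and edges; each genomic interval has its own local tree
assembled from the edges whose intervals cover it.  This module wraps
:mod:`tskit` for storage and iteration, attaches per-sample geographic
locations (continuous coordinates or discrete grid cells), and provides the
degree-based edge filter used to remove genealogical outlier nodes before
geographic inference.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tskit

from .errors import DataError, FormatError, ParameterError

NULL = tskit.NULL

__all__ = [
    "TreeSeq",
    "LocalTree",
    "load_tree_sequence",
    "write_tree_sequence",
    "iterate_local_trees",
    "filter_high_degree_edges",
    "simplify_to_samples",
]


@dataclass
class TreeSeq:
    """A tskit tree sequence plus per-sample geographic locations.

    ``locations`` maps each sample node id either to an ``(x, y)`` coordinate
    pair (continuous mode) or to an integer grid-cell id (discrete mode).
    """

    ts: tskit.TreeSequence
    locations: dict

    def __post_init__(self) -> None:
        samples = self.ts.samples()
        for s in samples:
            if int(s) not in self.locations:
                raise DataError(f"sample node {int(s)} has no location record")
        first = self.locations[int(samples[0])] if len(samples) else None
        self.mode = "discrete" if np.isscalar(first) else "continuous"

    @property
    def sequence_length(self) -> float:
        return self.ts.sequence_length

    @property
    def num_trees(self) -> int:
        return self.ts.num_trees

    def samples(self) -> np.ndarray:
        return self.ts.samples()

    def node_time(self, u: int) -> float:
        return self.ts.node(u).time

    def sample_states(self) -> dict:
        """Locations restricted to sample nodes, as the fit functions expect."""
        return {int(s): self.locations[int(s)] for s in self.ts.samples()}


@dataclass
class LocalTree:
    """One local genealogy, materialized for the parsimony dynamic programme.

    Only nodes that participate in at least one edge of this tree are
    *present*; ``nodes`` lists them in ascending time order (children always
    precede parents).
    """

    left: float
    right: float
    parent: dict
    children: dict
    time: dict
    nodes: list
    roots: list
    samples: set

    @property
    def span(self) -> float:
        return self.right - self.left

    def branch_length(self, u: int) -> float:
        p = self.parent.get(u, NULL)
        if p == NULL:
            return 0.0
        return self.time[p] - self.time[u]


def _local_tree_from_tskit(tree: tskit.Tree, sample_set: set) -> LocalTree:
    parent, children, time, nodes = {}, {}, {}, []
    for u in tree.nodes():
        p = tree.parent(u)
        kids = sorted(tree.children(u))
        if p == NULL and not kids:
            continue  # isolated node: not part of this local tree
        parent[u] = p
        children[u] = kids
        time[u] = tree.time(u)
        nodes.append(u)
    nodes.sort(key=lambda u: (time[u], u))
    roots = [u for u in nodes if parent[u] == NULL]
    left, right = tree.interval
    return LocalTree(left, right, parent, children, time, nodes, roots,
                     samples=set(nodes) & sample_set)


def iterate_local_trees(tsw: TreeSeq, with_diffs: bool = False):
    """Yield the local trees left to right; intervals partition the genome.

    With ``with_diffs`` each item is ``(tree, (edges_out, edges_in))`` giving
    the edges removed from and inserted into the previous tree.
    """
    sample_set = set(int(s) for s in tsw.ts.samples())
    if not with_diffs:
        for tree in tsw.ts.trees():
            yield _local_tree_from_tskit(tree, sample_set)
    else:
        diffs = tsw.ts.edge_diffs()
        for tree in tsw.ts.trees():
            _, edges_out, edges_in = next(diffs)
            yield (_local_tree_from_tskit(tree, sample_set),
                   (list(edges_out), list(edges_in)))


# ---------------------------------------------------------------------------
# I/O


def _tables_from_frames(nodes: pd.DataFrame, edges: pd.DataFrame,
                        sequence_length: float | None = None) -> tskit.TreeSequence:
    required_n = {"id", "time", "is_sample"}
    required_e = {"left", "right", "parent", "child"}
    if not required_n.issubset(nodes.columns):
        raise FormatError(f"nodes table needs columns {sorted(required_n)}")
    if not required_e.issubset(edges.columns):
        raise FormatError(f"edges table needs columns {sorted(required_e)}")
    nodes = nodes.sort_values("id")
    if not np.array_equal(nodes["id"].to_numpy(), np.arange(len(nodes))):
        raise FormatError("node ids must be consecutive integers from 0")
    if sequence_length is None:
        sequence_length = float(edges["right"].max()) if len(edges) else 1.0
    tc = tskit.TableCollection(sequence_length=sequence_length)
    for _, row in nodes.iterrows():
        flags = tskit.NODE_IS_SAMPLE if int(row["is_sample"]) else 0
        tc.nodes.add_row(flags=flags, time=float(row["time"]))
    for _, row in edges.iterrows():
        tc.edges.add_row(left=float(row["left"]), right=float(row["right"]),
                         parent=int(row["parent"]), child=int(row["child"]))
    try:
        tc.sort()
        return tc.tree_sequence()
    except (tskit.LibraryError, ValueError) as e:
        raise FormatError(f"invalid tree sequence tables: {e}") from e


def _locations_from_frame(df: pd.DataFrame) -> dict:
    if "cell_id" in df.columns:
        return {int(r["node_id"]): int(r["cell_id"]) for _, r in df.iterrows()}
    if {"x", "y"}.issubset(df.columns):
        return {int(r["node_id"]): (float(r["x"]), float(r["y"]))
                for _, r in df.iterrows()}
    raise FormatError("samples table needs columns node_id and x,y or cell_id")


def load_tree_sequence(path: str, locations=None) -> TreeSeq:
    """Load a ``.trees`` file or a directory of nodes/edges/samples TSVs.

    ``locations`` may be a DataFrame, a path to a samples TSV, or a dict; it
    is required when the input does not carry sample locations itself.
    """
    if os.path.isdir(path):
        nodes = pd.read_csv(os.path.join(path, "nodes.tsv"), sep="\t", comment="#")
        edges = pd.read_csv(os.path.join(path, "edges.tsv"), sep="\t", comment="#")
        ts = _tables_from_frames(nodes, edges)
        samples_path = os.path.join(path, "samples.tsv")
        if locations is None and os.path.exists(samples_path):
            locations = pd.read_csv(samples_path, sep="\t", comment="#")
    else:
        try:
            ts = tskit.load(path)
        except Exception as e:  # tskit raises various types on bad files
            raise FormatError(f"cannot read tree-sequence file {path}: {e}") from e
    if locations is None:
        # fall back on per-individual locations embedded in the file
        locations = {}
        for s in ts.samples():
            node = ts.node(s)
            if node.individual != NULL:
                loc = ts.individual(node.individual).location
                if len(loc) >= 2:
                    locations[int(s)] = (float(loc[0]), float(loc[1]))
    if isinstance(locations, str):
        locations = pd.read_csv(locations, sep="\t", comment="#")
    if isinstance(locations, pd.DataFrame):
        locations = _locations_from_frame(locations)
    return TreeSeq(ts, dict(locations))


def write_tree_sequence(tsw: TreeSeq, directory: str) -> None:
    """Write the plain-TSV dialect: nodes.tsv, edges.tsv, samples.tsv."""
    os.makedirs(directory, exist_ok=True)
    ts = tsw.ts
    nodes = pd.DataFrame({
        "id": np.arange(ts.num_nodes),
        "time": ts.nodes_time,
        "is_sample": (ts.nodes_flags & tskit.NODE_IS_SAMPLE).astype(bool).astype(int),
        "individual": ts.nodes_individual,
    })
    edges = pd.DataFrame({
        "left": ts.edges_left, "right": ts.edges_right,
        "parent": ts.edges_parent, "child": ts.edges_child,
    })
    nodes.to_csv(os.path.join(directory, "nodes.tsv"), sep="\t", index=False)
    edges.to_csv(os.path.join(directory, "edges.tsv"), sep="\t", index=False)
    recs = []
    for s in ts.samples():
        loc = tsw.locations[int(s)]
        if np.isscalar(loc):
            recs.append({"node_id": int(s), "cell_id": int(loc)})
        else:
            recs.append({"node_id": int(s), "x": loc[0], "y": loc[1]})
    pd.DataFrame(recs).to_csv(os.path.join(directory, "samples.tsv"),
                              sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering


def _nearest_rank_threshold(degrees: np.ndarray, upper_pct: float) -> float:
    """Outlier threshold over positive degrees.

    Nearest-rank (1 - upper_pct) quantile, floored strictly above the median
    positive degree so that near-uniform degree distributions (where the top
    quantile equals the typical degree) flag nothing; an outlier must both
    sit in the upper tail and exceed the typical degree.
    """
    d = np.sort(degrees[degrees >= 1])
    if d.size == 0:
        return math.inf
    rank = math.ceil((1.0 - upper_pct) * d.size)
    thr = float(d[max(rank, 1) - 1])
    median = float(np.median(d))
    if thr <= median:
        return math.nextafter(median, math.inf)
    return thr


def filter_high_degree_edges(tsw: TreeSeq, upper_pct: float) -> TreeSeq:
    """Drop edges touching non-sample nodes of outlying in- or out-degree.

    Out-degree of a node counts edges in which it is the parent, in-degree
    edges in which it is the child, each edge once.  A non-sample node is an
    outlier when its degree is at or above the nearest-rank
    ``(1 - upper_pct)`` quantile of the corresponding degree distribution
    over non-sample nodes with degree >= 1.  ``upper_pct = 0`` disables
    filtering entirely.
    """
    if not (0.0 <= upper_pct < 1.0):
        raise ParameterError("upper_pct must be in [0, 1)")
    ts = tsw.ts
    if upper_pct == 0.0 or ts.num_edges == 0:
        return TreeSeq(ts, dict(tsw.locations))
    is_sample = (ts.nodes_flags & tskit.NODE_IS_SAMPLE).astype(bool)
    out_deg = np.bincount(ts.edges_parent, minlength=ts.num_nodes).astype(float)
    in_deg = np.bincount(ts.edges_child, minlength=ts.num_nodes).astype(float)
    out_thr = _nearest_rank_threshold(out_deg[~is_sample], upper_pct)
    in_thr = _nearest_rank_threshold(in_deg[~is_sample], upper_pct)
    bad_parent = (~is_sample) & (out_deg >= out_thr)
    bad_child = (~is_sample) & (in_deg >= in_thr)
    keep = ~(bad_parent[ts.edges_parent] | bad_child[ts.edges_child])
    tc = ts.dump_tables()
    tc.edges.set_columns(
        left=ts.edges_left[keep], right=ts.edges_right[keep],
        parent=ts.edges_parent[keep], child=ts.edges_child[keep])
    tc.sort()
    return TreeSeq(tc.tree_sequence(), dict(tsw.locations))


def simplify_to_samples(tsw: TreeSeq, sample_ids) -> TreeSeq:
    """Restrict to a subset of samples, remapping locations to the new ids."""
    sample_ids = [int(s) for s in sample_ids]
    ts2, node_map = tsw.ts.simplify(sample_ids, map_nodes=True)
    locations = {}
    for old in sample_ids:
        new = int(node_map[old])
        if new != NULL:
            locations[new] = tsw.locations[old]
    return TreeSeq(ts2, locations)
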