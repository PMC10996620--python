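"""Spatiotemporal ancestry coefficients and ancestry flux.

For a subset ``i`` of the samples, ``z_ik(t)`` is the fraction of the
subset's genome that survives in the genealogy at time ``t`` in the past
and is carried by an ancestral lineage located in region ``k`` at that
time.  ``phi_ijk(t_l, t_r)`` (ancestry flux) is the fraction of the
subset's genome whose genealogical path overlaps the window ``[t_l, t_r)``
and passes through at least one ancestor that moved, in forward time, from
region ``j`` to region ``k`` during the window.

Sample material is accounted per (sample, genomic position): each sample's
path through each local tree contributes that tree's span once, so shared
ancestral segments count once per descending sampled path.  Genomic
positions whose local root is younger than ``t`` have no surviving
ancestral material at ``t`` and are excluded from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .history import MigrationHistory, location_at
from .trees import NULL, TreeSeq

__all__ = ["ancestry_coefficients", "ancestry_flux", "replicate_and_average",
           "average_replicates"]


def _sample_paths(tsw: TreeSeq, sample_ids):
    """Yield (span, sample, [(edge_id, child, parent, t_child, t_parent)...])

    per (local tree, sample): the chain of edges from the sample to its
    local root.
    """
    ts = tsw.ts
    times = ts.nodes_time
    for tree in ts.trees():
        span = tree.interval.right - tree.interval.left
        for s in sample_ids:
            chain = []
            u = s
            while True:
                p = tree.parent(u)
                if p == NULL:
                    break
                chain.append((tree.edge(u), u, p,
                              float(times[u]), float(times[p])))
                u = p
            yield span, s, chain


def ancestry_coefficients(tsw: TreeSeq, histories: dict, subsets: dict,
                          regions=None, times=None) -> pd.DataFrame:
    """Ancestry coefficients z_ik(t) on a grid of times.

    ``histories`` maps edge id to a :class:`MigrationHistory`; ``subsets``
    maps subset labels to lists of sample node ids; ``regions`` maps cells
    to region labels (identity when omitted).  Returns a tidy frame with
    columns subset, region, time, z, A; times where no ancestral material
    survives are emitted with ``A = 0`` and missing z.
    """
    if times is None:
        raise ParameterError("a time grid is required")
    times = np.asarray(times, dtype=float)
    region_of = (lambda c: c) if regions is None else (lambda c: regions[c])
    A = {lab: np.zeros(times.size) for lab in subsets}
    Ak: dict = {lab: {} for lab in subsets}
    for lab, sample_ids in subsets.items():
        for span, _s, chain in _sample_paths(tsw, sample_ids):
            for edge_id, _c, _p, t_lo, t_hi in chain:
                sel = np.flatnonzero((times >= t_lo) & (times < t_hi))
                if sel.size == 0:
                    continue
                if edge_id not in histories:
                    raise DataError(f"no migration history for edge {edge_id}")
                h = histories[edge_id]
                for j in sel:
                    k = region_of(location_at(h, times[j]))
                    A[lab][j] += span
                    Ak[lab].setdefault(k, np.zeros(times.size))[j] += span
    rows = []
    for lab in subsets:
        denom = A[lab]
        for k, num in sorted(Ak[lab].items(), key=lambda kv: str(kv[0])):
            for j, t in enumerate(times):
                if denom[j] > 0:
                    rows.append({"subset": lab, "region": k, "time": t,
                                 "z": num[j] / denom[j], "A": denom[j]})
        for j, t in enumerate(times):
            if denom[j] == 0:
                rows.append({"subset": lab, "region": None, "time": t,
                             "z": np.nan, "A": 0.0})
    out = pd.DataFrame(rows)
    _check_normalization(out)
    return out


def _check_normalization(z_table: pd.DataFrame) -> None:
    ok = z_table[z_table["A"] > 0]
    if len(ok) == 0:
        return
    sums = ok.groupby(["subset", "time"])["z"].sum()
    if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
        raise RuntimeError("ancestry coefficients do not sum to one")


def ancestry_flux(tsw: TreeSeq, histories: dict, subsets: dict,
                  regions=None, windows=None,
                  denominator: str = "overlap") -> pd.DataFrame:
    """Ancestry-flux coefficients phi_ijk over half-open time windows.

    A (sample, position) contributes to the denominator of a window when its
    genealogical path overlaps it (``denominator="overlap"``) or extends
    entirely through it (``"span_full"``); it contributes to the numerator
    of the ordered region pair (j, k) when its path carries at least one
    forward-time j -> k move inside the window — an indicator, regardless
    of how many such moves occur.
    """
    if windows is None:
        raise ParameterError("a list of [t_left, t_right) windows is required")
    windows = [(float(a), float(b)) for a, b in windows]
    for a, b in windows:
        if b <= a:
            raise ParameterError("windows must satisfy t_left < t_right")
    for (a1, b1), (a2, b2) in zip(sorted(windows), sorted(windows)[1:]):
        if a2 < b1:
            raise ParameterError("windows must not overlap")
    if denominator not in ("overlap", "span_full"):
        raise ParameterError("denominator must be 'overlap' or 'span_full'")
    region_of = (lambda c: c) if regions is None else (lambda c: regions[c])
    A = {lab: np.zeros(len(windows)) for lab in subsets}
    Ajk: dict = {lab: {} for lab in subsets}
    for lab, sample_ids in subsets.items():
        for span, _s, chain in _sample_paths(tsw, sample_ids):
            if not chain:
                continue
            root_time = max(c[4] for c in chain)
            base_time = min(c[3] for c in chain)
            for w_idx, (tl, tr) in enumerate(windows):
                if denominator == "overlap":
                    hit = base_time < tr and root_time > tl
                else:
                    hit = root_time >= tr and base_time <= tl
                if not hit:
                    continue
                A[lab][w_idx] += span
                pairs = set()
                for edge_id, _c, _p, t_lo, t_hi in chain:
                    if t_hi <= tl or t_lo >= tr:
                        continue
                    h = histories[edge_id]
                    for tau, src, dst in h.forward_moves():
                        if tl <= tau < tr:
                            j, k = region_of(src), region_of(dst)
                            if j != k:
                                pairs.add((j, k))
                for j, k in pairs:
                    Ajk[lab].setdefault((j, k),
                                        np.zeros(len(windows)))[w_idx] += span
    rows = []
    for lab in subsets:
        for (j, k), num in sorted(Ajk[lab].items(), key=lambda kv: str(kv[0])):
            for w_idx, (tl, tr) in enumerate(windows):
                if A[lab][w_idx] > 0:
                    rows.append({"subset": lab, "region_from": j,
                                 "region_to": k, "t_left": tl, "t_right": tr,
                                 "phi": num[w_idx] / A[lab][w_idx],
                                 "A": A[lab][w_idx]})
        if not Ajk[lab]:
            for w_idx, (tl, tr) in enumerate(windows):
                rows.append({"subset": lab, "region_from": None,
                             "region_to": None, "t_left": tl, "t_right": tr,
                             "phi": 0.0, "A": A[lab][w_idx]})
    return pd.DataFrame(rows)


def replicate_and_average(pipeline, n_replicates: int, seed,
                          key_columns, value_columns=("z",)):
    """Average tables over independently seeded replicates.

    ``pipeline(rng)`` must return a tidy DataFrame whose rows are identified
    by ``key_columns`` and whose ``value_columns`` are averaged; the result
    carries mean, min, and max per cell.  Missing rows in a replicate are
    treated as zero for averaging (a region pair absent from one replicate's
    flux table has zero flux in that replicate).
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be at least 1")
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    frames = []
    for r, ss in enumerate(streams):
        df = pipeline(np.random.default_rng(ss)).copy()
        df["replicate"] = r
        frames.append(df)
    out = [average_replicates(frames, key_columns, col).set_index(
        list(key_columns)) for col in value_columns]
    return pd.concat(out, axis=1).reset_index()


def average_replicates(frames, key_columns, value_column) -> pd.DataFrame:
    """Mean/min/max of one value column across replicate frames.

    Rows absent from a replicate count as zero in that replicate (e.g. a
    region pair with no migration events has zero flux there).
    """
    n_reps = len(frames)
    allf = pd.concat(frames, ignore_index=True)
    allf = allf.dropna(subset=list(key_columns))
    wide = allf.set_index(list(key_columns) + ["replicate"])[value_column] \
        .unstack("replicate")
    wide = wide.reindex(columns=range(n_reps)).fillna(0.0)
    col = value_column
    return pd.DataFrame({
        f"{col}_mean": wide.mean(axis=1),
        f"{col}_min": wide.min(axis=1),
        f"{col}_max": wide.max(axis=1),
    }).reset_index()
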