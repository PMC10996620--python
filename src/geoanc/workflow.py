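"""End-to-end pipelines tying location inference to the ancestry summaries.

The replicate design mirrors the empirical workflow: fit and average the
discrete cost functions once (deterministic), then per replicate draw each
node's cell uniformly among the minimizers of its averaged cost function,
sample a minimum-cost migration history for every edge conditional on those
cells, compute the ancestry coefficients and flux, and average the tables
across replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ancestry import ancestry_coefficients, ancestry_flux, average_replicates
from .errors import ParameterError
from .history import HistorySampler, sample_histories_for_ts
from .locate import average_cost_functions, locate_ancestors
from .trees import TreeSeq

__all__ = ["draw_node_cells", "replicate_summaries"]

DEFAULT_BIN_GENERATIONS = 100.0
DEFAULT_GENERATION_YEARS = 25.0
DEFAULT_REPLICATES = 100


def draw_node_cells(F, rng) -> dict:
    """One cell per node, uniform over the minimizer set of its F_u."""
    cells = {}
    for u, acf in F.items():
        _, minimizers = acf.fn.minimize()
        m = np.asarray(minimizers)
        cells[u] = int(m[rng.integers(m.size)]) if m.size > 1 else int(m[0])
    return cells


def replicate_summaries(tsw: TreeSeq, cost_matrix, grid, subsets,
                        regions=None, times=None, windows=None,
                        n_replicates: int = DEFAULT_REPLICATES, seed=None,
                        weighting="none", flux_denominator="overlap",
                        naive=False):
    """Replicate-averaged ancestry coefficient and flux tables.

    Returns ``(z_mean, flux_mean)`` frames with mean/min/max per table cell.
    Either ``times`` or ``windows`` may be omitted to skip that summary.
    """
    if times is None and windows is None:
        raise ParameterError("need a time grid and/or a window list")
    F = average_cost_functions(tsw, cost_matrix, weighting=weighting,
                               naive=naive)
    sampler = HistorySampler(grid)
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    z_frames, flux_frames = [], []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cells = draw_node_cells(F, rng)
        histories = sample_histories_for_ts(tsw, cells, sampler, rng)
        if times is not None:
            z = ancestry_coefficients(tsw, histories, subsets, regions, times)
            z["replicate"] = r
            z_frames.append(z)
        if windows is not None:
            fl = ancestry_flux(tsw, histories, subsets, regions, windows,
                               denominator=flux_denominator)
            fl["replicate"] = r
            flux_frames.append(fl)
    z_mean = (average_replicates(z_frames, ["subset", "region", "time"], "z")
              if z_frames else None)
    flux_mean = (average_replicates(
        flux_frames, ["subset", "region_from", "region_to", "t_left",
                      "t_right"], "phi") if flux_frames else None)
    return z_mean, flux_mean
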