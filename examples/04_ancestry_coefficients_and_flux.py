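"""Spatiotemporal ancestry coefficients and ancestry flux on simulated data.

Simulates a dispersing population, discretizes its arena into grid cells,
and tracks where the samples' ancestors lived (z coefficients) and when
ancestry moved between the west and east halves of the arena (flux).
"""

import numpy as np

from geoanc.geography import (assign_samples_to_cells, build_planar_grid,
                              cost_matrix_from_adjacency)
from geoanc.simulate import SimParams, simulate_population
from geoanc.trees import TreeSeq
from geoanc.workflow import replicate_summaries

params = SimParams(sigma=1.0, n_generations=200, seed=20240902)
truth = simulate_population(params)
ts = truth.tsw.ts

grid = build_planar_grid((0, 0, params.side, params.side), params.side / 5,
                         "square")
cells = assign_samples_to_cells(
    np.array([truth.locations[int(s)] for s in ts.samples()]), grid)
tsw = TreeSeq(ts, {int(s): int(c) for s, c in zip(ts.samples(), cells)})

# regions: west vs east half of the arena
regions = {c: ("west" if grid.centers[c, 0] < params.side / 2 else "east")
           for c in range(grid.num_cells)}
times = np.arange(0.0, 200.0, 25.0)
windows = [(t, t + 50.0) for t in np.arange(0.0, 200.0, 50.0)]

z, flux = replicate_summaries(tsw, cost_matrix_from_adjacency(grid), grid,
                              {"all": [int(s) for s in ts.samples()]},
                              regions=regions, times=times, windows=windows,
                              n_replicates=20, seed=3)
print("fraction of ancestry in each half of the arena through time:")
print(z.pivot_table(index="time", columns="region", values="z_mean")
      .round(3).to_string())
print("\nancestry flux between halves (mean over 20 replicates):")
print(flux[["region_from", "region_to", "t_left", "t_right", "phi_mean"]]
      .round(4).to_string(index=False))
# each z row sums to 1 over regions; phi is the fraction of surviving
# ancestral material that crossed between the halves in that window.
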