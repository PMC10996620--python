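"""Simulate a dispersing population and recover its dispersal scale.

Runs the density-regulated spatial forward model at sigma = 1, computes the
oracle effective migration rate from the true ancestor locations, and
compares it with the estimate recovered from the genealogy alone.
"""

import numpy as np

from geoanc.locate import average_cost_functions, effective_migration_rate, \
    locate_ancestors
from geoanc.simulate import SimParams, oracle_sigma, simulate_population

params = SimParams(sigma=1.0, seed=20240901)
truth = simulate_population(params)
ts = truth.tsw.ts
print(f"simulated {ts.num_samples} sampled genomes, {ts.num_trees} local "
      f"trees, {ts.num_nodes} nodes on a {params.side:g}x{params.side:g} arena")

sigma_e = oracle_sigma(truth, "gaussian")
est = effective_migration_rate(truth.tsw, "quadratic", weighting="inverse",
                               seed=1)
print(f"oracle sigma_e (true locations):    {sigma_e:.3f}")
print(f"estimated from genealogy alone:     {est.sigma_hat:.3f}")
print(f"mean per-branch migration cost:     {est.rate:.3f}")

# location accuracy for recent ancestors
F = average_cost_functions(truth.tsw, "quadratic", weighting="inverse")
df = locate_ancestors(F, times=ts.nodes_time)
young = df[(df["time"] > 0) & (df["time"] < 50)]
err = np.mean(np.hypot(young["x"] - [truth.locations[u][0] for u in young["node_id"]],
                       young["y"] - [truth.locations[u][1] for u in young["node_id"]]))
print(f"mean location error, nodes < 50 generations: {err:.2f} "
      f"(arena side {params.side:g})")
# sigma_e exceeds the nominal kernel sd because paternal genealogical links
# add the mother-father mate distance; the parsimony-based estimate tracks
# sigma_e monotonically but undershoots it, since a most-parsimonious
# history is the cheapest one consistent with the data.
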