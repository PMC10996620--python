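# Methods

## Model and assumptions

The package treats a tree sequence as ground truth: a set of nodes (sampled
and ancestral haplotypes, each with a time in generations before present)
and edges (parent–child transmissions attached to genomic intervals), whose
restriction to any genomic position is a local genealogical tree.  Migration
is modelled purely as a cost on ancestor–descendant displacements; lineages
are assumed to move independently of one another and of the coalescent
process.  The method is a heuristic summary, not a likelihood: it finds the
cheapest migration explanation of the sampled locations, and everything
downstream inherits that minimal-cost character.

## The parsimony fit

For node *u* in local tree *k*, `f_uk(x)` is the minimum over all placements
of the other nodes of the sum of per-branch costs `w_e · d(parent, child)`,
with *u* pinned at *x* and samples pinned at their observed locations.  It
is computed in two sweeps:

* **inside** (postorder): `inside_u` = Σ over children *c* of
  `(K_w ⊗ inside_c)`, where `(K_w ⊗ f)(x) = min_y w·d(x, y) + f(y)` is the
  min-plus convolution through the branch kernel;
* **outside** (preorder): `outside_root = 0`;
  `outside_c = K_w ⊗ (outside_u + Σ_{siblings s} K_w ⊗ inside_s)`, built
  with prefix/suffix partial sums over the (sorted) child list so cost
  functions are only ever added, never subtracted;
* `f_u = inside_u + outside_u`.

The three cost models are closed under addition, positive scaling, and the
convolution:

* **discrete**: vectors over G cells; `(K_w ⊗ f)[x] = min_y w·C[x,y] + f[y]`.
  `C` must be finite (connected grid) with zero diagonal; asymmetric
  matrices are allowed and are read in the parent→child (time-forward)
  direction, with the transposed matrix used in the outside sweep.  When a
  grid with unit-cost neighbour migration is supplied, `C` is the *geodesic*
  matrix (unit cost × minimum neighbour steps), because one branch may carry
  any number of migration events; this metric closure is what makes the
  Sankoff programme exact under the event-pricing model.  User-supplied
  arbitrary matrices are accepted as-is, with the caveat that history
  sampling requires metric-closed costs.
* **quadratic** (squared Euclidean): per-axis `a(x−m)² + c`;
  convolution maps curvature `a → a·w/(a+w)` (center and offset fixed);
  sums combine by the weighted-mean formula.  Both axes are carried
  separately; the two-leaf fit reproduces the closed-form weighted mean
  `(w₁x₁ + w₂x₂)/(w₁+w₂)` exactly.
* **Manhattan**: per-axis convex piecewise-linear functions stored as
  sorted breakpoints with non-decreasing slopes; convolution clamps slopes
  to `[−w, +w]` (the function is unchanged where `|f′| ≤ w` and continues
  linearly outside); sums merge breakpoint lists and prune
  redundant breakpoints.  Breakpoints of every fitted function are a subset
  of the sample coordinates, so L1 optima land on sample coordinates.

Sampled nodes are represented by degenerate pins (zero at their own
location); samples are required to be leaves.  Polytomies are handled
natively by the sums over children, and local trees may have several roots
(each root's component is fitted independently) — edge filtering can
disconnect trees.

**Branch weighting.**  `w = 1` (unweighted) or `w = 1/branch length`.
Zero-length branches under inverse weighting are floored at a configurable
`eps` (default 1e−8 generations), which keeps weights finite while making
separation of the endpoints effectively prohibitive.

## Genome-wide averaging and location estimates

`F_u` is the genomic-span-weighted average of `f_uk` over the local trees in
which *u* carries at least one edge; nodes with no edges anywhere report no
estimate.  The scan over trees maintains the inside values incrementally:
after each edge diff, only nodes on the rootward paths of changed edges are
recomputed (in ascending time order, so children precede parents), while
the outside sweep is rerun per tree.  Because the incremental path
re-executes exactly the same floating-point expressions as a from-scratch
refit, its output is bit-identical to the naive route (`naive=True`), which
remains available and defines the semantics; the incremental scan is purely
a performance device.

Ancestors are placed at the minimizer of `F_u`.  Discrete ties are resolved
by policy — lowest cell id, seeded uniform draw, or reporting the full
minimizer set — and the tie count is always recorded.  Piecewise-linear
argmin intervals are reported as their midpoint (the full box under
`report_all`).  Soft assignments draw cells with probability proportional
to `exp(−λ·(F_u(x) − min F_u))`; λ = 0 is uniform, large λ concentrates on
the minimizer set.

## Migration histories and ancestry statistics

The ancestry statistics need lineage locations at arbitrary times, not just
at node times.  Conditional on the endpoint cells of an edge, a minimum-cost
history under unit-cost neighbour migration is a shortest grid path; the
sampler draws uniformly over all shortest paths (walking the shortest-path
DAG with predecessor-count weights) and places the event times as order
statistics of independent uniforms on the branch interval.  Event counts
always equal the geodesic distance between the endpoints.  Times run in
generations before present; an event `(τ, j, k)` means the ancestor moved
from cell *j* to cell *k* at τ *in forward time* (the lineage occupies *j*
at times ≥ τ).  Uniform path sampling and uniform order-statistic times are
the least-informative choices consistent with minimum cost.

`z_ik(t)`: for each sample and genomic position, the unique lineage spanning
time *t* on that sample's path (if any) contributes the local tree's span to
the denominator `A_i(t)` and to the numerator of the region containing the
interpolated lineage location.  Positions whose local root is younger than
*t* are excluded from both, so Σ_k z_ik(t) = 1 wherever `A_i(t) > 0` (the
code asserts this on every run), and z at t = 0 reproduces the sample
composition exactly.  Material is accounted once per descending sampled
path: a segment ancestral to several samples counts once per sample.

`φ_ijk(t_l, t_r)`: the denominator counts (span-weighted) sample positions
whose path overlaps the window; the numerator for the ordered pair (j, k)
counts positions whose path carries at least one forward-time j→k move
inside the window — an indicator, not an event count.  The alternative
denominator requiring the path to span the entire window is available
(`denominator="span_full"`); window overlap is the default because a
lineage that exists during part of the window can contribute flux during
that part.

The replicate design re-draws tie-broken cells and histories with
independent seeded streams (default 100 replicates) and reports mean,
minimum, and maximum per table cell; rows absent from a replicate (a pair
with no events) count as zero in that replicate.

## Effective migration rate and dispersal calibration

For each local tree a most-parsimonious full assignment is backtraced from
the inside values (root at its argmin, each child at the argmin of branch
cost plus its own inside function; discrete ties are resolved by seeded
sampling and counted).  The rate is the span-weighted average over trees of
the mean per-branch cost of that history.  With inverse-branch-length
weighting the rate is calibrated to a dispersal standard deviation:

* Gaussian kernel / quadratic cost: per-branch `‖Δ‖²/t` has expectation
  `2σ²` under a 2-D random walk, so `σ̂ = sqrt(rate/2)`;
* Laplace kernel / Manhattan cost: per axis `E|Δ| = σ·sqrt(t/2)`, so the
  statistic `(|Δx|+|Δy|)/sqrt(t)` has expectation `σ·sqrt(2)` and is
  averaged per branch and divided by `sqrt(2)`.

A most-parsimonious history minimizes total cost, so per-branch costs — and
hence σ̂ — systematically undershoot the truth; in the validation study the
ratio σ̂/σ_e is a stable ≈ 0.65–0.70 across dispersal scales and seeds.
The estimator is therefore a *relative* dispersal measure: it is monotone in
the true scale (Spearman ρ ≥ 0.93 against the oracle in every run of the
recovery study) but not an unbiased absolute one, and the package makes no
bias correction.

## The synthetic-data generator

`simulate_population` implements a density-regulated spatial birth–death
model: semelparous hermaphroditic diploids on a square arena with
reflecting boundaries; offspring numbers Poisson with mean
`R/(1 + N_t(R−1)/K)` where `N_t` is the density (individuals within radius
3σ, self included, divided by the circle area); one mate per mother drawn
uniformly within 3σ (selfing only when no neighbour exists — skipping
reproduction instead would silently bias demography); offspring displaced
from the mother by a Gaussian or Laplace kernel with per-axis sd σ and
surviving with probability `min(1, K/O_t)`; recombination at a fixed per-bp
rate with full tree-sequence recording, simplified at the end to the extant
individuals.  Densities are exact pairwise counts (kd-tree), not kernel
smoothing: reproducibility over speed at desk scale.

Defaults, chosen once as the study conditions: σ = 1, R = 2,
`K = 30/(π(3σ)²)` (so an interaction circle holds ~30 individuals, matching
the 30 founders), arena side 20σ, 300 generations, 10⁶ bp at 10⁻⁸
recombination per bp per generation.  This yields ~400 adults, tens of
local trees, and a ~30-second nine-simulation recovery grid; the dispersal
grid σ ∈ {0.5, 1.0, 2.0} with three replicates per level is a subsample of
a full calibration sweep, sized for a single-CPU desk budget.

What the generator emulates: isolation by distance, local density
regulation, boundary effects, kernel shape (Laplace kurtosis > Gaussian).
What it does not: overlapping generations, heterogeneous or temporally
varying habitat, selection, long-distance admixture pulses, and
tree-sequence *inference* error — inputs here are true genealogies, so
passing tests bound method error only, not error inherited from upstream
reconstruction.  One intrinsic feature worth noting: the true
per-generation displacement along a *paternal* genealogical link includes
the mother–father mate distance on top of the dispersal kernel, so the
oracle σ_e (ML estimate from true locations, `mean(Δ²/t)` per axis for the
Gaussian case, `sqrt(2)·mean(|Δ|/sqrt(t))` for Laplace, zero-length links
excluded) sits ~30% above the nominal kernel σ.  σ_e, not σ, is the
recovery target.

`walk_locations_on_tree_sequence` is a fast fixture that paints locations
down an existing dated tree sequence (per-axis variance σ²·t along each
child's largest-span parent edge, roots at a configurable origin); it gives
estimator tests exact random-walk truth without demography.

## Input handling and filtering

Tree sequences load from `.trees` files or a plain-TSV dialect (`nodes.tsv`,
`edges.tsv`, `samples.tsv`); validation (parent older than child, no
overlapping intervals per child, one location per sample) is enforced at
load.  Genomic coordinates are 0-based half-open throughout.

Genealogical outlier filtering removes edges touching non-sample nodes
whose in- or out-degree falls at or above the nearest-rank `(1 − p)`
quantile of the positive-degree distribution *and* strictly above its
median — the second condition makes the filter inert on near-uniform degree
distributions, where the top quantile equals the typical degree and a pure
quantile rule would remove everything.  `p = 0` disables filtering.  Degrees
are computed once, after restriction to the analysis samples; the filter is
a single pass, and the resulting (possibly multi-rooted) trees are handled
throughout.

## Numerical choices

* Min-plus convolutions use exact closed forms per family; no generic
  numerical minimization is performed anywhere in the fit.
* Piecewise-linear breakpoints are pruned whenever a slope repeats;
  breakpoint unions use exact float comparison (no snapping tolerance).
* Tie detection (discrete minimizer sets, flat PWL argmin intervals) uses
  exact equality of computed values; under unit-cost grids and dyadic
  weights these comparisons are exact by construction.
* The inverse-weighting branch-length floor is 1e−8 generations.
* Disconnected grids produce infinite geodesic entries, flagged at
  construction and rejected with a clear error if the DP would consume them.

## Limitations

* Parsimony ignores near-optimal solutions; summaries describe major
  trends, not calibrated posterior uncertainty (the soft-assignment
  sampler explores, but does not calibrate, that uncertainty).
* The effective migration rate is relatively, not absolutely, calibrated
  (see above).
* Continuous-mode location histories are not interpolated; the ancestry
  statistics are defined for discrete regions only.
* No spherical geometry: global grids must be built and land-masked
  upstream and supplied as cell/adjacency tables.
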