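# Methods

`phylogrid` implements the standard spatial-phylogenetics workflow for a
regional flora or fauna: occurrence records are cleaned and binned onto a
square grid, combined with a rooted phylogeny, scored with per-cell
diversity and endemism metrics, tested against a structured null model,
classified with CANAPE, and partitioned into bioregions by range-weighted
phylogenetic turnover. This note documents the models, conventions,
numerical choices, and what the synthetic validation does and does not
establish.

## Data model

The central object is a binary presence–absence matrix **X** over grid
cells × taxa. Multiple records of a taxon in a cell collapse to one
presence; abundance is never used. Column sums are taxon range sizes
`r_t` (cells occupied), row sums are cell richness. Cells with no records
are excluded from all analyses and emitted as nulls in outputs so maps
can show them as gaps.

The phylogeny is any rooted tree with non-negative branch lengths
(polytomies allowed). A *branch* is the edge above a non-root node; the
root carries no edge (a root edge length in the input is ignored with a
warning). For each branch `b` with length `L_b`, its descendant tip set
`D_b` and its *range* `R_b` — the set of cells where at least one member
of `D_b` occurs — are computed bottom-up; `R_parent ⊇ R_child` always
holds. Tree tips and matrix columns are reconciled before any metric:
tips without occurrences are pruned (collapsed unifurcations sum their
edge lengths) and matrix taxa absent from the tree are dropped, both
reported. Reconciliation is idempotent.

## Per-cell metrics

For an analyzable cell `c` with branch set `B_c = {b : c ∈ R_b}`:

| metric | definition |
|---|---|
| TR  | number of taxa present (row sum) |
| WE  | Σ_{t∈c} 1/r_t |
| PD  | Σ_{b∈B_c} L_b |
| PE  | Σ_{b∈B_c} L_b / \|R_b\| |
| RPD | PD / PD on the comparison tree |
| RPE | PE / PE on the comparison tree |

Conventions worth stating:

* **PD includes the path to the root.** A cell containing a single taxon
  scores that tip's root-path length, not zero. This is the convention of
  the standard gridded-biodiversity toolchain and makes PD/PE sums
  unambiguous.
* **The comparison tree** has identical topology with every branch set to
  `total_length / n_branches`, preserving total length exactly. RPD and
  RPE therefore contrast pure tree shape with expectation near 1: values
  above 1 flag concentrations of unusually long branches, below 1 of
  short branches. (With lengths preserved only up to a global scale, the
  RPD/RPE ratios are scale-invariant anyway; preserving the total makes
  the intermediate PD_alt/PE_alt values interpretable too.)
* **Conservation identities.** Because each branch's length is divided
  evenly over its range, Σ_c PE_c equals the total tree length, and
  Σ_c WE_c equals the number of taxa, whenever every taxon is sampled.
  Both identities are enforced in tests to 1e-10 and are useful run-time
  sanity checks on real data.
* Cells with a zero RPD/RPE denominator (possible only for degenerate
  all-zero-length trees) are flagged NaN and excluded from significance.

## Structured null model and significance

The null holds both marginals of **X** fixed — every taxon keeps its
range size, every cell keeps its richness — and reshuffles which taxa
occupy which cells. Branch lengths are never shuffled. The default
sampler is a checkerboard-swap MCMC: pick two presences `(r1,c1)`,
`(r2,c2)` with `r1≠r2`, `c1≠c2` and both diagonal entries absent, and
swap them to `(r1,c2)`, `(r2,c1)`. Every accepted swap preserves the
marginals exactly (asserted, not assumed, on every replicate); the
chain's stationary distribution is uniform over binary matrices with the
observed marginals. Burn-in is 10× the number of presences in attempted
swaps and thinning between replicates 5×; both factors and the sampler
itself are pluggable (`sampler_factory`), since any exact-marginal
sampler is admissible. A matrix admitting no swap (e.g. all-ones) is
returned unchanged with a warning.

Significance per cell and metric is the empirical quantile
`q = (#{null < obs} + 0.5·#{null == obs}) / n_rand`, with ties counted
half. Tie detection uses exact float equality: null and observed metrics
flow through the identical vectorized computation, so marginal-determined
quantities tie bitwise — TR, whose richness is held fixed by the null,
must come out at q = 0.5 everywhere, and is carried through the test as a
built-in self-check. Two-tailed map categories use per-tail α = 0.025
(`q ≥ 0.975` high, `q ≤ 0.025` low). The default replicate count is 999;
`n_rand < 19` is rejected as unable to resolve the tails. Identical seed
and inputs give bitwise-identical results.

The tested metrics are PD, RPD, PE on the original tree, PE on the
comparison tree, and RPE — the last three because CANAPE needs both PE
variants. This null assumes occurrences of a taxon are spatially
unstructured; spatially autocorrelated or dispersal-limited nulls are out
of scope.

## CANAPE

Classification is a pure function of three quantiles. Step 1
(candidacy): a cell is endemism-significant if PE on *either* tree sits
in the upper one-tailed α = 0.05 of its null. Step 2: among candidates,
`q_RPE ≥ 0.975` → **paleo** (range-restricted long branches),
`q_RPE ≤ 0.025` → **neo** (range-restricted short branches), otherwise
**mixed**; mixed cells with both PE quantiles ≥ 0.99 are promoted to
**super**. All four thresholds are configuration knobs with these
defaults, and `super` can be collapsed into `mixed`. Categories are
exhaustive and mutually exclusive, and increasing `q_RPE` can never move
a candidate from paleo toward neo (both property-tested). No
multiple-testing correction is applied across cells, following the
convention for these per-cell randomization maps.

## Range-weighted turnover and bioregions

Each branch carries weight `w_b = L_b/|R_b|`. For cells i, j:

    S_i = Σ_{b∈B_i} w_b   (identically the cell's PE; cross-checked to 1e-10)
    W_ij = Σ_{b∈B_i∩B_j} w_b
    d_ij = 1 − 2·W_ij/(S_i + S_j)

`d` is symmetric with zero diagonal, 0 for identical lineage composition
and 1 for none shared. Because branch sets include root paths, any two
occupied cells share deep branches; those have large ranges and hence
small weights, so the weighting discounts them naturally and no branch is
excluded. Bioregions come from average-linkage (UPGMA) agglomeration of
`d` cut to a user-chosen `k`; cells are processed in lexicographic id
order so tie-breaking is deterministic. `k` is never auto-selected — a
mean-silhouette profile over candidate `k` is available as an aid. With
fully disjoint planted blocks, all between-block distances tie at exactly
1.0 and coarser cuts can coincide with the planted partition; the
silhouette profile then plateaus rather than peaks uniquely.

## Spatial conventions

All gridding is planar, in meters, on half-open cells
`[x0, x0+s) × [y0, y0+s)` from a lower-left origin — each point falls in
exactly one cell, and a point on a shared edge belongs to the
higher-index cell. Default cell size is 10 km. With a boundary polygon,
only cells whose intersection has positive area are retained (cells
touching the boundary only along an edge or corner are not). Cleaning
drops records with missing coordinates, coordinates exactly equal to
zero (the placeholder convention in occurrence databases; no fuzzy
tolerance), and points outside the boundary, each logged with its
reason. Geographic inputs should be projected before gridding; a
built-in equirectangular approximation
(`x = R·cos(lat0)·Δlon, y = R·Δlat`) is provided and is adequate at
island scale (distortion grows away from the reference point) — for
continental extents, project externally with a proper equal-area CRS and
feed planar coordinates.

## Synthetic landscapes: what they emulate and what they don't

The generator produces Yule (pure-birth, uniform tip-splitting)
topologies with i.i.d. exponential(1) branch lengths and Bernoulli
background occupancy, plus planted structure with recorded ground truth:

* **paleo relict** — one tip's terminal branch stretched ×`m_paleo`
  (default 20), occurrences confined to a small block with occupancy 1;
* **neo radiation** — terminal branches of one clade (nearest available
  size to the request; realized tips recorded) shrunk ×`m_neo`
  (default 0.05), likewise confined;
* **bioregions** — disjoint clades confined to disjoint blocks with
  within-block occupancy 0.5 and low background noise.

Default validation sizes are desk-scale: the endemism landscape uses a
12×12 grid of 10 km cells, 60 taxa, 15% background occupancy and 2×2
corner hotspot blocks; the bioregion landscape uses three 30-cell bands
with 15-taxon clades and 2% noise; null tests use 199 replicates and the
type-I study pools five 100-taxon/100-cell landscapes. These sizes keep
the full validation suite in the tens of seconds while leaving each
planted signal identifiable. Hotspot "recovery" in the validation means
at least one planted-block cell receives the planted label — the natural
detection criterion for a map reader — not that every block cell does;
under the fixed-marginal null the relict's range relocates wholesale in
some replicates, so individual block cells near the decision threshold
can legitimately fall to `mixed`.

What passing these tests shows: the metric engine matches an independent
brute-force oracle exactly; the null is structurally exact and its
significance calibrated (type-I ≈ 5% at the 0.05 two-tailed level); and
planted signals of the stated effect sizes are recovered. What they do
not show: robustness to real-data pathologies — taxonomic synonymy,
spatially autocorrelated sampling effort, coordinate uncertainty,
tree-reconstruction error — none of which the generator emulates.
Randomization-based significance is robust to *uniform* sampling-effort
differences between cells (richness is conditioned on), but not to
within-cell taxonomic bias.

## Numerical and degenerate-input choices

* Incidence is uint8; metric accumulation in float64 via matrix products;
  oracle agreement is asserted at 1e-10.
* Missing branch lengths parse as 0 with a warning; zero-length branches
  contribute 0 to every sum. Negative lengths are fatal.
* Duplicate tip labels, unbalanced Newick, empty tree/matrix
  intersection, and `k` outside `[1, n_cells]` are fatal.
* All randomness derives from integer seeds through
  `numpy.random.Generator` (PCG64); the pipeline derives fixed per-stage
  seeds from the top-level seed so toggling one stage never shifts
  another stage's stream.

## Known limitations

* The checkerboard chain's mixing time is not monitored; the default
  burn-in/thinning factors are generous for matrices up to a few thousand
  presences (the calibration test covers exactly this regime) but very
  large or very dense matrices may need longer chains, or a fill-based
  sampler plugged in.
* Cell counts for a real coastline depend on the (unstated) projection
  and grid origin; reproducing a published grid exactly requires both.
* The equirectangular projection helper is not equal-area; at island
  scale the induced cell-area distortion is well under 1%, but it is the
  user's responsibility at larger extents.
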