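# phylogrid

Spatial phylogenetics for gridded occurrence data: where on a landscape
is evolutionary history concentrated, and is that concentration more
than sampling noise?

Given georeferenced occurrence records and a rooted phylogeny with
branch lengths, `phylogrid` bins records into equal-area grid cells and
computes, per cell:

* **TR** — taxon richness;
* **WE** — weighted endemism, Σ 1/r_t over present taxa (r_t = cells
  occupied by taxon t);
* **PD** — Faith's phylogenetic diversity, Σ L_b over branches b whose
  descendants reach the cell (root path included);
* **PE** — phylogenetic endemism, Σ L_b/|R_b| with each branch length
  divided among the |R_b| cells of its range;
* **RPD / RPE** — PD (resp. PE) relative to a comparison tree with the
  same topology and all branch lengths equal, isolating tree *shape*:
  values >1 mark concentrations of long branches, <1 of short ones.

Significance comes from a structured randomization that reshuffles taxon
identities across cells while holding every taxon's range size and every
cell's richness fixed (checkerboard-swap MCMC with exact marginals;
999 replicates by default). On top of the per-cell quantiles, **CANAPE**
classifies endemism hotspots as *neo* (range-restricted short branches),
*paleo* (range-restricted long branches), *mixed* or *super*, and a
range-weighted **phylo-Sorensen** turnover matrix
(d_ij = 1 − 2W_ij/(S_i+S_j) on branch weights L_b/|R_b|) is clustered
with UPGMA into bioregions.

A synthetic-data module generates landscapes with *planted* relicts,
radiations and bioregion blocks plus ground truth, so the entire chain is
testable without any downloads. It is intended for researchers mapping
conservation priorities for a regional flora or fauna, and doubles as a
compact, fully tested reference implementation of these metrics.

## Worked example

The numbered scripts under `analysis/` run a complete desk-scale study
on synthetic data. `analysis/01_simulate_landscape.py` generates a
60-taxon tree on a 12×12 grid of 10 km cells with two planted hotspots —
a paleo-relict (terminal branch ×20) confined to the lower-left 2×2
block and a 6-tip radiation (terminal branches ×0.05) confined to the
upper-right block — plus 2% deliberately corrupt occurrence rows:

```
$ python analysis/01_simulate_landscape.py
tree: 60 tips, total length 106.84
occurrences: 1159 rows (1136 presences + corrupt rows)
planted paleo relict t056 in ['r0_c0', 'r0_c1', 'r1_c0', 'r1_c1']
planted neo radiation (6 tips) in ['r10_c10', 'r10_c11', 'r11_c10', 'r11_c11']
```

`02` cleans, grids and scores the cells. The four paleo-block cells top
the PE ranking — a long branch confined to four cells contributes
20-fold more per-cell weight than a background branch — and their
RPE ≫ 1 already hints at old endemism:

```
$ python analysis/02_diversity_endemism.py
cleaning: kept 1136/1159 records; rejections: {'zero coordinate': 12, 'missing coordinate': 11}
grid: 144 cells, 144 analyzable (0 without records), 60 taxa
top 5 cells by phylogenetic endemism (PE):
           TR     WE      PD     PE    RPD    RPE
r0_c0    14.0  0.942  50.567  2.821  1.095  2.052
r1_c0    11.0  0.688  42.680  2.643  1.150  2.544
r0_c1     8.0  0.530  41.979  2.536  1.288  3.035
r1_c1     8.0  0.585  39.821  2.516  1.294  2.921
r11_c10  14.0  1.859  43.918  1.450  0.970  0.451
```

`03` runs the structured null (199 replicates at desk scale) and CANAPE.
Both planted blocks surface with the correct flavor — paleo cells via
the upper RPE tail, neo cells via q_RPE = 0 and extreme PE on the
equal-branch-length comparison tree:

```
$ python analysis/03_significance_canape.py
PD: 4 cells significantly high, 7 significantly low (per-tail alpha 0.025)
RPD: 2 cells significantly high, 7 significantly low (per-tail alpha 0.025)
CANAPE: 11/144 cells with significant endemism; categories {'not_significant': 133, 'mixed': 5, 'neo': 4, 'paleo': 2}
        category  q_PE_orig  q_PE_alt  q_RPE
r0_c1      paleo      1.000     0.824  1.000
r1_c1      paleo      0.975     0.839  0.980
r10_c10      neo      0.638     1.000  0.000
...
```

`04` builds the turnover matrix, cuts the UPGMA dendrogram, and — on a
second landscape with three planted 15-taxon clade bands — recovers the
bioregions perfectly:

```
$ python analysis/04_bioregions.py
turnover: 144 cells, mean dissimilarity 0.701
bioregions at k=3: sizes [4, 4, 136]
planted-bioregion landscape: k=3 recovery ARI = 1.000
```

(On the hotspot landscape the k=3 cut isolates exactly the two planted
4-cell blocks against the background — the hotspots are also the most
lineage-distinct neighborhoods.)

The same workflow is available as a CLI (`phylogrid simulate | clean |
grid | metrics | randomize | canape | turnover | all`) and as a single
call, `phylogrid.run_pipeline(RunConfig(...))`, which writes metrics,
significance, CANAPE and bioregion tables (CSV/GeoJSON/Newick) plus a
manifest that reproduces the run bit-for-bit.

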