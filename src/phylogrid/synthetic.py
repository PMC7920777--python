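"""Synthetic trees and presence landscapes with known planted structure.

The generator emulates the inputs of a gridded island flora study: a
rooted phylogeny with branch lengths and a presence–absence landscape on
a rectangular grid. Structure can be planted so that every downstream
stage has a known answer:

* a paleo-endemic relict — one tip whose terminal branch is stretched by
  a large multiplier and whose occurrences are confined to a small cell
  block;
* a neo-endemic radiation — a clade whose terminal branches are shrunk by
  a small multiplier, likewise confined to a block;
* bioregions — disjoint clades confined to disjoint cell blocks, giving
  block-structured lineage turnover.

Topologies are Yule (pure-birth, uniform random tip splitting) with
i.i.d. exponential(1) branch lengths. All randomness flows from a single
integer seed; identical seeds give identical Newick strings and
landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .occurrences import Grid, build_grid
from .phylotree import IndexedTree
from .presence import PresenceMatrix

__all__ = ["Block", "Scenario", "simulate_tree", "simulate_landscape",
           "scenario_grid", "emit_occurrences", "simulate_endemism_landscape",
           "simulate_bioregion_landscape"]


@dataclass(frozen=True)
class Block:
    """Rectangular block of grid cells (rows row0..row0+n_rows-1, same cols)."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("empty block")

    def cell_ids(self) -> list[str]:
        return [Grid.cell_id(r, c)
                for r in range(self.row0, self.row0 + self.n_rows)
                for c in range(self.col0, self.col0 + self.n_cols)]

    def within(self, n_rows: int, n_cols: int) -> bool:
        return (0 <= self.row0 and self.row0 + self.n_rows <= n_rows
                and 0 <= self.col0 and self.col0 + self.n_cols <= n_cols)


@dataclass
class Scenario:
    """Landscape recipe: grid shape, background occupancy, planted features."""

    n_rows: int
    n_cols: int
    cell_size: float = 10_000.0
    p_bg: float = 0.1
    paleo_block: Block | None = None
    neo_block: Block | None = None
    bioregion_blocks: tuple[Block, ...] | None = None
    bioregion_clades: tuple[tuple[str, ...], ...] | None = None
    p_within: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg <= 1.0):
            raise ValueError("p_bg must be in [0, 1]")
        if not (0.0 <= self.p_within <= 1.0):
            raise ValueError("p_within must be in [0, 1]")
        for blk in self._all_blocks():
            if not blk.within(self.n_rows, self.n_cols):
                raise ValueError(f"block {blk} outside the grid")
        if (self.bioregion_blocks is None) != (self.bioregion_clades is None):
            raise ValueError("bioregion blocks and clades must come together")
        if self.bioregion_blocks is not None and \
                len(self.bioregion_blocks) != len(self.bioregion_clades):
            raise ValueError("one clade per bioregion block required")

    def _all_blocks(self) -> list[Block]:
        blocks = [b for b in (self.paleo_block, self.neo_block) if b is not None]
        if self.bioregion_blocks:
            blocks.extend(self.bioregion_blocks)
        return blocks


def _grow_yule(root: dendropy.Node, n_tips: int, rng: np.random.Generator):
    """Uniform random tip splitting under ``root`` until n_tips leaves."""
    leaves = [root]
    while len(leaves) < n_tips:
        idx = int(rng.integers(0, len(leaves)))
        parent = leaves.pop(idx)
        for _ in range(2):
            leaves.append(parent.new_child())
    return leaves


def _finalize_tree(tree: dendropy.Tree, labels: list[str],
                   rng: np.random.Generator) -> None:
    """Name leaves (deterministic traversal order) and draw Exp(1) lengths."""
    leaves = list(tree.leaf_node_iter())
    assert len(leaves) == len(labels)
    for leaf, label in zip(leaves, labels):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=label)
    for nd in tree.postorder_node_iter():
        if nd is not tree.seed_node:
            nd.edge.length = float(rng.exponential(1.0))
        else:
            nd.edge.length = None


def simulate_tree(
    n_taxa: int, seed: int,
    m_paleo: float | None = None,
    neo_clade_size: int | None = None, m_neo: float | None = None,
) -> tuple[IndexedTree, dict]:
    """Yule tree with optional paleo/neo branch-length edits.

    ``m_paleo`` stretches one randomly chosen tip's terminal branch
    (the relict); ``neo_clade_size``/``m_neo`` shrink the terminal
    branches of one clade of (as close as possible to) that many tips
    (the radiation). Edits are applied after base lengths are drawn, so
    the unedited tree for the same seed has identical base lengths.

    Returns (tree, annotations); annotations record ``paleo_tip`` and
    ``neo_tips`` ground truth.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if (neo_clade_size is None) != (m_neo is None):
        raise ValueError("neo_clade_size and m_neo must come together")
    if neo_clade_size is not None and not (2 <= neo_clade_size <= n_taxa - 1):
        raise ValueError("neo clade size exceeds available tips")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    _grow_yule(tree.seed_node, n_taxa, rng)
    labels = [f"t{i:03d}" for i in range(n_taxa)]
    _finalize_tree(tree, labels, rng)

    annotations: dict = {"paleo_tip": None, "neo_tips": []}
    neo_tips: set[str] = set()
    if neo_clade_size is not None:
        # internal node whose descendant tip count is nearest the request
        counts = []
        for nd in tree.postorder_internal_node_iter():
            if nd is tree.seed_node:
                continue
            tips = [lf.taxon.label for lf in nd.leaf_iter()]
            counts.append((abs(len(tips) - neo_clade_size), len(tips), nd, tips))
        counts.sort(key=lambda t: (t[0], t[1]))
        _, _, clade, tips = counts[0]
        for lf in clade.leaf_iter():
            lf.edge.length *= m_neo
        neo_tips = set(tips)
        annotations["neo_tips"] = sorted(neo_tips)
    if m_paleo is not None:
        eligible = [lf for lf in tree.leaf_node_iter()
                    if lf.taxon.label not in neo_tips]
        if not eligible:
            raise ValueError("no tip left for the paleo edit")
        relict = eligible[int(rng.integers(0, len(eligible)))]
        relict.edge.length *= m_paleo
        annotations["paleo_tip"] = relict.taxon.label
    return IndexedTree(tree), annotations


def scenario_grid(scenario: Scenario) -> Grid:
    """Grid over the scenario's abstract extent (origin at 0, meters)."""
    s = scenario.cell_size
    return build_grid((0.0, 0.0, scenario.n_cols * s, scenario.n_rows * s),
                      cell_size=s)


def simulate_landscape(
    tree: IndexedTree, scenario: Scenario, annotations: dict | None = None,
) -> tuple[PresenceMatrix, dict]:
    """Presence landscape over the scenario grid with planted structure.

    Background presences are independent Bernoulli(p_bg) per (cell,
    taxon). Planted taxa (relict, radiation) are overwritten to occupy
    exactly their block (occupancy 1 inside, absent outside); bioregion
    clades are confined to their blocks with within-block occupancy
    Bernoulli(p_within). Every taxon is guaranteed at least one cell.

    Returns (matrix over the full grid, ground-truth dict). Call
    ``matrix.drop_empty()`` before computing metrics.
    """
    annotations = annotations or {}
    rng = np.random.default_rng(scenario.seed)
    n_cells = scenario.n_rows * scenario.n_cols
    cells = [Grid.cell_id(r, c) for r in range(scenario.n_rows)
             for c in range(scenario.n_cols)]
    cell_idx = {c: i for i, c in enumerate(cells)}
    taxa = list(tree.tip_labels)
    t_idx = {t: j for j, t in enumerate(taxa)}
    X = (rng.random((n_cells, len(taxa))) < scenario.p_bg).astype(np.uint8)

    truth: dict = {"seed": scenario.seed, "paleo": None, "neo": None,
                   "bioregions": []}
    restricted_cells: dict[str, list[int]] = {}

    def confine(names: list[str], block: Block, occupancy: float) -> list[int]:
        rows = [cell_idx[c] for c in block.cell_ids()]
        for name in names:
            j = t_idx[name]
            X[:, j] = 0
            if occupancy >= 1.0:
                X[rows, j] = 1
            else:
                X[rows, j] = (rng.random(len(rows)) < occupancy).astype(np.uint8)
            restricted_cells[name] = rows
        return rows

    if scenario.paleo_block is not None:
        tip = annotations.get("paleo_tip")
        if tip is None:
            raise ValueError("paleo_block set but no paleo_tip annotation")
        rows = confine([tip], scenario.paleo_block, 1.0)
        truth["paleo"] = {"tip": tip, "cells": [cells[i] for i in rows]}
    if scenario.neo_block is not None:
        tips = annotations.get("neo_tips") or []
        if not tips:
            raise ValueError("neo_block set but no neo_tips annotation")
        rows = confine(list(tips), scenario.neo_block, 1.0)
        truth["neo"] = {"tips": list(tips), "cells": [cells[i] for i in rows]}
    if scenario.bioregion_blocks:
        for block, clade in zip(scenario.bioregion_blocks,
                                scenario.bioregion_clades):
            rows = confine(list(clade), block, scenario.p_within)
            truth["bioregions"].append(
                {"taxa": list(clade), "cells": [cells[i] for i in rows]})

    # rescue: every taxon occupies at least one cell
    for j, name in enumerate(taxa):
        if X[:, j].sum() == 0:
            pool = restricted_cells.get(name, list(range(n_cells)))
            X[pool[int(rng.integers(0, len(pool)))], j] = 1

    return PresenceMatrix(cells=cells, taxa=taxa, incidence=X), truth


def emit_occurrences(
    matrix: PresenceMatrix, grid: Grid, seed: int,
    corrupt_fraction: float = 0.0,
) -> pd.DataFrame:
    """Point records (one per presence) jittered uniformly inside cells.

    The jitter exercises half-open cell-edge binning end to end:
    rasterizing the emitted records reproduces the matrix exactly.
    ``corrupt_fraction`` appends that fraction of deliberately broken
    rows (zero latitude or "NA" longitude) for the cleaner to reject.
    Columns follow the Darwin-Core-ish defaults of the reader.
    """
    rng = np.random.default_rng(seed)
    rows_out: list[dict] = []
    r_idx, c_idx = np.nonzero(matrix.incidence)
    for i, j in zip(r_idx, c_idx):
        row, col = Grid.parse_cell_id(matrix.cells[i])
        x = grid.origin_x + (col + rng.random()) * grid.cell_size
        y = grid.origin_y + (row + rng.random()) * grid.cell_size
        rows_out.append({"species": matrix.taxa[j],
                         "decimalLatitude": repr(y), "decimalLongitude": repr(x)})
    n_corrupt = int(round(corrupt_fraction * len(rows_out)))
    for k in range(n_corrupt):
        sp = matrix.taxa[int(rng.integers(0, matrix.n_taxa))]
        if k % 2 == 0:
            rows_out.append({"species": sp, "decimalLatitude": "0",
                             "decimalLongitude": repr(float(grid.origin_x))})
        else:
            rows_out.append({"species": sp, "decimalLatitude": "NA",
                             "decimalLongitude": "NA"})
    return pd.DataFrame(rows_out,
                        columns=["species", "decimalLatitude", "decimalLongitude"])


def simulate_endemism_landscape(
    seed: int, n_taxa: int = 60, n_rows: int = 12, n_cols: int = 12,
    p_bg: float = 0.15, m_paleo: float = 20.0,
    neo_clade_size: int = 6, m_neo: float = 0.05,
    block_size: int = 2, cell_size: float = 10_000.0,
) -> tuple[IndexedTree, PresenceMatrix, dict]:
    """Landscape with one paleo-relict and one neo-radiation hotspot.

    The relict tip (terminal branch × ``m_paleo``) is confined to a
    ``block_size``² block in the lower-left corner; the radiation clade
    (terminal branches × ``m_neo``) to one in the upper-right. Everything
    else is Bernoulli(p_bg) background. Ground truth lists the planted
    tips and cells.
    """
    rng = np.random.default_rng(seed)
    tree_seed = int(rng.integers(0, 2**31 - 1))
    land_seed = int(rng.integers(0, 2**31 - 1))
    tree, ann = simulate_tree(n_taxa, tree_seed, m_paleo=m_paleo,
                              neo_clade_size=neo_clade_size, m_neo=m_neo)
    scenario = Scenario(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell_size, p_bg=p_bg,
        paleo_block=Block(0, 0, block_size, block_size),
        neo_block=Block(n_rows - block_size, n_cols - block_size,
                        block_size, block_size),
        seed=land_seed,
    )
    matrix, truth = simulate_landscape(tree, scenario, ann)
    truth["scenario"] = scenario
    return tree, matrix, truth


def simulate_bioregion_landscape(
    seed: int, n_regions: int = 3, taxa_per_clade: int = 15,
    block_rows: int = 3, n_cols: int = 10, p_bg: float = 0.02,
    p_within: float = 0.5, cell_size: float = 10_000.0,
) -> tuple[IndexedTree, PresenceMatrix, dict]:
    """Landscape of disjoint clades confined to disjoint row blocks.

    The tree is ``n_regions`` Yule clades of ``taxa_per_clade`` tips
    joined at the root; clade g is confined to the g-th horizontal band
    of ``block_rows`` rows. Ground truth includes the cell → region map.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    labels = []
    for g in range(n_regions):
        clade_root = tree.seed_node.new_child()
        if taxa_per_clade > 1:
            _grow_yule(clade_root, taxa_per_clade, rng)
        labels.extend(f"g{g}_t{i:02d}" for i in range(taxa_per_clade))
    _finalize_tree(tree, labels, rng)
    itree = IndexedTree(tree)

    blocks = tuple(Block(row0=g * block_rows, col0=0,
                         n_rows=block_rows, n_cols=n_cols)
                   for g in range(n_regions))
    clades = tuple(tuple(f"g{g}_t{i:02d}" for i in range(taxa_per_clade))
                   for g in range(n_regions))
    scenario = Scenario(
        n_rows=n_regions * block_rows, n_cols=n_cols, cell_size=cell_size,
        p_bg=p_bg, p_within=p_within,
        bioregion_blocks=blocks, bioregion_clades=clades,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    matrix, truth = simulate_landscape(itree, scenario)
    region_of_cell = {}
    for g in range(n_regions):
        for cid in blocks[g].cell_ids():
            region_of_cell[cid] = g
    truth["region_of_cell"] = region_of_cell
    truth["scenario"] = scenario
    return itree, matrix, truth
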