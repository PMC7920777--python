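"""Range-weighted phylo-Sorensen turnover and bioregion clustering.

Each branch b carries weight w_b = L_b/|R_b| (its length divided among
the cells of its range). For cells i, j with branch sets B_i, B_j:

    S_i  = Σ_{b∈B_i} w_b            (equals the cell's PE)
    W_ij = Σ_{b∈B_i ∩ B_j} w_b
    d_ij = 1 − 2·W_ij / (S_i + S_j)

d is 0 for identical lineage composition and 1 when no branch is shared.
Because branch sets include root paths, any two occupied cells share some
deep branches — but those have large ranges and hence small weights, so
the weighting downplays them naturally and no branch need be excluded.

Bioregions are obtained by average-linkage (UPGMA) clustering of the
turnover matrix, cut to a user-chosen number of clusters k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .phylotree import BranchIncidence, IndexedTree

log = logging.getLogger(__name__)

__all__ = ["TurnoverMatrix", "Bioregions", "rw_phylosor_matrix",
           "cluster_bioregions", "silhouette_by_k"]


@dataclass
class TurnoverMatrix:
    """Symmetric cells × cells range-weighted phylo-Sorensen dissimilarity."""

    cells: list[str]
    values: np.ndarray  # (n, n), zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.cells), len(self.cells)):
            raise ValueError("matrix shape does not match cell list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("turnover matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("turnover diagonal not zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("turnover entries outside [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.cells)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class Bioregions:
    """Cell → region assignment from a k-cut of the UPGMA dendrogram."""

    cells: list[str]
    labels: np.ndarray      # int region label per cell, 1..k
    linkage: np.ndarray     # scipy linkage matrix (cells in ``cells`` order)
    k: int

    def assignment(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cells, name="region")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (leaf names = cell ids)."""
        root = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.cells[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for ch in (left, right):
                bl = node.dist - ch.dist if not ch.is_leaf() else node.dist
                parts.append(f"{rec(ch)}:{bl:.6g}")
            return "(" + ",".join(parts) + ")"

        return rec(root) + ";"


def rw_phylosor_matrix(
    incidence: BranchIncidence, tree: IndexedTree,
) -> TurnoverMatrix:
    """Pairwise range-weighted phylo-Sorensen dissimilarities.

    Cells with zero total branch weight (S_i = 0, possible only with
    all-zero branch lengths) are excluded with a warning.
    """
    P = incidence.cell_branch.astype(np.float64)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 analyzable cells")
    R = incidence.range_sizes.astype(np.float64)
    w = np.where(R > 0, tree.lengths / np.maximum(R, 1.0), 0.0)
    S = P @ w                       # per-cell total weight (= PE)
    keep = S > 0
    cells = [c for c, k in zip(incidence.cells, keep) if k]
    if not keep.all():
        log.warning("%d cells with zero branch weight excluded from turnover",
                    int((~keep).sum()))
    Pk = P[keep]
    Sk = S[keep]
    W = (Pk * w) @ Pk.T             # shared weight W_ij
    denom = Sk[:, None] + Sk[None, :]
    d = 1.0 - 2.0 * W / denom
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)             # symmetrize away float noise
    return TurnoverMatrix(cells=cells, values=d)


def cluster_bioregions(turnover: TurnoverMatrix, k: int) -> Bioregions:
    """UPGMA clustering of the turnover matrix cut to exactly k regions.

    Cells are processed in lexicographic cell_id order so merge
    tie-breaking is deterministic. Region labels are 1..k.
    """
    n = len(turnover.cells)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} cells")
    order = np.argsort(np.asarray(turnover.cells, dtype=object))
    cells = [turnover.cells[i] for i in order]
    D = turnover.values[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        # maxclust can undershoot on exact-tie heights; fall back to cutting
        # at successively lower heights until k clusters appear
        heights = np.unique(Z[:, 2])[::-1]
        for h in heights:
            labels = hierarchy.fcluster(Z, t=h - 1e-12, criterion="distance")
            if len(np.unique(labels)) >= k:
                break
    return Bioregions(cells=cells, labels=labels, linkage=Z, k=k)


def silhouette_by_k(turnover: TurnoverMatrix, ks) -> pd.Series:
    """Mean silhouette width for each candidate k (an aid for choosing k;
    never auto-selects)."""
    out = {}
    D = turnover.values
    n = len(turnover.cells)
    for k in ks:
        if not (2 <= k < n):
            continue
        regions = cluster_bioregions(turnover, k)
        by_cell = dict(zip(regions.cells, regions.labels))
        labels = np.array([by_cell[c] for c in turnover.cells])
        sil = []
        for i in range(n):
            same = labels == labels[i]
            same[i] = False
            a = D[i, same].mean() if same.any() else 0.0
            b = min(D[i, labels == lab].mean()
                    for lab in np.unique(labels) if lab != labels[i])
            sil.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
        out[k] = float(np.mean(sil))
    return pd.Series(out, name="mean_silhouette")
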