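"""Indexed phylogeny, tip/matrix reconciliation, comparison tree, branch ranges.

A "branch" throughout this package is the edge above a non-root node; the
root carries no edge. Per-branch descendant tip sets and per-branch spatial
ranges (the set of cells where at least one descendant occurs) are the
building blocks of PD, PE and the range-weighted turnover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .presence import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = ["IndexedTree", "BranchIncidence", "parse_newick", "reconcile",
           "equalize_branches", "branch_incidence"]


class IndexedTree:
    """Rooted tree with branch lengths, indexed for vectorized metrics.

    Branches (non-root nodes) are enumerated in postorder. For each branch
    b the index exposes its length L_b and its descendant tip set D_b; the
    total tree length is Σ L_b.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        root = tree.seed_node
        if root.edge.length not in (None, 0, 0.0):
            log.warning("root edge length %s ignored (the root carries no edge)",
                        root.edge.length)
        self.branch_nodes = [nd for nd in tree.postorder_node_iter() if nd is not root]
        lengths = []
        n_missing = 0
        for nd in self.branch_nodes:
            L = nd.edge.length
            if L is None:
                n_missing += 1
                L = 0.0
            if L < 0:
                raise ValueError("negative branch length")
            lengths.append(float(L))
        if n_missing:
            log.warning("%d branches had no length; treated as 0", n_missing)
        self.lengths = np.array(lengths, dtype=float)
        self.tip_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        # postorder descendant tip sets: union of children, singleton at tips
        self._tip_sets: list[frozenset[str]] = []
        cache: dict[int, frozenset[str]] = {}
        for nd in self.branch_nodes:
            if nd.is_leaf():
                s = frozenset([nd.taxon.label])
            else:
                s = frozenset().union(*(cache[id(ch)] for ch in nd.child_nodes()))
            cache[id(nd)] = s
            self._tip_sets.append(s)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def branch_tip_sets(self) -> list[frozenset[str]]:
        """Descendant tip set D_b per branch, in branch (postorder) order."""
        return list(self._tip_sets)

    def branch_taxon_matrix(self, taxa: list[str]) -> np.ndarray:
        """Boolean (n_branches, n_taxa) membership: M[b, t] iff t ∈ D_b.

        ``taxa`` must cover every tip label (reconcile first).
        """
        idx = {t: i for i, t in enumerate(taxa)}
        missing = set(self.tip_labels) - set(taxa)
        if missing:
            raise ValueError(f"tips absent from taxa ordering: {sorted(missing)[:5]}")
        M = np.zeros((self.n_branches, len(taxa)), dtype=bool)
        for b, s in enumerate(self._tip_sets):
            for t in s:
                M[b, idx[t]] = True
        return M

    # -- IO / derivation -----------------------------------------------------

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def clone(self) -> "IndexedTree":
        return IndexedTree(self._tree.clone(depth=1))

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def parse_newick(path_or_string, *, is_string: bool | None = None) -> IndexedTree:
    """Parse a rooted Newick tree with branch lengths into an IndexedTree.

    Accepts a file path or (with ``is_string=True`` or a string containing
    parentheses) raw Newick text. Missing branch lengths become 0 with a
    warning; duplicate tip labels and malformed Newick are fatal.
    Internal node labels are preserved; polytomies are allowed.
    """
    data = str(path_or_string)
    if is_string is None:
        is_string = "(" in data
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    try:
        if is_string:
            tree = dendropy.Tree.get(data=data, **kwargs)
        else:
            tree = dendropy.Tree.get(path=data, **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"failed to parse Newick: {exc}") from exc
    tree.is_rooted = True
    return IndexedTree(tree)


@dataclass
class ReconcileReport:
    tips_pruned: list[str] = field(default_factory=list)
    taxa_dropped: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.tips_pruned or self.taxa_dropped)


def reconcile(
    tree: IndexedTree, matrix: PresenceMatrix,
) -> tuple[IndexedTree, PresenceMatrix, ReconcileReport]:
    """Make tree tips and matrix columns agree exactly.

    Tips absent from the matrix are pruned (unifurcations collapsed by
    summing branch lengths); matrix taxa absent from the tree are dropped.
    Idempotent; an empty intersection is fatal.
    """
    tips = set(tree.tip_labels)
    taxa = set(matrix.taxa)
    common = tips & taxa
    if not common:
        raise ValueError("tree tips and matrix taxa share no names")
    report = ReconcileReport(
        tips_pruned=sorted(tips - taxa), taxa_dropped=sorted(taxa - tips),
    )
    if report.tips_pruned:
        dtree = tree.dendropy_tree.clone(depth=1)
        keep = [tx for tx in dtree.taxon_namespace if tx.label in common]
        dtree.retain_taxa(keep)  # sums collapsed edge lengths
        dtree.purge_taxon_namespace()
        new_tree = IndexedTree(dtree)
    else:
        new_tree = tree
    if report.taxa_dropped:
        new_matrix = matrix.select_taxa([t for t in matrix.taxa if t in common])
    else:
        new_matrix = matrix
    if not report.empty:
        log.info("reconcile pruned %d tips, dropped %d matrix taxa",
                 len(report.tips_pruned), len(report.taxa_dropped))
    return new_tree, new_matrix, report


def equalize_branches(tree: IndexedTree) -> IndexedTree:
    """Comparison tree: same topology, every branch = total_length/n_branches.

    Total tree length is preserved exactly, so PD/PE ratios against this
    tree (RPD/RPE) contrast pure tree shape with expectation near 1.
    """
    if tree.n_branches < 1:
        raise ValueError("tree has no branches")
    equal = tree.total_length / tree.n_branches
    dtree = tree.dendropy_tree.clone(depth=1)
    for nd in dtree.preorder_node_iter():
        if nd is not dtree.seed_node:
            nd.edge.length = equal
    return IndexedTree(dtree)


@dataclass
class BranchIncidence:
    """Per-branch spatial ranges over the analyzable cells.

    ``cell_branch[c, b]`` is True iff cell c lies in branch b's range R_b
    (some taxon of D_b present in c); ``range_sizes[b]`` = |R_b|.
    Branch order matches ``tree.branch_nodes``; cell order matches the
    matrix.
    """

    cells: list[str]
    cell_branch: np.ndarray  # bool (n_cells, n_branches)
    range_sizes: np.ndarray  # int (n_branches,)

    def branch_range(self, b: int) -> set[str]:
        return {c for c, v in zip(self.cells, self.cell_branch[:, b]) if v}

    def branches_in_cell(self, cell_id: str) -> np.ndarray:
        return np.nonzero(self.cell_branch[self.cells.index(cell_id)])[0]


def branch_incidence(tree: IndexedTree, matrix: PresenceMatrix) -> BranchIncidence:
    """Compute branch ranges bottom-up from the presence matrix.

    R_b for a tip branch is the tip's occupied cells; for an internal
    branch it is the union of its children's ranges (equivalently, cells
    where any descendant occurs). Requires tree and matrix reconciled.
    """
    if set(tree.tip_labels) != set(matrix.taxa):
        raise ValueError("tree tips and matrix taxa differ; reconcile first")
    M = tree.branch_taxon_matrix(matrix.taxa)
    P = (matrix.incidence.astype(np.int64) @ M.T.astype(np.int64)) > 0
    return BranchIncidence(
        cells=list(matrix.cells),
        cell_branch=P,
        range_sizes=P.sum(axis=0).astype(np.int64),
    )
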