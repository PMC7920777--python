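import numpy as np
import pytest

from phylogrid import PresenceMatrix, parse_newick, reconcile, simulate_tree

FIXTURE_NEWICK = "((A:1,B:1):1,(C:2,D:2):0.5);"
FIXTURE_PAIRS = [("c1", "A"), ("c1", "B"), ("c2", "B"), ("c2", "C"),
                 ("c2", "D"), ("c3", "C"), ("c3", "D")]


@pytest.fixture
def fixture_tree():
    """4-taxon tree with hand-computable branch sums (total length 7.5)."""
    return parse_newick(FIXTURE_NEWICK)


@pytest.fixture
def fixture_matrix():
    """3-cell landscape: {A,B} | {B,C,D} | {C,D}."""
    return PresenceMatrix.from_pairs(FIXTURE_PAIRS)


@pytest.fixture
def fixture_pair(fixture_tree, fixture_matrix):
    tree, mat, _ = reconcile(fixture_tree, fixture_matrix)
    return tree, mat


def random_instance(seed, max_taxa=10, max_cells=15):
    """Small random tree + presence matrix for oracle cross-checks.

    Guarantees every taxon occupies >=1 cell and every cell holds >=1
    taxon (analyzable instance).
    """
    rng = np.random.default_rng(seed)
    n_taxa = int(rng.integers(3, max_taxa + 1))
    n_cells = int(rng.integers(2, max_cells + 1))
    tree, _ = simulate_tree(n_taxa, int(rng.integers(0, 2**31 - 1)))
    X = (rng.random((n_cells, n_taxa)) < rng.uniform(0.15, 0.6)).astype(np.uint8)
    for j in range(n_taxa):
        if X[:, j].sum() == 0:
            X[int(rng.integers(0, n_cells)), j] = 1
    for i in range(n_cells):
        if X[i].sum() == 0:
            X[i, int(rng.integers(0, n_taxa))] = 1
    cells = [f"cell{i:02d}" for i in range(n_cells)]
    return tree, PresenceMatrix(cells=cells, taxa=list(tree.tip_labels),
                                incidence=X)


def cell_taxa_map(matrix):
    """dict cell -> set of present taxa (oracle input format)."""
    return {c: matrix.taxa_in_cell(c) for c in matrix.cells}
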