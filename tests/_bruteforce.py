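"""Independent brute-force oracle for the per-cell metrics and turnover.

Deliberately written against raw Newick text with dendropy traversals,
python sets and explicit loops — no shared code with the vectorized
implementation it cross-checks.
"""

from __future__ import annotations

import dendropy


def _load(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)
    t.is_rooted = True
    return t


def _branches(tree: dendropy.Tree):
    """(length, descendant tip label set) per non-root node."""
    out = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        tips = {lf.taxon.label for lf in nd.leaf_iter()}
        out.append((float(nd.edge.length or 0.0), tips))
    return out


def total_length_brute(newick: str) -> float:
    return sum(L for L, _ in _branches(_load(newick)))


def tr_brute(cell_taxa: dict[str, set[str]]) -> dict[str, int]:
    return {c: len(taxa) for c, taxa in cell_taxa.items()}


def we_brute(cell_taxa: dict[str, set[str]]) -> dict[str, float]:
    ranges: dict[str, int] = {}
    for taxa in cell_taxa.values():
        for t in taxa:
            ranges[t] = ranges.get(t, 0) + 1
    return {c: sum(1.0 / ranges[t] for t in taxa)
            for c, taxa in cell_taxa.items()}


def pd_brute(newick: str, cell_taxa: dict[str, set[str]]) -> dict[str, float]:
    """PD as the union-of-root-paths length of each cell's taxa."""
    tree = _load(newick)
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    out = {}
    for c, taxa in cell_taxa.items():
        seen = set()
        total = 0.0
        for t in taxa:
            nd = leaf_by_label[t]
            while nd.parent_node is not None:
                if id(nd) not in seen:
                    seen.add(id(nd))
                    total += float(nd.edge.length or 0.0)
                nd = nd.parent_node
        out[c] = total
    return out


def _branch_weights(newick: str, cell_taxa: dict[str, set[str]]):
    """Per branch: (cells in its range, weight L/|range|)."""
    out = []
    for L, tips in _branches(_load(newick)):
        cells = {c for c, taxa in cell_taxa.items() if taxa & tips}
        if cells:
            out.append((cells, L / len(cells)))
    return out


def pe_brute(newick: str, cell_taxa: dict[str, set[str]]) -> dict[str, float]:
    bw = _branch_weights(newick, cell_taxa)
    return {c: sum(w for cells, w in bw if c in cells) for c in cell_taxa}


def equalized_newick_lengths(newick: str) -> str:
    """Same topology with every branch set to total/n_branches."""
    tree = _load(newick)
    nonroot = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
    total = sum(float(nd.edge.length or 0.0) for nd in nonroot)
    equal = total / len(nonroot)
    for nd in nonroot:
        nd.edge.length = equal
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def rpd_brute(newick: str, cell_taxa: dict[str, set[str]]) -> dict[str, float]:
    pd_o = pd_brute(newick, cell_taxa)
    pd_a = pd_brute(equalized_newick_lengths(newick), cell_taxa)
    return {c: pd_o[c] / pd_a[c] for c in cell_taxa}


def rpe_brute(newick: str, cell_taxa: dict[str, set[str]]) -> dict[str, float]:
    pe_o = pe_brute(newick, cell_taxa)
    pe_a = pe_brute(equalized_newick_lengths(newick), cell_taxa)
    return {c: pe_o[c] / pe_a[c] for c in cell_taxa}


def turnover_brute(newick: str, cell_taxa: dict[str, set[str]],
                   ci: str, cj: str) -> float:
    """Range-weighted phylo-Sorensen dissimilarity between two cells."""
    bw = _branch_weights(newick, cell_taxa)
    s_i = sum(w for cells, w in bw if ci in cells)
    s_j = sum(w for cells, w in bw if cj in cells)
    shared = sum(w for cells, w in bw if ci in cells and cj in cells)
    return 1.0 - 2.0 * shared / (s_i + s_j)


def branch_ranges_brute(newick: str, cell_taxa: dict[str, set[str]]):
    """List of (descendant tip set, range cell set) per non-root branch."""
    return [(tips, {c for c, taxa in cell_taxa.items() if taxa & tips})
            for _, tips in _branches(_load(newick))]
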