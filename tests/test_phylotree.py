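import numpy as np
import pytest

from phylogrid import (PresenceMatrix, branch_incidence, equalize_branches,
                       parse_newick, reconcile)

from _bruteforce import branch_ranges_brute
from conftest import cell_taxa_map, random_instance


class TestParseNewick:
    def test_fixture_tip_count_and_total_length(self, fixture_tree):
        assert sorted(fixture_tree.tip_labels) == ["A", "B", "C", "D"]
        assert fixture_tree.total_length == pytest.approx(7.5)
        assert fixture_tree.n_branches == 6

    def test_two_tip_tree(self):
        t = parse_newick("(A:1,B:2);")
        assert t.total_length == pytest.approx(3)
        assert sorted(map(set, t.branch_tip_sets()), key=sorted) == [
            {"A"}, {"B"}]

    def test_internal_label_preserved(self):
        t = parse_newick("((A:1,B:1)AB:1,C:2);")
        labels = [nd.label for nd in t.branch_nodes if not nd.is_leaf()]
        assert "AB" in labels
        assert t.total_length == pytest.approx(5)

    def test_polytomy_allowed(self):
        t = parse_newick("(A:1,B:1,C:1);")
        assert t.n_tips == 3 and t.n_branches == 3

    def test_malformed_and_duplicate_labels_fatal(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,B:1:1,C;")
        with pytest.raises(ValueError):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_file_roundtrip(self, tmp_path, fixture_tree):
        p = tmp_path / "t.nwk"
        fixture_tree.write_newick(p)
        again = parse_newick(p, is_string=False)
        assert again.total_length == pytest.approx(7.5)
        assert sorted(again.tip_labels) == sorted(fixture_tree.tip_labels)


class TestReconcile:
    def test_extra_tip_pruned_and_reported(self, fixture_tree):
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c1", "B"), ("c2", "C")])
        tree, m, report = reconcile(fixture_tree, mat)
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert report.tips_pruned == ["D"] and report.taxa_dropped == []

    def test_collapsed_unifurcation_sums_lengths(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c2", "C")])
        pruned, _, _ = reconcile(tree, mat)
        # A's path to the root collapses to a single branch of length 2
        by_tips = {frozenset(s): L for s, L in
                   zip(pruned.branch_tip_sets(), pruned.lengths)}
        assert by_tips[frozenset({"A"})] == pytest.approx(2.0)
        assert pruned.total_length == pytest.approx(4.0)

    def test_matrix_taxon_not_in_tree_dropped(self, fixture_tree):
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c1", "X")])
        _, m, report = reconcile(fixture_tree, mat)
        assert m.taxa == ["A"] and report.taxa_dropped == ["X"]

    def test_identity_and_idempotence(self, fixture_tree, fixture_matrix):
        t1, m1, rep = reconcile(fixture_tree, fixture_matrix)
        assert rep.empty
        assert t1 is fixture_tree and m1 is fixture_matrix
        t2, m2, rep2 = reconcile(t1, m1)
        assert rep2.empty and t2 is t1

    def test_empty_intersection_fatal(self, fixture_tree):
        mat = PresenceMatrix.from_pairs([("c1", "X")])
        with pytest.raises(ValueError):
            reconcile(fixture_tree, mat)


class TestEqualizeBranches:
    def test_fixture_equal_value(self, fixture_tree):
        eq = equalize_branches(fixture_tree)
        assert np.allclose(eq.lengths, 7.5 / 6)

    def test_total_length_preserved_and_topology_unchanged(self, fixture_tree):
        eq = equalize_branches(fixture_tree)
        assert abs(eq.total_length - fixture_tree.total_length) < 1e-12
        assert eq.branch_tip_sets() == fixture_tree.branch_tip_sets()

    def test_already_equal_tree_is_fixed_point(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        eq = equalize_branches(t)
        assert np.allclose(eq.lengths, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_trees_conserve_total(self, seed):
        tree, _ = random_instance(seed)[0], None
        eq = equalize_branches(tree)
        assert abs(eq.total_length - tree.total_length) < 1e-12


class TestBranchIncidence:
    def test_fixture_internal_branch_range(self, fixture_pair):
        tree, mat = fixture_pair
        inc = branch_incidence(tree, mat)
        by_tips = {frozenset(s): b for b, s in enumerate(tree.branch_tip_sets())}
        ab = by_tips[frozenset({"A", "B"})]
        assert inc.branch_range(ab) == {"c1", "c2"}
        assert inc.range_sizes[ab] == 2

    def test_tip_branch_range_is_occupancy(self, fixture_pair):
        tree, mat = fixture_pair
        inc = branch_incidence(tree, mat)
        by_tips = {frozenset(s): b for b, s in enumerate(tree.branch_tip_sets())}
        assert inc.branch_range(by_tips[frozenset({"A"})]) == {"c1"}

    def test_single_cell_landscape_all_ranges_one(self, fixture_tree):
        mat = PresenceMatrix.from_pairs(
            [("c1", t) for t in fixture_tree.tip_labels])
        inc = branch_incidence(fixture_tree, mat)
        assert (inc.range_sizes == 1).all()

    def test_mismatch_fatal(self, fixture_tree):
        mat = PresenceMatrix.from_pairs([("c1", "A")])
        with pytest.raises(ValueError):
            branch_incidence(fixture_tree, mat)

    def test_parent_range_contains_child_range(self):
        for seed in range(5):
            tree, mat = random_instance(seed, max_taxa=8, max_cells=20)
            inc = branch_incidence(tree, mat)
            node_to_b = {id(nd): b for b, nd in enumerate(tree.branch_nodes)}
            for b, nd in enumerate(tree.branch_nodes):
                parent = nd.parent_node
                if id(parent) in node_to_b:
                    pb = node_to_b[id(parent)]
                    assert (inc.cell_branch[:, pb] >= inc.cell_branch[:, b]).all()

    def test_ranges_match_bruteforce_sets(self):
        for seed in range(8):
            tree, mat = random_instance(seed, max_taxa=8, max_cells=20)
            inc = branch_incidence(tree, mat)
            got = {frozenset(s): inc.branch_range(b)
                   for b, s in enumerate(tree.branch_tip_sets())}
            for tips, cells in branch_ranges_brute(tree.as_newick(),
                                                   cell_taxa_map(mat)):
                assert got[frozenset(tips)] == cells
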