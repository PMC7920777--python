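import numpy as np
import pytest

from phylogrid import (PresenceMatrix, branch_incidence, compute_cell_metrics,
                       faith_pd, parse_newick,
                       phylo_endemism, relative_metrics, taxon_richness,
                       weighted_endemism)

from _bruteforce import (pd_brute, pe_brute, rpd_brute, rpe_brute, tr_brute,
                         we_brute)
from conftest import cell_taxa_map, random_instance


class TestFixtureValues:
    """Hand-computed values on the 4-taxon / 3-cell landscape."""

    def test_tr(self, fixture_pair):
        _, mat = fixture_pair
        assert taxon_richness(mat).tolist() == [2, 3, 2]

    def test_we(self, fixture_pair):
        _, mat = fixture_pair
        assert weighted_endemism(mat).tolist() == pytest.approx([1.5, 1.5, 1.0])

    def test_pd_pe(self, fixture_pair):
        tree, mat = fixture_pair
        inc = branch_incidence(tree, mat)
        assert faith_pd(inc, tree).tolist() == pytest.approx([3.0, 6.5, 4.5])
        assert phylo_endemism(inc, tree).tolist() == pytest.approx(
            [2.0, 3.25, 2.25])

    def test_rpd_rpe(self, fixture_pair):
        tree, mat = fixture_pair
        cm = compute_cell_metrics(mat, tree)
        assert cm["RPD"].tolist() == pytest.approx([0.8, 1.04, 1.2])
        assert cm["RPE"].loc["c1"] == pytest.approx(2.0 / 2.5)
        assert cm["RPE"].loc["c3"] == pytest.approx(2.25 / 1.875)

    def test_cell_with_all_taxa_has_pd_total_length(self, fixture_tree):
        mat = PresenceMatrix.from_pairs(
            [("c1", t) for t in fixture_tree.tip_labels] + [("c2", "A")])
        cm = compute_cell_metrics(mat, fixture_tree)
        assert cm["PD"].loc["c1"] == pytest.approx(7.5)


class TestSimpleCases:
    def test_single_taxon_cells(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c2", "A"), ("c3", "C")])
        from phylogrid import reconcile
        t, m, _ = reconcile(tree, mat)
        cm = compute_cell_metrics(m, t)
        assert (cm["TR"] == 1).all()
        # single-taxon cells score the tip's root-path length
        # (B pruned, so A's path collapses to 1+1=2)
        assert cm["PD"].tolist() == pytest.approx([2.0, 2.0, 2.0])

    def test_we_symmetry_saturated_landscape(self, fixture_tree):
        cells = [f"c{i}" for i in range(5)]
        mat = PresenceMatrix.from_pairs(
            [(c, t) for c in cells for t in fixture_tree.tip_labels])
        we = weighted_endemism(mat)
        assert np.allclose(we, 4 / 5)

    def test_endemic_taxon_contributes_one(self):
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c1", "B"), ("c2", "B")])
        we = weighted_endemism(mat)
        assert we.loc["c1"] == pytest.approx(1.0 + 0.5)

    def test_confined_flora_pe_equals_pd(self, fixture_tree):
        mat = PresenceMatrix.from_pairs(
            [("c1", t) for t in fixture_tree.tip_labels])
        inc = branch_incidence(fixture_tree, mat)
        assert phylo_endemism(inc, fixture_tree).loc["c1"] == pytest.approx(
            faith_pd(inc, fixture_tree).loc["c1"])

    def test_equal_branch_input_tree_rpd_is_one(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        mat = PresenceMatrix.from_pairs([("c1", "A"), ("c1", "B"),
                                         ("c2", "C"), ("c2", "D")])
        cm = compute_cell_metrics(mat, tree)
        assert np.allclose(cm["RPD"], 1.0)

    def test_zero_denominator_flagged_nan(self):
        import pandas as pd
        rpd, rpe = relative_metrics(
            pd.Series([1.0]), pd.Series([1.0]),
            pd.Series([0.0]), pd.Series([0.0]))
        assert np.isnan(rpd.iloc[0]) and np.isnan(rpe.iloc[0])


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_identities(self, seed):
        tree, mat = random_instance(seed)
        cm = compute_cell_metrics(mat, tree)
        assert abs(cm["PE"].sum() - tree.total_length) < 1e-10
        assert abs(cm["WE"].sum() - mat.n_taxa) < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_pe_bounded_by_pd(self, seed):
        tree, mat = random_instance(seed)
        cm = compute_cell_metrics(mat, tree)
        assert (cm["PE"] <= cm["PD"] + 1e-12).all()
        assert (cm["PE"] > 0).all() and (cm["RPD"] > 0).all()
        assert (cm["WE"] <= cm["TR"] + 1e-12).all()

    def test_permutation_invariance(self):
        tree, mat = random_instance(42)
        rng = np.random.default_rng(0)
        ci = rng.permutation(mat.n_cells)
        ti = rng.permutation(mat.n_taxa)
        permuted = PresenceMatrix(
            cells=[mat.cells[i] for i in ci],
            taxa=[mat.taxa[j] for j in ti],
            incidence=mat.incidence[np.ix_(ci, ti)])
        cm1 = compute_cell_metrics(mat, tree).sort_index()
        cm2 = compute_cell_metrics(permuted, tree).sort_index()
        assert np.allclose(cm1.to_numpy(), cm2.to_numpy())


class TestOracleEquivalence:
    """All six metrics against the independent brute-force implementation."""

    @pytest.mark.parametrize("seed", range(50))
    def test_all_metrics_match_bruteforce(self, seed):
        tree, mat = random_instance(seed, max_taxa=10, max_cells=15)
        newick = tree.as_newick()
        ctm = cell_taxa_map(mat)
        cm = compute_cell_metrics(mat, tree)
        for c in mat.cells:
            assert cm["TR"].loc[c] == tr_brute(ctm)[c]
            assert abs(cm["WE"].loc[c] - we_brute(ctm)[c]) < 1e-10
            assert abs(cm["PD"].loc[c] - pd_brute(newick, ctm)[c]) < 1e-10
            assert abs(cm["PE"].loc[c] - pe_brute(newick, ctm)[c]) < 1e-10
            assert abs(cm["RPD"].loc[c] - rpd_brute(newick, ctm)[c]) < 1e-10
            assert abs(cm["RPE"].loc[c] - rpe_brute(newick, ctm)[c]) < 1e-10
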