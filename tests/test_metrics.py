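import dendropy
import numpy as np
import pytest

from phyloendemix.grid import CommunityMatrix
from phyloendemix.metrics import (
    branch_incidence,
    cell_metrics,
    corrected_weighted_endemism,
    make_comparison_tree,
    phylogenetic_endemism,
    relative_phylogenetic_endemism,
    richness,
    weighted_endemism,
)

from conftest import brute_force_pe, random_instance


def matrix_from(presence, endemic=None):
    presence = np.asarray(presence, dtype=np.uint8)
    n_cells, n_taxa = presence.shape
    endemic = (np.zeros(n_taxa, bool) if endemic is None
               else np.asarray(endemic, bool))
    return CommunityMatrix(
        presence=presence, cell_ids=np.arange(n_cells),
        taxon_ids=[f"t{j}" for j in range(n_taxa)], endemic_mask=endemic)


def get_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


class TestRichnessAndWE:
    def test_sr_er(self):
        m = matrix_from([[0, 1], [1, 1]], endemic=[False, True])
        np.testing.assert_array_equal(richness(m), [1, 2])
        np.testing.assert_array_equal(richness(m, endemic_only=True), [1, 1])

    def test_er_equals_sr_when_all_endemic(self):
        m = matrix_from([[1, 1], [1, 0]], endemic=[True, True])
        np.testing.assert_array_equal(m.er, m.sr)

    def test_we_single_cell_endemic(self):
        m = matrix_from([[1]])
        assert weighted_endemism(m)[0] == pytest.approx(1.0)

    def test_we_sums_inverse_ranges(self):
        # cell 0 holds A (range 2) and B (range 1): WE = 1/2 + 1
        m = matrix_from([[1, 1], [1, 0]])
        assert weighted_endemism(m)[0] == pytest.approx(1.5)

    def test_we_conservation_identity(self):
        for seed in range(20):
            _, m = random_instance(seed)
            assert weighted_endemism(m).sum() == pytest.approx(
                m.n_taxa, abs=1e-9)

    def test_empty_selection_raises(self):
        m = matrix_from([[1]], endemic=[False])
        with pytest.raises(ValueError):
            weighted_endemism(m, endemic_only=True)

    def test_range_scale(self):
        m = matrix_from([[1, 1], [1, 0]])
        np.testing.assert_allclose(
            weighted_endemism(m, range_scale=25.0),
            weighted_endemism(m) / 25.0)


class TestCWE:
    def test_ratio(self):
        np.testing.assert_allclose(
            corrected_weighted_endemism(np.array([1.5]), np.array([2.0])),
            [0.75])

    def test_upper_bound_single_cell_taxa(self):
        m = matrix_from([[1, 1, 0], [0, 0, 1]])
        cwe = corrected_weighted_endemism(weighted_endemism(m), m.sr)
        np.testing.assert_allclose(cwe, 1.0)

    def test_uniform_range_closed_form(self):
        # every taxon occupies the same 3 cells: CWE = 1/3 everywhere
        m = matrix_from(np.ones((3, 4)))
        cwe = corrected_weighted_endemism(weighted_endemism(m), m.sr)
        np.testing.assert_allclose(cwe, 1.0 / 3.0)

    def test_zero_richness_excluded_not_propagated(self):
        out = corrected_weighted_endemism(np.array([1.0, 0.0]),
                                          np.array([2.0, 0.0]))
        assert out[0] == 0.5 and np.isnan(out[1])

    def test_bounds_on_random_instances(self):
        for seed in range(10):
            _, m = random_instance(seed)
            we = weighted_endemism(m)
            cwe = corrected_weighted_endemism(we, m.sr)
            assert (we <= m.sr + 1e-12).all()
            assert ((cwe > 0) & (cwe <= 1 + 1e-12)).all()


class TestBranchIncidence:
    def test_cherry_root_branch_spans_both_cells(self):
        tree = get_tree("(A:1,B:1):1;")
        m = CommunityMatrix(
            presence=np.array([[1, 0], [0, 1]], dtype=np.uint8),
            cell_ids=np.arange(2), taxon_ids=["A", "B"],
            endemic_mask=np.zeros(2, bool))
        inc = branch_incidence(tree, m)
        # one branch (the root) must span both cells with range 2
        spans = inc.incidence.all(axis=0)
        assert spans.any()
        assert set(inc.branch_ranges.tolist()) <= {1, 2}

    def test_ubiquitous_taxon_pendant_range(self):
        tree = get_tree("(A:1,B:1):1;")
        m = CommunityMatrix(
            presence=np.array([[1, 1], [1, 0], [1, 0]], dtype=np.uint8),
            cell_ids=np.arange(3), taxon_ids=["A", "B"],
            endemic_mask=np.zeros(2, bool))
        inc = branch_incidence(tree, m)
        a_col = inc.taxon_ids.index("A")
        pendant_a = [i for i in range(len(inc.lengths))
                     if inc.branch_tips[i].sum() == 1
                     and inc.branch_tips[i, a_col]][0]
        assert inc.branch_ranges[pendant_a] == 3

    def test_missing_taxon_raises_with_names(self):
        tree = get_tree("(A:1,B:1):1;")
        m = CommunityMatrix(
            presence=np.array([[1, 1]], dtype=np.uint8),
            cell_ids=np.arange(1), taxon_ids=["A", "Z"],
            endemic_mask=np.zeros(2, bool))
        with pytest.raises(ValueError, match="Z"):
            branch_incidence(tree, m)


class TestPE:
    def test_single_taxon_single_cell(self):
        tree = get_tree("(A:2,B:1):1;")
        m = CommunityMatrix(
            presence=np.array([[1]], dtype=np.uint8),
            cell_ids=np.arange(1), taxon_ids=["A"],
            endemic_mask=np.zeros(1, bool))
        # B absent from the matrix is pruned; every remaining branch has
        # range 1, so PE equals the retained tree length (A's pendant
        # merged with its root path)
        inc = branch_incidence(tree, m)
        pe = phylogenetic_endemism(inc)
        assert pe[0] == pytest.approx(inc.lengths.sum())
        assert pe[0] >= 2.0

    def test_pe_conservation_identity(self):
        for seed in range(20):
            tree, m = random_instance(seed)
            inc = branch_incidence(tree, m)
            assert phylogenetic_endemism(inc).sum() == pytest.approx(
                inc.lengths.sum(), abs=1e-9)

    def test_star_tree_symmetry(self):
        tree = get_tree("(A:1,B:1,C:1);")
        m = CommunityMatrix(
            presence=np.eye(3, dtype=np.uint8),
            cell_ids=np.arange(3), taxon_ids=["A", "B", "C"],
            endemic_mask=np.zeros(3, bool))
        pe = phylogenetic_endemism(branch_incidence(tree, m))
        assert np.allclose(pe, pe[0])

    def test_matches_brute_force_oracle(self):
        for seed in range(25):
            tree, m = random_instance(seed, max_tips=15, max_cells=12)
            inc = branch_incidence(tree, m)
            np.testing.assert_allclose(
                phylogenetic_endemism(inc), brute_force_pe(tree, m),
                atol=1e-12)

    def test_monotone_in_new_single_cell_taxon(self):
        tree = get_tree("((A:1,B:1):1,(C:1,N:1):1);")
        base = CommunityMatrix(
            presence=np.array([[1, 1, 0], [0, 1, 1]], dtype=np.uint8),
            cell_ids=np.arange(2), taxon_ids=["A", "B", "C"],
            endemic_mask=np.zeros(3, bool))
        plus = CommunityMatrix(
            presence=np.array([[1, 1, 0, 1], [0, 1, 1, 0]], dtype=np.uint8),
            cell_ids=np.arange(2), taxon_ids=["A", "B", "C", "N"],
            endemic_mask=np.zeros(4, bool))
        pe0 = phylogenetic_endemism(branch_incidence(tree, base))
        pe1 = phylogenetic_endemism(branch_incidence(tree, plus))
        we0 = weighted_endemism(base)
        we1 = weighted_endemism(plus)
        assert pe1[0] > pe0[0] and we1[0] > we0[0]


class TestComparisonTreeAndRPE:
    def test_lengths_equalized_preserving_total(self):
        tree = get_tree("(A:1,(B:2,C:3):0);")
        out = make_comparison_tree(tree)
        lens = [e.length for e in out.preorder_edge_iter()
                if e.length is not None]
        assert np.allclose(lens, 6.0 / 4.0)
        assert out.length() == pytest.approx(tree.length(), abs=1e-12)

    def test_equal_length_tree_is_fixed_point(self):
        tree = get_tree("((A:1,B:1):1,C:1);")
        out = make_comparison_tree(tree)
        assert out.length() == pytest.approx(tree.length(), abs=1e-12)
        assert all(e.length == pytest.approx(1.0)
                   for e in out.preorder_edge_iter() if e.length is not None)

    def test_zero_length_tree_raises(self):
        with pytest.raises(ValueError):
            make_comparison_tree(get_tree("(A:0,B:0):0;"))

    def test_rpe_is_one_on_equal_length_tree(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        m = CommunityMatrix(
            presence=np.array(
                [[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 1, 1]], dtype=np.uint8),
            cell_ids=np.arange(3), taxon_ids=["A", "B", "C", "D"],
            endemic_mask=np.zeros(4, bool))
        inc = branch_incidence(tree, m)
        inc_alt = branch_incidence(make_comparison_tree(tree), m)
        rpe = relative_phylogenetic_endemism(
            phylogenetic_endemism(inc), phylogenetic_endemism(inc_alt))
        np.testing.assert_allclose(rpe, 1.0, atol=1e-12)

    def test_long_restricted_branch_raises_rpe(self):
        tree = get_tree("((A:10,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        m = CommunityMatrix(
            presence=np.array(
                [[1, 0, 0, 0], [0, 1, 1, 1], [0, 1, 1, 1]], dtype=np.uint8),
            cell_ids=np.arange(3), taxon_ids=["A", "B", "C", "D"],
            endemic_mask=np.zeros(4, bool))
        inc = branch_incidence(tree, m)
        inc_alt = branch_incidence(make_comparison_tree(tree), m)
        rpe = relative_phylogenetic_endemism(
            phylogenetic_endemism(inc), phylogenetic_endemism(inc_alt))
        assert rpe[0] > 1.0 and rpe[1] < 1.0

    def test_rpe_invariant_to_global_length_scaling(self):
        tree, m = random_instance(5, max_tips=10, max_cells=8)
        def rpe_of(t):
            inc = branch_incidence(t, m)
            alt = branch_incidence(make_comparison_tree(t), m)
            return relative_phylogenetic_endemism(
                phylogenetic_endemism(inc), phylogenetic_endemism(alt))
        base = rpe_of(tree)
        scaled = tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 7.5
        np.testing.assert_allclose(rpe_of(scaled), base, atol=1e-9)


class TestCellMetricsTable:
    def test_columns_and_nan_pattern(self):
        tree = get_tree("((A:1,B:1):1,C:2);")
        m = CommunityMatrix(
            presence=np.array([[1, 1, 0], [0, 0, 1]], dtype=np.uint8),
            cell_ids=np.arange(2), taxon_ids=["A", "B", "C"],
            endemic_mask=np.array([True, False, False]))
        tab = cell_metrics(m, tree).set_index("cell")
        assert {"SR", "ER", "WE", "CWE_NAT", "WE_END", "CWE_END",
                "PE_obs", "PE_alt", "RPE"} <= set(tab.columns)
        assert tab.loc[0, "ER"] == 1
        assert np.isnan(tab.loc[1, "CWE_END"])  # no endemics in cell 1
        assert tab.loc[0, "PE_obs"] > 0
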