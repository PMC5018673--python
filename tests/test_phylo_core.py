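import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amaztraits.errors import NewickParseError, TreeValidationError
from amaztraits.phylo_core import (
    is_ultrametric,
    lambda_transform,
    parse_newick,
    prune_to_taxa,
    resolve_polytomies,
    vcv_matrix,
    write_newick,
)


class TestParseNewick:
    def test_three_taxon_structure(self, three_taxon_tree):
        t = three_taxon_tree
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert len(t.internal_nodes) == 2
        depths = t.node_depths()
        assert all(depths[tip] == pytest.approx(2.0) for tip in t.tips)

    @pytest.mark.parametrize(
        "bad",
        ["((A:1.0,B:1.0):1.0,C:2.0;", "((A:1,B:1):1,C:2))", "(A:1"],
    )
    def test_malformed_raises_with_offset(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeValidationError, match="branch length"):
            parse_newick("((A:1,B):1,C:2);")

    def test_quoted_labels_and_comments(self):
        t = parse_newick("((A:1,'B b':1):1,C:2)[a comment];")
        assert "B b" in t.tip_labels


class TestNewickRoundTrip:
    def test_three_taxon_round_trip(self, three_taxon_tree):
        back = parse_newick(write_newick(three_taxon_tree))
        assert back.tip_labels == three_taxon_tree.tip_labels
        np.testing.assert_allclose(
            vcv_matrix(back).matrix, vcv_matrix(three_taxon_tree).matrix
        )

    def test_zero_length_branches_survive(self):
        t = resolve_polytomies(parse_newick("(A:1,B:1,C:1);"), seed=0)
        back = parse_newick(write_newick(t))
        np.testing.assert_allclose(vcv_matrix(back).matrix, vcv_matrix(t).matrix)

    def test_simulated_tree_distance_matrix_preserved(self, tree_factory):
        t = tree_factory(100, seed=5)
        back = parse_newick(write_newick(t))
        assert back.tip_labels == t.tip_labels
        np.testing.assert_allclose(
            vcv_matrix(back).matrix, vcv_matrix(t).matrix, rtol=0, atol=0
        )


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self, three_taxon_tree):
        r = resolve_polytomies(three_taxon_tree, seed=1)
        assert write_newick(r) == write_newick(three_taxon_tree)

    def test_trifurcation_distances_preserved(self):
        t = parse_newick("(A:1,B:1,C:1);")
        r = resolve_polytomies(t, seed=0)
        assert r.is_binary()
        # pairwise path length = 2 for every pair, diag 1, off-diag unchanged
        C = vcv_matrix(r).matrix
        d = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
        np.testing.assert_allclose(d[~np.eye(3, dtype=bool)], 2.0)

    def test_covariance_identical_on_multifurcating_tree(self, tree_factory):
        t = tree_factory(50, seed=9)
        # collapse ten internal branches into polytomies
        internal = [n for n in t.internal_nodes if n.parent is not None][:10]
        for node in internal:
            parent = node.parent
            for c in node.children:
                c.length += node.length
                c.parent = parent
            parent.children.remove(node)
            parent.children.extend(node.children)
        collapsed = type(t)(t.root, validate=False)
        assert not collapsed.is_binary()
        r = resolve_polytomies(collapsed, seed=3)
        assert r.is_binary()
        Ca = vcv_matrix(collapsed)
        Cb = vcv_matrix(r)
        assert Ca.tip_order == Cb.tip_order
        np.testing.assert_allclose(Ca.matrix, Cb.matrix, atol=1e-12)

    def test_deterministic_in_seed(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert write_newick(resolve_polytomies(t, 7)) == write_newick(
            resolve_polytomies(t, 7)
        )


class TestVcvMatrix:
    def test_three_taxon_hand_values(self, three_taxon_tree):
        C = vcv_matrix(three_taxon_tree)
        expected = {"A": {"A": 2, "B": 1, "C": 0}, "B": {"B": 2, "C": 0}, "C": {"C": 2}}
        idx = {l: i for i, l in enumerate(C.tip_order)}
        for a, row in expected.items():
            for b, v in row.items():
                assert C.matrix[idx[a], idx[b]] == pytest.approx(v)

    def test_star_tree_no_shared_history(self, star_tree):
        C = vcv_matrix(star_tree).matrix
        assert np.all(np.diag(C) == 1.0)
        assert np.all(C[~np.eye(4, dtype=bool)] == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_psd_on_random_trees(self, tree_factory, seed):
        C = vcv_matrix(tree_factory(40, seed=seed)).matrix
        np.testing.assert_allclose(C, C.T)
        eig = np.linalg.eigvalsh(C)
        assert eig.min() >= -1e-9 * np.trace(C)

    def test_ultrametric_tree_constant_diagonal(self, tree_factory):
        C = vcv_matrix(tree_factory(60, seed=2)).matrix
        assert np.ptp(np.diag(C)) < 1e-9 * np.diag(C).max()


class TestLambdaTransform:
    def test_identity_at_one_and_diagonal_at_zero(self, three_taxon_tree):
        C = vcv_matrix(three_taxon_tree)
        np.testing.assert_allclose(lambda_transform(C, 1.0).matrix, C.matrix)
        C0 = lambda_transform(C, 0.0).matrix
        np.testing.assert_allclose(C0, np.diag(np.diag(C.matrix)))

    def test_half_scales_off_diagonals(self, three_taxon_tree):
        C = vcv_matrix(three_taxon_tree)
        Ch = lambda_transform(C, 0.5)
        idx = {l: i for i, l in enumerate(C.tip_order)}
        assert Ch.matrix[idx["A"], idx["B"]] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(Ch.matrix), np.diag(C.matrix))

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range_rejected(self, three_taxon_tree, lam):
        with pytest.raises(ValueError):
            lambda_transform(vcv_matrix(three_taxon_tree), lam)

    @given(
        lam1=st.floats(0, 1, allow_nan=False),
        lam2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_composition_multiplies_lambdas(self, lam1, lam2):
        C = vcv_matrix(parse_newick("((A:1.0,B:1.0):1.0,C:2.0);"))
        twice = lambda_transform(lambda_transform(C, lam1), lam2)
        once = lambda_transform(C, lam1 * lam2)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-12)


class TestPruneAndUltrametric:
    def test_prune_preserves_covariance_submatrix(self, tree_factory):
        t = tree_factory(30, seed=4)
        keep = t.tip_labels[::3]
        C_full = vcv_matrix(t)
        pruned = prune_to_taxa(t, keep)
        C_sub = C_full.submatrix(pruned.tip_labels)
        np.testing.assert_allclose(vcv_matrix(pruned).matrix, C_sub.matrix, atol=1e-12)

    def test_ultrametric_judgement(self, three_taxon_tree):
        assert is_ultrametric(three_taxon_tree)
        assert not is_ultrametric(parse_newick("(A:1,B:2);"), rel_tol=1e-6)

    def test_tolerance_absorbs_tiny_perturbation(self, tree_factory):
        t = tree_factory(20, seed=1)
        t.tips[0].length += 1e-12
        assert is_ultrametric(t, rel_tol=1e-8)
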