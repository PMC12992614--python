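import numpy as np
import networkx as nx
import pandas as pd
import pytest

from phylodisp import trees as ph
from phylodisp.simulate import simulate_tree


def brute_force_patristic(tree):
    """Independent path-walk oracle: shortest weighted paths on the tree graph."""
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = nx.shortest_path_length(g, leaves[a], leaves[b], weight="weight")
            out.loc[a, b] = out.loc[b, a] = d
    return out


class TestReadTrees:
    def test_single_tree(self):
        trees = ph.read_trees("((A:1,B:1):1,C:2);")
        assert len(trees) == 1
        assert sorted(l.taxon.label for l in trees[0].leaf_node_iter()) == ["A", "B", "C"]

    def test_multiple_identical_trees(self):
        trees = ph.read_trees("((A:1,B:1):1,C:2);\n((A:1,B:1):1,C:2);")
        assert len(trees) == 2

    def test_malformed_names_tree_index(self):
        with pytest.raises(ph.TreeParseError, match="tree 1"):
            ph.read_trees("((A:1,B:1")

    def test_single_leaf_rejected(self):
        with pytest.raises(ph.TreeParseError, match="fewer than 2"):
            ph.read_trees("(A:1);")

    def test_leaf_set_mismatch_warns_and_intersects(self):
        with pytest.warns(UserWarning, match="common leaves"):
            trees = ph.read_trees("((A:1,B:1):1,C:2);((A:1,B:1):1,D:2);")
        for t in trees:
            assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["A", "B"]


class TestPatristic:
    def test_two_leaf_path(self):
        d = ph.patristic_matrix(ph.read_trees("(A:1,B:1);")[0])
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_three_leaf_paths(self, three_leaf_tree):
        d = ph.patristic_matrix(three_leaf_tree)
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["B", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_brute_force_on_random_tree(self):
        tree, _ = simulate_tree(10, 1, 1.0, seed=5)
        d = ph.patristic_matrix(tree)
        oracle = brute_force_patristic(tree)
        np.testing.assert_allclose(
            d.to_numpy(), oracle.loc[d.index, d.columns].to_numpy(), atol=1e-10
        )

    def test_missing_branch_length_errors(self):
        tree = ph.read_trees("((A:1,B),C:2);")[0]
        with pytest.raises(ValueError, match="missing branch length"):
            ph.patristic_matrix(tree)


class TestMeanPatristic:
    def test_single_tree_is_identity(self, three_leaf_tree):
        d1 = ph.patristic_matrix(three_leaf_tree)
        dm = ph.mean_patristic([three_leaf_tree])
        np.testing.assert_allclose(dm.to_numpy(), d1.to_numpy())

    def test_two_trees_average(self):
        trees = ph.read_trees("(A:1,B:1);(A:2,B:2);")
        dm = ph.mean_patristic(trees)
        assert dm.loc["A", "B"] == pytest.approx(3.0)

    def test_five_trees_match_elementwise_mean(self):
        trees = [simulate_tree(8, 1, 1.0, seed=s)[0] for s in range(5)]
        # same label set by construction
        dm = ph.mean_patristic(trees)
        stack = np.stack([ph.patristic_matrix(t).loc[dm.index, dm.columns].to_numpy()
                          for t in trees])
        np.testing.assert_allclose(dm.to_numpy(), stack.mean(axis=0), atol=1e-12)


def _quartet_residual(d6, split):
    """NNLS residual of a fixed 4-leaf topology, pendant edges + one internal."""
    from scipy.optimize import nnls

    leaves = ["A", "B", "C", "D"]
    pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
    rows = []
    for x, y in pairs:
        row = [float(x == l or y == l) for l in leaves]
        crosses = (x in split) != (y in split)
        row.append(float(crosses))
        rows.append(row)
    sol, res = nnls(np.array(rows), d6)
    return res ** 2


class TestConsensus:
    def test_additive_matrix_recovered_exactly(self):
        tree, _ = simulate_tree(7, 1, 1.0, seed=9)
        d = ph.patristic_matrix(tree)
        fitted = ph.patristic_matrix(ph.consensus_tree(d))
        np.testing.assert_allclose(
            fitted.loc[d.index, d.columns].to_numpy(), d.to_numpy(), atol=1e-8
        )

    def test_conflicting_trees_nonnegative_lengths(self):
        trees = ph.read_trees(
            "((A:1,B:1):1,(C:1,D:1):1);((A:1,C:1):1,(B:1,D:1):1);"
        )
        dm = ph.mean_patristic(trees)
        cons = ph.consensus_tree(dm)
        for e in cons.preorder_edge_iter():
            if e.tail_node is not None:
                assert e.length >= 0

    def test_noisy_additive_beats_generating_topology(self, rng):
        # build additive distances on the AB|CD quartet, perturb, and check the
        # consensus residual does not exceed the generating topology's refit
        labels = ["A", "B", "C", "D"]
        base = ph.patristic_matrix(
            ph.read_trees("((A:1.0,B:1.4):0.8,(C:1.2,D:0.9):0.6);")[0]
        ).loc[labels, labels]
        noise = rng.normal(0, 0.01, size=(4, 4))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        noisy = pd.DataFrame(np.abs(base.to_numpy() + noise), index=labels, columns=labels)
        cons = ph.consensus_tree(noisy)
        fitted = ph.patristic_matrix(cons).loc[labels, labels].to_numpy()
        resid = ((fitted - noisy.to_numpy()) ** 2)[np.triu_indices(4, 1)].sum()
        d6 = noisy.to_numpy()[np.triu_indices(4, 1)]
        oracle = _quartet_residual(d6, {"A", "B"})
        assert resid <= oracle + 1e-8

    def test_invalid_matrix_rejected(self):
        bad = pd.DataFrame([[0, 1, 2], [1, 0, 3], [2, 4, 0]],
                           index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            ph.consensus_tree(bad)


class TestPhyloVcv:
    def test_three_leaf_shared_paths(self, three_leaf_tree):
        C = ph.phylo_vcv(three_leaf_tree).matrix
        assert C.loc["A", "A"] == pytest.approx(2.0)
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)
        assert C.loc["C", "C"] == pytest.approx(2.0)

    def test_correlation_unit_diagonal(self):
        tree, _ = simulate_tree(12, 1, 1.0, seed=3)
        cov = ph.phylo_vcv(tree, correlation=True)
        np.testing.assert_allclose(np.diag(cov.values()), 1.0, atol=1e-10)

    def test_positive_semidefinite(self):
        tree, _ = simulate_tree(12, 1, 1.0, seed=4)
        C = ph.phylo_vcv(tree).values()
        assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_vcv_patristic_identity(self):
        # d(i,j) = C_ii + C_jj - 2 C_ij, also on a non-ultrametric tree
        for nwk in ["((A:1,B:1):1,C:2);", "((A:0.5,B:2.0):1,(C:0.3,D:1.1):0.4);"]:
            tree = ph.read_trees(nwk)[0]
            C = ph.phylo_vcv(tree).matrix
            d = ph.patristic_matrix(tree)
            dv = np.diag(C.to_numpy())
            ident = dv[:, None] + dv[None, :] - 2 * C.to_numpy()
            np.testing.assert_allclose(ident, d.to_numpy(), atol=1e-10)

    def test_unrooted_tree_rejected(self):
        tree = ph.read_trees("(A:1,B:1,C:1,D:1);")[0]
        with pytest.raises(ValueError, match="unrooted"):
            ph.phylo_vcv(tree)


class TestLambdaTransform:
    def test_identity_and_diagonal(self, three_leaf_tree):
        cov = ph.phylo_vcv(three_leaf_tree)
        np.testing.assert_allclose(
            ph.lambda_transform(cov, 1.0).values(), cov.values()
        )
        off = ph.lambda_transform(cov, 0.0).values()
        assert np.allclose(off, np.diag(np.diag(off)))

    def test_half_scaling(self, three_leaf_tree):
        cov = ph.phylo_vcv(three_leaf_tree)
        assert ph.lambda_transform(cov, 0.5).matrix.loc["A", "B"] == pytest.approx(0.5)

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_preserves_psd(self, lam):
        tree, _ = simulate_tree(10, 1, 1.0, seed=8)
        cov = ph.phylo_vcv(tree)
        assert np.linalg.eigvalsh(ph.lambda_transform(cov, lam).values()).min() >= -1e-10

    def test_out_of_range_rejected(self, three_leaf_tree):
        cov = ph.phylo_vcv(three_leaf_tree)
        with pytest.raises(ValueError):
            ph.lambda_transform(cov, 1.5)
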