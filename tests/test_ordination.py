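"""Ordination primitives against independent oracles and closed forms."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from rlqspace.errors import DegenerateInputError, ValidationError
from rlqspace.ordination import (
    correspondence_analysis,
    gower_distance,
    patristic_distance,
    pca,
    pcoa,
    upgma_dendrogram,
)
from conftest import random_abundance_table


class TestCorrespondenceAnalysis:
    def test_block_diagonal_table_has_unit_eigenvalue(self):
        L = pd.DataFrame([[10.0, 0.0], [0.0, 10.0]], index=list("ab"),
                         columns=list("xy"))
        res = correspondence_analysis(L)
        assert res.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)

    def test_independence_table_has_zero_inertia(self):
        r = np.array([0.2, 0.3, 0.5])
        c = np.array([0.6, 0.4])
        L = pd.DataFrame(np.outer(r, c) * 100)
        res = correspondence_analysis(L)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert len(res.eigenvalues) == 0 or np.all(res.eigenvalues < 1e-12)

    def test_total_inertia_equals_chi2_over_n(self, rng):
        L = random_abundance_table(rng, 4, 3) + 1.0  # avoid zero cells for chi2
        chi2 = chi2_contingency(L.values, correction=False)[0]
        res = correspondence_analysis(L)
        assert res.total_inertia == pytest.approx(chi2 / L.values.sum(), rel=1e-9)

    def test_transition_formula_links_row_and_col_scores(self, rng):
        L = random_abundance_table(rng, 6, 5)
        res = correspondence_analysis(L)
        P = L.values / L.values.sum()
        c = P.sum(axis=0)
        lam = np.sqrt(res.eigenvalues)
        # col principal = weighted average of row principal / sqrt(eigenvalue)
        G = (P / c).T @ res.row_scores.values / lam
        np.testing.assert_allclose(G, res.col_scores.values, atol=1e-9)

    def test_zero_margin_raises_naming_the_row(self):
        L = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(DegenerateInputError, match="empty"):
            correspondence_analysis(L)


class TestPCA:
    def test_perfectly_correlated_pair_gives_eigenvalues_2_0(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        res = pca(X)
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-9)

    def test_uniform_weights_match_correlation_matrix_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        res = pca(X)
        C = np.corrcoef(X.values, rowvar=False)
        # population-sd standardization: same correlation matrix
        expected = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-9)

    def test_eigenvalues_sum_to_number_of_variables(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 6)))
        w = rng.random(25)
        res = pca(X, row_weights=w)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)

    def test_zero_variance_variable_named_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateInputError, match="flat"):
            pca(X)


class TestGower:
    def test_identical_rows_have_zero_distance(self):
        tr = pd.DataFrame([[1.0, 5.0], [1.0, 5.0], [3.0, 9.0]],
                          index=list("abc"))
        D = gower_distance(tr)
        assert D["a", "b"] == 0.0

    def test_range_endpoints_have_distance_one(self):
        tr = pd.DataFrame({"t": [0.0, 10.0]}, index=list("ab"))
        D = gower_distance(tr)
        assert D["a", "b"] == pytest.approx(1.0)

    def test_matches_hand_computation_with_missing_value(self):
        # species c missing trait u: pair (a,c) averages over trait v only
        tr = pd.DataFrame(
            {"u": [0.0, 4.0, np.nan], "v": [0.0, 1.0, 2.0]}, index=list("abc")
        )
        D = gower_distance(tr)
        assert D["a", "b"] == pytest.approx((4 / 4 + 1 / 2) / 2)
        assert D["a", "c"] == pytest.approx(2 / 2 / 1)
        assert D["b", "c"] == pytest.approx(1 / 2 / 1)

    def test_no_shared_trait_pair_is_an_error(self):
        tr = pd.DataFrame(
            {"u": [1.0, np.nan, 0.0], "v": [np.nan, 1.0, 0.0]}, index=list("abc")
        )
        with pytest.raises(ValidationError, match="'a'.*'b'"):
            gower_distance(tr)


class TestPatristic:
    def test_two_tip_depth_one_tree(self):
        tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
        D = patristic_distance(tree)
        assert D["a", "b"] == pytest.approx(2.0)

    def test_sister_tips_at_depth_d(self):
        tree = dendropy.Tree.get(data="((a:0.3,b:0.3):0.7,c:1);", schema="newick")
        D = patristic_distance(tree)
        assert D["a", "b"] == pytest.approx(0.6)
        assert D["a", "c"] == pytest.approx(2.0)

    def test_matches_graph_shortest_path_oracle(self):
        import networkx as nx

        tree = dendropy.Tree.get(
            data="((a:0.1,b:0.4):0.2,(c:0.3,(d:0.2,e:0.5):0.1):0.6);",
            schema="newick",
        )
        G = nx.Graph()
        for i, edge in enumerate(tree.preorder_edge_iter()):
            if edge.tail_node is None:
                continue
            head = edge.head_node.taxon.label if edge.head_node.taxon else f"n{i}"
            edge.head_node.label = head
            tail = edge.tail_node.label or "root"
            edge.tail_node.label = tail
            G.add_edge(tail, head, weight=edge.length)
        D = patristic_distance(tree)
        for a in "abcde":
            for b in "abcde":
                if a < b:
                    sp = nx.shortest_path_length(G, a, b, weight="weight")
                    assert D[a, b] == pytest.approx(sp, abs=1e-12)

    def test_missing_branch_length_raises(self):
        tree = dendropy.Tree.get(data="(a:1,(b,c:1):1);", schema="newick")
        with pytest.raises(ValidationError, match="branch length"):
            patristic_distance(tree)


class TestPCoA:
    def test_points_on_a_line_are_recovered(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=list("abc"))
        res = pcoa(D)
        coords = res.row_scores.values
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(rec, D.data, atol=1e-9)
        assert not res.extras["cailliez_corrected"]

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        D = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_non_euclidean_quadruple_triggers_cailliez(self):
        # equilateral triangle side 2 with a center at distance 1 to each
        # vertex: circumradius 2/sqrt(3) > 1, not Euclidean-embeddable
        D = np.full((4, 4), 2.0)
        D[3, :3] = D[:3, 3] = 1.0
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(D, ids=list("abcd"))
        res = pcoa(dm)
        assert res.extras["cailliez_corrected"]
        assert res.extras["cailliez_constant"] > 0
        coords = res.row_scores.values
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(
            rec, res.extras["corrected_distances"], atol=1e-6
        )

    def test_matches_skbio_on_euclidean_input(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(7)])
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm)
        np.testing.assert_allclose(
            ours.eigenvalues[:4],
            np.sort(theirs.eigvals.values)[::-1][:4],
            atol=1e-8,
        )

    def test_ultrametric_cophenetic_distances_are_euclidean(self, rng):
        from rlqspace.synthetic import simulate_phylogeny

        tree = simulate_phylogeny(12, seed=5)
        D = patristic_distance(tree)
        res = pcoa(D)
        tol = 1e-8 * np.abs(res.eigenvalues).max()
        assert res.eigenvalues.min() >= -tol
        assert not res.extras["cailliez_corrected"]


class TestUPGMA:
    def test_two_species_merge_at_half_distance(self):
        D = DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), ids=list("ab"))
        dendro = upgma_dendrogram(D)
        assert dendro.linkage[0, 2] == pytest.approx(3.0)  # cophenetic d
        assert dendro.cophenetic()["a", "b"] == pytest.approx(3.0)
        assert "(" in dendro.to_newick()

    def test_three_species_hand_worked(self):
        D = DistanceMatrix(
            np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float), ids=list("abc")
        )
        dendro = upgma_dendrogram(D)
        coph = dendro.cophenetic()
        assert coph["a", "b"] == pytest.approx(1.0)  # merged at height 0.5
        assert coph["a", "c"] == pytest.approx(4.0)
        assert dendro.linkage[0, 2] == pytest.approx(1.0)

    def test_output_is_ultrametric(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dendro = upgma_dendrogram(DistanceMatrix(d, ids=[str(i) for i in range(8)]))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_newick_round_trips_cophenetic_distances(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"x{i}" for i in range(6)]
        dendro = upgma_dendrogram(DistanceMatrix(d, ids=ids))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        from rlqspace.ordination import patristic_distance as pdist

        D_tree = pdist(tree)
        D_coph = dendro.cophenetic().filter(D_tree.ids)
        np.testing.assert_allclose(D_tree.data, D_coph.data, atol=1e-8)
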