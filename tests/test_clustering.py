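"""PAV distances, neighbor joining, bootstrap supports, PCA and Newick."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from panpav import (
    PavMatrix,
    bootstrap_support,
    clade_recovery,
    neighbor_joining,
    pav_distance,
    pca,
    read_newick,
    robinson_foulds,
    simulate_guide_tree,
    tree_splits,
    write_newick,
)


def matrix_from(rows, accessions):
    rows = np.asarray(rows, dtype=np.int8)
    return PavMatrix(
        pd.DataFrame(
            rows,
            index=pd.Index([f"g{i}" for i in range(rows.shape[0])], name="gene_id"),
            columns=accessions,
        )
    )


def random_binary_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths (truth generator for
    the NJ consistency sweep)."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for t in taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for idx in (i, j):
            parent.add_child(nodes[idx])
            nodes[idx].edge.length = float(rng.uniform(0.1, 2.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
        n.edge.length = float(rng.uniform(0.1, 2.0))
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    D = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
    return pd.DataFrame(D, index=labels, columns=labels)


class TestPavDistance:
    def test_known_values(self):
        pav = matrix_from(np.array([[1, 1], [1, 0], [0, 1], [0, 0]]), ["x", "y"])
        ham = pav_distance(pav, "hamming")
        jac = pav_distance(pav, "jaccard")
        assert ham.loc["x", "y"] == pytest.approx(0.5)
        assert jac.loc["x", "y"] == pytest.approx(2 / 3)

    def test_identical_rows_zero(self):
        pav = matrix_from(np.ones((10, 3)), ["a", "b", "c"])
        assert (pav_distance(pav).values == 0).all()

    def test_complementary_rows_hamming_one(self):
        pav = matrix_from(np.array([[1, 0], [0, 1], [1, 0]]), ["a", "b"])
        assert pav_distance(pav, "hamming").loc["a", "b"] == pytest.approx(1.0)

    def test_metric_properties(self, small_panel):
        _, pav, _ = small_panel
        D = pav_distance(pav, "hamming").values
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        # triangle inequality for hamming on a random triple sweep
        n = D.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.integers(0, n, 3)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_empty_union_warns(self):
        pav = matrix_from(np.array([[0, 0, 1], [0, 0, 1]]), ["a", "b", "c"])
        with pytest.warns(UserWarning, match="empty gene set"):
            jac = pav_distance(pav, "jaccard")
        assert jac.loc["a", "b"] == 0.0


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(D)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_closed_form(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(D)
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            truth = random_binary_tree(int(rng.integers(8, 21)), rng)
            rebuilt = neighbor_joining(patristic_matrix(truth))
            assert robinson_foulds(truth, rebuilt) == 0

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        truth = random_binary_tree(12, rng)
        D = patristic_matrix(truth)
        ours = neighbor_joining(D)
        skb = skbio_nj(DistanceMatrix(D.values, ids=list(D.index)))
        theirs = read_newick(str(skb).strip())
        assert robinson_foulds(ours, theirs) == 0

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame(np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]),
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D)

    def test_too_few_taxa_rejected(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"], dtype=float)
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(D)


class TestBootstrap:
    def test_single_replicate_supports_binary(self, small_panel):
        _, pav, _ = small_panel
        tree = bootstrap_support(pav, n_reps=1, seed=1)
        supports = [
            float(n.label) for n in tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_seed_reproducible(self, small_panel):
        _, pav, _ = small_panel
        t1 = bootstrap_support(pav, n_reps=10, seed=3)
        t2 = bootstrap_support(pav, n_reps=10, seed=3)
        assert write_newick(t1) == write_newick(t2)

    def test_clade_splits_strongly_supported(self, small_panel):
        _, pav, truth = small_panel
        tree = bootstrap_support(pav, n_reps=50, seed=4)
        mono, _ = clade_recovery(tree, truth.clade_map)
        assert all(mono.values())
        # supports of the clade-level splits are high
        leaves = frozenset(pav.accession_ids)
        anchor = min(leaves)
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            clades_below = {truth.clade_map[x] for x in below}
            full_clade = len(clades_below) == 1 and all(
                truth.clade_map[x] != next(iter(clades_below)) for x in leaves - below
            )
            if full_clade:
                assert float(node.label) >= 90.0


class TestPca:
    def test_identical_accessions_identical_scores(self):
        pav = matrix_from(np.array([[1, 1, 0], [0, 0, 1], [1, 1, 1]]), ["a", "b", "c"])
        res = pca(pav, n_components=2)
        np.testing.assert_allclose(res.scores.loc["a"], res.scores.loc["b"], atol=1e-12)

    def test_rank_one_pattern(self):
        rows = np.zeros((10, 4), dtype=np.int8)
        rows[:5, :2] = 1  # one axis of variation
        pav = matrix_from(rows, ["a", "b", "c", "d"])
        res = pca(pav, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_and_variance_identity(self, small_panel):
        _, pav, _ = small_panel
        n_acc = pav.n_accessions
        res = pca(pav, n_components=n_acc)
        X = pav.presence.to_numpy().astype(float).T
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.components, Xc, atol=1e-9
        )
        total_var = Xc.var(axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total_var, abs=1e-9)
        assert (np.diff(res.explained_variance) <= 1e-12).all()

    def test_component_count_validated(self, small_panel):
        _, pav, _ = small_panel
        with pytest.raises(ValueError):
            pca(pav, n_components=pav.n_accessions + 1)


class TestNewick:
    def test_round_trip_topology_and_lengths(self):
        text = "(A:1,B:2,(C:3,D:4):1);"
        tree = read_newick(text)
        out = write_newick(tree)
        again = read_newick(out)
        assert robinson_foulds(tree, again) == 0
        assert write_newick(again) == out  # byte-stable after canonicalisation
        lengths = {l.taxon.label: l.edge.length for l in again.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_supports_preserved(self, small_panel):
        _, pav, _ = small_panel
        tree = bootstrap_support(pav, n_reps=5, seed=9)
        out = write_newick(tree)
        again = read_newick(out)
        sup_in = sorted(
            n.label for n in tree.preorder_node_iter() if n.label and not n.is_leaf()
        )
        sup_out = sorted(
            n.label for n in again.preorder_node_iter() if n.label and not n.is_leaf()
        )
        assert sup_in == sup_out

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("(A:1,(B:2;")


class TestCladeRecovery:
    def test_identical_trees(self):
        tree = simulate_guide_tree(3, 4, seed=2)
        other = read_newick(write_newick(tree))
        from panpav import clade_map_from_tree

        mono, rf = clade_recovery(tree, clade_map_from_tree(tree), other)
        assert rf == 0
        assert all(mono.values())

    def test_star_tree_rf(self):
        resolved = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        star = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert robinson_foulds(star, resolved) == len(tree_splits(resolved))

    def test_leaf_set_mismatch(self):
        a = read_newick("(A:1,B:1,C:1);")
        b = read_newick("(A:1,B:1,D:1);")
        with pytest.raises(ValueError, match="leaf sets"):
            robinson_foulds(a, b)
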