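"""Neighbor joining, branch optimization, NNI search, bootstrap, RF."""

import numpy as np
import pytest

import orderphy as op
from orderphy.evolution_model import LikelihoodWorkspace, distance_matrix
from orderphy.tree import TreeError
from .conftest import random_binary_encoding


class TestNJTree:
    def test_three_taxon_branch_lengths(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        t = op.nj_tree(d, ["A", "B", "C"])
        lengths = {n.name: n.length for n in t.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_additive_four_taxon_matrix_recovers_split(self):
        # tree ((A,B),(C,D)) with all branches length 1
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                      [3, 3, 0, 2], [3, 3, 2, 0]], float)
        t = op.nj_tree(d, ["A", "B", "C", "D"])
        assert frozenset({"C", "D"}) in t.bipartitions()

    def test_tied_distances_give_valid_binary_tree(self):
        d = np.ones((5, 5)) - np.eye(5)
        t = op.nj_tree(d, list("ABCDE"))
        assert sorted(t.leaf_names()) == list("ABCDE")
        assert all((n.length or 0) >= 0 for n in t.postorder())

    def test_invalid_matrices_rejected(self):
        with pytest.raises(TreeError):
            op.nj_tree(np.array([[0, 1], [2, 0]], float), ["A", "B"])
        bad = np.zeros((3, 3))
        bad[0, 1] = np.nan
        with pytest.raises(TreeError):
            op.nj_tree(bad, ["A", "B", "C"])


class TestOptimizeBranchLengths:
    def test_parameter_recovery_on_fixed_topology(self):
        """Lengths estimated from data simulated under the model itself
        land within 20% of truth at 2000 characters."""
        m = op.make_model(5, ratio=2.0)
        rng = np.random.default_rng(7)
        root = op.Node()
        a = root.add(op.Node(length=0.3))
        a.add(op.Node("A", length=0.2))
        a.add(op.Node("B", length=0.4))
        root.add(op.Node("C", length=0.3))
        root.add(op.Node("D", length=0.5))
        tree = op.Tree(root)
        # simulate 2000 characters down the tree
        n_chars = 2000
        states = {}
        pi = m.stationary
        order = list(tree.preorder())
        states[id(order[0])] = (rng.random(n_chars) < pi[1]).astype(int)
        for node in order[1:]:
            P = op.transition_matrix(m, node.length)
            parent = states[id(node.parent)]
            u = rng.random(n_chars)
            states[id(node)] = np.where(parent == 1, (u < P[1, 1]),
                                        (u < P[0, 1])).astype(int)
        enc = random_binary_encoding(4, n_chars, seed=0)
        enc.taxa = ["A", "B", "C", "D"]
        for i, t in enumerate(enc.taxa):
            enc.matrix[i] = states[id(tree.find(t))]
        fitted = op.optimize_branch_lengths(tree, enc, m)
        for node, true_node in zip(fitted.postorder(), tree.postorder()):
            if true_node.parent is None:
                continue
            assert node.length == pytest.approx(true_node.length, rel=0.2)

    def test_constant_columns_drive_lengths_to_zero(self):
        enc = random_binary_encoding(4, 30, seed=1)
        enc.matrix[:] = enc.matrix[0]
        tree = op.random_tree(4, seed=2)
        fitted = op.optimize_branch_lengths(tree, enc, op.make_model(5))
        for n in fitted.postorder():
            if n.parent is not None:
                assert n.length < 1e-6

    def test_fixed_point(self):
        enc = random_binary_encoding(5, 60, seed=3)
        m = op.make_model(8)
        tree = op.random_tree(5, seed=3)
        cfg = op.SearchConfig()
        once = op.optimize_branch_lengths(tree, enc, m, cfg)
        ll1 = LikelihoodWorkspace(once, enc, m).log_likelihood()
        twice = op.optimize_branch_lengths(once, enc, m, cfg)
        ll2 = LikelihoodWorkspace(twice, enc, m).log_likelihood()
        assert abs(ll2 - ll1) < 10 * cfg.ll_epsilon
        assert ll2 >= ll1 - 1e-9


class TestMLSearch:
    def test_recovers_simulated_topology(self):
        hits = 0
        for seed in range(5):
            cfg = op.SimulationConfig(taxa=6, n_genes=50, seed=seed)
            tree = op.random_tree(6, seed=seed)
            leaves, _, _ = op.evolve(tree, cfg)
            enc = op.build_encoding(list(leaves))
            m = op.make_model(len(set().union(*(g.gene_families()
                                                for g in leaves))))
            found, _ = op.ml_search(enc, m, op.SearchConfig(seed=seed))
            hits += op.rf_distance(found, tree) == 0
        assert hits >= 4

    def test_identical_rows_become_siblings(self):
        a = op.Genome("A", [op.Chromosome([1, 2, 3, 4, 5, 6])])
        b = op.Genome("B", [op.Chromosome([1, 2, 3, 4, 5, 6])])
        c = op.Genome("C", [op.Chromosome([1, -4, -3, -2, 5, 6])])
        d = op.Genome("D", [op.Chromosome([-2, -1, 3, 4, -6, -5])])
        enc = op.build_encoding([a, b, c, d])
        tree, _ = op.ml_search(enc, op.make_model(6), op.SearchConfig())
        assert frozenset({"A", "B"}) in tree.bipartitions() or \
            frozenset({"C", "D"}) in tree.bipartitions()

    def test_search_not_worse_than_nj_start(self):
        cfg = op.SimulationConfig(taxa=7, n_genes=40, seed=11)
        leaves, _, _ = op.evolve(op.random_tree(7, seed=11), cfg)
        enc = op.build_encoding(list(leaves))
        m = op.make_model(len(set().union(*(g.gene_families()
                                            for g in leaves))))
        nj = op.nj_tree(distance_matrix(enc, m), list(enc.taxa))
        nj_fit = op.optimize_branch_lengths(nj, enc, m)
        nj_ll = LikelihoodWorkspace(nj_fit, enc, m).log_likelihood()
        _, search_ll = op.ml_search(enc, m, op.SearchConfig(seed=0))
        assert search_ll >= nj_ll - 1e-6

    def test_three_taxa_unique_topology(self):
        gs = [op.Genome(n, [op.Chromosome([1, 2, 3])]) for n in "XYZ"]
        enc = op.build_encoding(gs)
        tree, _ = op.ml_search(enc, op.make_model(3))
        assert sorted(tree.leaf_names()) == ["X", "Y", "Z"]


class TestBootstrap:
    def _compatible_encoding(self):
        """500 columns all perfectly compatible with one 5-leaf tree."""
        rng = np.random.default_rng(0)
        splits = [np.array(v) for v in
                  ([1, 1, 0, 0, 0], [1, 1, 1, 0, 0], [1, 1, 1, 1, 1],
                   [0, 0, 0, 1, 1], [1, 0, 0, 0, 0], [0, 0, 0, 0, 1])]
        mat = np.stack([splits[rng.integers(0, len(splits))]
                        for _ in range(500)], axis=1).astype(np.uint8)
        enc = random_binary_encoding(5, 500, seed=0)
        enc.matrix = mat
        return enc

    def test_fully_compatible_data_gives_full_support(self):
        enc = self._compatible_encoding()
        m = op.make_model(5)
        tree = op.bootstrap(enc, m, replicates=10, config=op.SearchConfig(seed=4))
        supports = [n.support for n in tree.postorder()
                    if n.parent is not None and not n.is_leaf
                    and n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        cfg = op.SimulationConfig(taxa=5, n_genes=30, seed=6)
        leaves, _, _ = op.evolve(op.random_tree(5, seed=6), cfg)
        enc = op.build_encoding(list(leaves))
        m = op.make_model(len(set().union(*(g.gene_families()
                                            for g in leaves))))
        tree = op.bootstrap(enc, m, replicates=1, config=op.SearchConfig(seed=1))
        for n in tree.postorder():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_seed_reproducibility(self):
        cfg = op.SimulationConfig(taxa=6, n_genes=30, seed=8)
        leaves, _, _ = op.evolve(op.random_tree(6, seed=8), cfg)
        enc = op.build_encoding(list(leaves))
        m = op.make_model(len(set().union(*(g.gene_families()
                                            for g in leaves))))
        t1 = op.bootstrap(enc, m, replicates=5, config=op.SearchConfig(seed=9))
        t2 = op.bootstrap(enc, m, replicates=5, config=op.SearchConfig(seed=9))
        assert op.write_newick(t1, with_supports=True) == \
            op.write_newick(t2, with_supports=True)
        sup = [n.support for n in t1.postorder() if n.support is not None]
        assert all(0 <= s <= 100 for s in sup)


class TestRFDistance:
    def test_identical_trees(self):
        t = op.random_tree(8, seed=0)
        assert op.rf_distance(t, t.copy()) == 0

    def test_distinct_quartets(self):
        t1 = op.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = op.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert op.rf_distance(t1, t2) == 2

    def test_matches_dendropy(self):
        import dendropy

        for seed in range(5):
            t1 = op.random_tree(10, seed=seed)
            t2 = op.random_tree(10, seed=seed + 100)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.newick(), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expect = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert op.rf_distance(t1, t2) == expect

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(TreeError):
            op.rf_distance(op.random_tree(5, seed=0), op.random_tree(6, seed=0))


def test_majority_consensus_keeps_majority_split():
    t1 = op.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = op.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t3 = op.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
    cons = op.majority_consensus([t1, t2, t3])
    assert frozenset({"C", "D"}) in cons.bipartitions()


def test_broken_adjacencies_rarely_reform():
    """Character independence rests on broken adjacencies almost never
    re-forming; at default study conditions the fraction is below 5%."""
    from orderphy.experiments import reformation_fraction

    reformed = broken = 0
    for seed in range(3):
        cfg = op.SimulationConfig(seed=seed)
        tree = op.random_tree(cfg.taxa, seed=seed)
        leaves, ancestors, _ = op.evolve(tree, cfg)
        by_name = {g.name: g for g in list(leaves) + list(ancestors)}
        r, b = reformation_fraction(tree, by_name)
        reformed += r
        broken += b
    assert broken > 0
    assert reformed / broken < 0.05
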