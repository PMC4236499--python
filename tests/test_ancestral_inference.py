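"""Marginal posteriors, gene-content thresholding, and TSP assembly."""

import itertools
import math

import numpy as np
import pytest

import orderphy as op
from orderphy.ancestral_inference import (AncestralError, EXACT_LIMIT,
                                          TSPInstance, tour_weight)
from orderphy.genome_core import O
from .conftest import brute_force_posterior, random_binary_encoding


class TestMarginalPosteriors:
    def test_all_present_zero_branches(self):
        enc = random_binary_encoding(4, 10, seed=0)
        enc.matrix[:] = 1
        tree = op.random_tree(4, seed=1)
        for n in tree.postorder():
            if n.parent is not None:
                n.length = 0.0
        post = op.marginal_posteriors(tree, enc, op.make_model(5))
        assert post.matrix == pytest.approx(np.ones_like(post.matrix))

    @pytest.mark.parametrize("leaves,seed", [(4, 0), (5, 1), (6, 2)])
    def test_matches_brute_force_bayes(self, leaves, seed):
        tree = op.random_tree(leaves, seed=seed)
        enc = random_binary_encoding(leaves, 12, seed=seed)
        m = op.make_model(9)
        post = op.marginal_posteriors(tree, enc, m)
        for name in post.nodes:
            for c in range(enc.n_characters):
                expect = brute_force_posterior(tree, enc, m, name, c)
                assert post.row(name)[c] == pytest.approx(expect, abs=1e-9)

    def test_three_leaf_star_majority_state_wins(self):
        """Symmetric model, equal branches, leaf states {1,1,0}: the root
        posterior of presence exceeds 1/2 (closed-form check)."""
        m = op.make_model(1, ratio=1.0)
        enc = random_binary_encoding(3, 1, seed=0)
        enc.matrix[:, 0] = [1, 1, 0]
        root = op.Node("R")
        for t in ("T1", "T2", "T3"):
            root.add(op.Node(t, length=0.5))
        post = op.marginal_posteriors(op.Tree(root), enc, m)
        P = op.transition_matrix(m, 0.5)
        num = 0.5 * P[1, 1] * P[1, 1] * P[1, 0]
        den = num + 0.5 * P[0, 1] * P[0, 1] * P[0, 0]
        assert post.row("R")[0] == pytest.approx(num / den, abs=1e-12)
        assert post.row("R")[0] > 0.5

    def test_missing_branch_lengths_rejected(self):
        tree = op.random_tree(4, seed=0)
        list(tree.postorder())[0].length = None
        with pytest.raises(op.TreeError):
            op.marginal_posteriors(tree, random_binary_encoding(4, 5, seed=0),
                                   op.make_model(3))


class TestInferGeneContent:
    def _table(self, probs):
        from orderphy.ancestral_inference import PosteriorTable
        from orderphy.genome_core import (ADJACENCY, GENE_FAMILY,
                                          CharacterMeta)

        cols = [CharacterMeta(GENE_FAMILY, 1), CharacterMeta(GENE_FAMILY, 2),
                CharacterMeta(ADJACENCY, op.canonical_adjacency(1, 2))]
        return PosteriorTable(nodes=["A1"], columns=cols,
                              matrix=np.array([probs]))

    @pytest.mark.parametrize("p,present", [(0.51, True), (0.50, False),
                                           (0.49, False)])
    def test_strictly_greater_than_half(self, p, present):
        content = op.infer_gene_content(self._table([p, 0.9, 0.9]))["A1"]
        assert (1 in content.genes) == present

    def test_adjacency_to_absent_gene_dropped(self):
        content = op.infer_gene_content(self._table([0.9, 0.2, 0.9]))["A1"]
        assert 2 not in content.genes
        assert all(adj.genes() == (1,) or 2 not in adj.genes()
                   for adj, _ in content.adjacencies)

    def test_threshold_validation(self):
        with pytest.raises(AncestralError):
            op.infer_gene_content(self._table([1, 1, 1]), threshold=1.5)


def _content(genes, candidates, node="A1"):
    from orderphy.ancestral_inference import AncestralContent

    return AncestralContent(node=node, genes=set(genes),
                            adjacencies=[(op.canonical_adjacency(a, b), p)
                                         for (a, b), p in candidates])


class TestBuildTSP:
    def test_single_chromosome_perfect_candidates(self):
        content = _content([1, 2, 3], [((O, 1), 1.0), ((1, 2), 1.0),
                                       ((2, 3), 1.0), ((O, -3), 1.0)])
        inst = op.build_tsp(content)
        tour = op.solve_tsp(inst, mode="exact")
        genome = op.assemble_genome(tour, inst, name="A1")
        assert genome.canonical() == op.Genome(
            "A1", [op.Chromosome([1, 2, 3])]).canonical()

    def test_conflicting_candidates_keep_higher_probability(self):
        content = _content([1, 2, 3],
                           [((O, -1), 0.9), ((1, 2), 0.9), ((1, 3), 0.6),
                            ((2, 3), 0.8), ((O, -3), 0.5), ((O, -2), 0.4),
                            ((O, 1), 0.5), ((O, 2), 0.3), ((O, 3), 0.4)])
        inst = op.build_tsp(content)
        tour = op.solve_tsp(inst, mode="exact")
        genome = op.assemble_genome(tour, inst, name="A1")
        got = set(op.extract_adjacencies(genome))
        assert op.canonical_adjacency(1, 2) in got
        assert op.canonical_adjacency(1, 3) not in got

    def test_chromosome_count_from_telomere_mass(self):
        content = _content([1, 2], [((O, 1), 0.95), ((O, -1), 0.9),
                                    ((O, 2), 0.95), ((O, -2), 0.9)])
        # telomere mass 3.7 -> L = 2 linear chromosomes
        inst = op.build_tsp(content)
        assert len(inst.cap_indices) == 4
        tour = op.solve_tsp(inst, mode="exact")
        genome = op.assemble_genome(tour, inst, name="A1")
        assert len(genome.chromosomes) == 2

    def test_mandatory_edges_form_perfect_matching(self):
        content = _content([1, 2, 3], [((1, 2), 0.7)])
        inst = op.build_tsp(content)
        touched = [v for e in inst.mandatory for v in e]
        gene_vertices = [i for i, v in enumerate(inst.vertices)
                         if v[0] in ("t", "h")]
        assert sorted(touched) == sorted(gene_vertices)

    def test_no_present_genes_rejected(self):
        with pytest.raises(AncestralError):
            op.build_tsp(_content([], []))


class TestSolveTSP:
    def _random_instance(self, rng, n):
        w = rng.uniform(0, 10, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        return TSPInstance(vertices=list(range(n)), weights=w,
                           mandatory=[], cap_indices=[])

    def test_four_vertex_brute_force(self):
        w = np.array([[0, 1, 2, 3], [1, 0, 4, 5],
                      [2, 4, 0, 6], [3, 5, 6, 0]], float)
        inst = TSPInstance(vertices=list(range(4)), weights=w,
                           mandatory=[], cap_indices=[])
        tour = op.solve_tsp(inst, mode="exact")
        best = min(tour_weight(inst, [0] + list(p))
                   for p in itertools.permutations([1, 2, 3]))
        assert tour_weight(inst, tour) == pytest.approx(best)

    def test_exact_equals_enumeration_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            inst = self._random_instance(rng, n)
            exact = tour_weight(inst, op.solve_tsp(inst, mode="exact"))
            brute = min(tour_weight(inst, [0] + list(p))
                        for p in itertools.permutations(range(1, n)))
            assert exact == pytest.approx(brute, abs=1e-9)

    def test_heuristic_never_beats_exact(self):
        rng = np.random.default_rng(6)
        for rep in range(30):
            inst = self._random_instance(rng, int(rng.integers(5, 10)))
            exact = tour_weight(inst, op.solve_tsp(inst, mode="exact"))
            heur = tour_weight(inst, op.solve_tsp(inst, mode="heuristic",
                                                  seed=rep))
            assert heur >= exact - 1e-9

    def test_mandatory_edges_always_in_tour(self):
        content = _content(range(1, 8), [((i, i + 1), 0.8)
                                         for i in range(1, 7)])
        inst = op.build_tsp(content)
        for mode in ("exact", "heuristic"):
            tour = op.solve_tsp(inst, mode=mode, seed=3)
            edges = {frozenset((tour[i], tour[(i + 1) % len(tour)]))
                     for i in range(len(tour))}
            assert all(frozenset(e) in edges for e in inst.mandatory)

    def test_oversized_exact_instance_advises_heuristic(self):
        rng = np.random.default_rng(0)
        inst = self._random_instance(rng, EXACT_LIMIT + 2)
        with pytest.raises(AncestralError, match="heuristic"):
            op.solve_tsp(inst, mode="exact")


class TestEndToEnd:
    def test_identical_inputs_reproduce_ancestors_exactly(self):
        g = [op.Genome(n, [op.Chromosome([1, 2, 3]), op.Chromosome([4, 5])])
             for n in "ABCD"]
        enc = op.build_encoding(g)
        m = op.make_model(5)
        tree, _ = op.ml_search(enc, m, op.SearchConfig(seed=0))
        tree.midpoint_root()
        tree = op.optimize_branch_lengths(tree, enc, m)
        ancestors, post = op.reconstruct_ancestors(tree, enc, m)
        assert np.all((post.matrix > 0.99) | (post.matrix < 0.01)
                      | np.isclose(post.matrix, 0.5))
        for anc in ancestors:
            assert anc.canonical() == g[0].canonical()

    def test_posterior_rows_normalized(self):
        cfg = op.SimulationConfig(taxa=6, n_genes=30, seed=3)
        tree = op.random_tree(6, seed=3)
        leaves, _, _ = op.evolve(tree, cfg)
        enc = op.build_encoding(list(leaves))
        m = op.make_model(len(set().union(*(g.gene_families()
                                            for g in leaves))))
        fitted = op.optimize_branch_lengths(tree, enc, m)
        post = op.marginal_posteriors(fitted, enc, m)
        assert np.all(post.matrix >= 0) and np.all(post.matrix <= 1)

    def test_low_rate_simulation_recovers_root_adjacencies(self):
        cfg = op.SimulationConfig(taxa=6, n_genes=40, seed=12,
                                  events_per_branch=1.0)
        tree = op.random_tree(6, seed=12)
        leaves, true_anc, _ = op.evolve(tree, cfg)
        enc = op.build_encoding(list(leaves))
        m = op.make_model(len(set().union(*(g.gene_families()
                                            for g in leaves))))
        fitted = op.optimize_branch_lengths(tree, enc, m)
        ancestors, _ = op.reconstruct_ancestors(fitted, enc, m, seed=0)
        root_name = tree.root.name
        true_adj = set(op.extract_adjacencies(true_anc[root_name]))
        got = set(op.extract_adjacencies(ancestors[root_name]))
        assert len(true_adj & got) / len(true_adj) >= 0.95
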