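import itertools

import numpy as np
import pytest

import orderphy as op
from orderphy.genome_core import GENE_FAMILY, BinaryEncoding, CharacterMeta


@pytest.fixture
def small_doc():
    """Four genomes over 5 families with one rearrangement apart."""
    return op.GenomeDocument([
        op.Genome("A", [op.Chromosome([1, 2, 3, 4, 5])]),
        op.Genome("B", [op.Chromosome([1, -3, -2, 4, 5])]),
        op.Genome("C", [op.Chromosome([1, 2, 3, 4, 5])]),
        op.Genome("D", [op.Chromosome([1, 2, 3, -5, -4])]),
    ])


def random_binary_encoding(n_taxa: int, n_chars: int, seed: int) -> BinaryEncoding:
    """Arbitrary 0/1 matrix dressed up as an encoding (for model tests)."""
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.uint8)
    cols = [CharacterMeta(GENE_FAMILY, j + 1) for j in range(n_chars)]
    return BinaryEncoding(taxa=[f"T{i + 1}" for i in range(n_taxa)],
                          columns=cols, matrix=mat)


def brute_force_log_likelihood(tree, enc, model) -> float:
    """Likelihood by exhaustive summation over internal-state assignments."""
    import math

    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    pi = model.stationary
    P = {id(n): op.transition_matrix(model, n.length)
         for n in nodes if n.parent is not None}
    leafrow = {t: enc.matrix[i] for i, t in enumerate(enc.taxa)}
    total = 0.0
    for c in range(enc.n_characters):
        site = 0.0
        for states in itertools.product([0, 1], repeat=len(internals)):
            sdict = {id(n): s for n, s in zip(internals, states)}
            p = pi[sdict[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                s = leafrow[n.name][c] if n.is_leaf else sdict[id(n)]
                p *= P[id(n)][sdict[id(n.parent)], s]
            site += p
        total += math.log(site)
    return total


def brute_force_posterior(tree, enc, model, node_name: str, char: int) -> float:
    """P(state 1 at the named internal node | data) by enumeration."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    pi = model.stationary
    P = {id(n): op.transition_matrix(model, n.length)
         for n in nodes if n.parent is not None}
    leafrow = {t: enc.matrix[i] for i, t in enumerate(enc.taxa)}
    query = next(n for n in internals if n.name == node_name)
    tot = [0.0, 0.0]
    for states in itertools.product([0, 1], repeat=len(internals)):
        sdict = {id(n): s for n, s in zip(internals, states)}
        p = pi[sdict[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            s = leafrow[n.name][char] if n.is_leaf else sdict[id(n)]
            p *= P[id(n)][sdict[id(n.parent)], s]
        tot[sdict[id(query)]] += p
    return tot[1] / (tot[0] + tot[1])
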