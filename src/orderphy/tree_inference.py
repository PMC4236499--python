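"""Maximum-likelihood tree search on the binary encoding, with bootstrap.

Pipeline: pairwise ML distances seed a neighbor-joining tree; branch
lengths are optimized one edge at a time by bracketed 1-D maximization;
the topology is then hill-climbed over nearest-neighbor-interchange (NNI)
moves, accepting the best strictly improving neighbor until none exists.
Bootstrap supports come from column resampling of the encoding.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np

from .evolution_model import (LikelihoodWorkspace, TransitionModel,
                              distance_matrix, transition_matrix)
from .genome_core import BinaryEncoding
from .tree import Node, Tree, TreeError, rf_distance  # re-export rf_distance

__all__ = [
    "SearchConfig", "nj_tree", "optimize_branch_lengths", "ml_search",
    "bootstrap", "rf_distance", "majority_consensus",
]


@dataclass
class SearchConfig:
    """Knobs of the NNI hill-climb; all runs are deterministic given seed."""

    max_nni_rounds: int = 50
    branch_tol: float = 1e-6
    ll_epsilon: float = 1e-6
    seed: int = 0
    max_branch_length: float = 10.0
    distance_cap: float = 5.0
    neighbor_sweeps: int = 3   # branch-optimization sweeps per NNI candidate
    full_sweeps: int = 20      # sweeps on the current/accepted tree

    def __post_init__(self) -> None:
        if (self.max_nni_rounds <= 0 or self.branch_tol <= 0
                or self.ll_epsilon <= 0):
            raise ValueError("search parameters must be positive")


def nj_tree(distances: np.ndarray, names: list[str]) -> Tree:
    """Neighbor-joining starting tree (scikit-bio backend).

    Negative inferred branch lengths are clamped to zero and the root is
    collapsed to a trifurcation (unrooted representation).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(names):
        raise TreeError("distance matrix shape does not match names")
    if np.isnan(d).any():
        raise TreeError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise TreeError("distance matrix must be symmetric with zero diagonal")
    if len(names) < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")

    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    sk = _skbio_nj(DistanceMatrix(d, ids=list(names)))
    buf = _io.StringIO()
    sk.write(buf, format="newick")
    from .io_formats import read_newick

    tree = read_newick(buf.getvalue())
    for n in tree.postorder():
        if n.parent is not None:
            n.length = max(n.length or 0.0, 0.0)
    tree.unroot()
    return tree


def _optimize_branches(ws: LikelihoodWorkspace, tol: float, epsilon: float,
                       max_sweeps: int, max_len: float) -> float:
    """In-place coordinate-wise branch-length optimization; returns log L."""
    ll = ws.log_likelihood()
    for _ in range(max_sweeps):
        out, out_scale = ws.outward()
        for node in ws.nodes:
            if node.parent is None:
                continue
            D = ws.down[id(node)]
            U = out[id(node)]
            w = ws.weights

            def neg_ll(t: float) -> float:
                P = transition_matrix(ws.model, t)
                site = np.einsum("ca,ab,cb->c", U, P, D)
                with np.errstate(divide="ignore"):
                    return -float(np.dot(w, np.log(np.maximum(site, 1e-300))))

            from .evolution_model import _bracketed_minimize

            node.length = _bracketed_minimize(neg_ll, lo=1e-9, hi=max_len,
                                              xatol=tol)
            # refresh tables so later edges see the update
            ws.refresh()
            out, out_scale = ws.outward()
        new_ll = ws.log_likelihood()
        if new_ll - ll < epsilon:
            ll = max(new_ll, ll)
            break
        ll = new_ll
    return ll


def optimize_branch_lengths(tree: Tree, enc: BinaryEncoding,
                            model: TransitionModel,
                            config: SearchConfig | None = None) -> Tree:
    """Return a copy of ``tree`` with ML-optimized branch lengths."""
    config = config or SearchConfig()
    t = tree.copy()
    ws = LikelihoodWorkspace(t, enc, model)
    _optimize_branches(ws, config.branch_tol, config.ll_epsilon,
                       config.full_sweeps, config.max_branch_length)
    return t


def _nni_neighbors(tree: Tree):
    """All NNI neighbors of an unrooted binary tree (trifurcating root).

    For each internal edge (u, v) with v a non-root internal child of u,
    the two neighbors swap one child of v with one fixed u-side subtree.
    Yields fresh trees; the input is untouched.
    """
    pre = list(tree.preorder())
    for i, v in enumerate(pre):
        if v.parent is None or v.is_leaf:
            continue
        u = v.parent
        others = [w for w in u.children if w is not v]
        if not others:
            continue
        for ci in range(len(v.children)):
            t2 = tree.copy()
            pre2 = list(t2.preorder())
            v2 = pre2[i]
            u2 = v2.parent
            x2 = [w for w in u2.children if w is not v2][0]
            c2 = v2.children[ci]
            u2.children[u2.children.index(x2)] = c2
            c2.parent = u2
            v2.children[ci] = x2
            x2.parent = v2
            yield t2


def ml_search(enc: BinaryEncoding, model: TransitionModel,
              config: SearchConfig | None = None) -> tuple[Tree, float]:
    """NJ seed + NNI hill climb; returns (tree, log-likelihood).

    The accepted log-likelihood sequence is strictly increasing; with
    fewer than 4 taxa the unique topology is returned without search.
    """
    config = config or SearchConfig()
    d = distance_matrix(enc, model, cap=config.distance_cap)
    if len(enc.taxa) < 3:
        raise TreeError("need at least 3 taxa")
    if len(enc.taxa) == 3:
        root = Node()
        for name in enc.taxa:
            root.add(Node(name, length=0.1))
        tree = Tree(root)
    else:
        tree = nj_tree(d, list(enc.taxa))
    ws = LikelihoodWorkspace(tree, enc, model)
    ll = _optimize_branches(ws, config.branch_tol, config.ll_epsilon,
                            config.full_sweeps, config.max_branch_length)
    if len(enc.taxa) < 4:
        return tree, ll

    for _ in range(config.max_nni_rounds):
        best_ll, best_tree = ll, None
        for cand in _nni_neighbors(tree):
            try:
                wsc = LikelihoodWorkspace(cand, enc, model)
            except TreeError:  # pragma: no cover
                continue
            cand_ll = _optimize_branches(
                wsc, config.branch_tol, config.ll_epsilon,
                config.neighbor_sweeps, config.max_branch_length)
            if cand_ll > best_ll + config.ll_epsilon:
                best_ll, best_tree = cand_ll, cand
        if best_tree is None:
            break
        tree = best_tree
        ws = LikelihoodWorkspace(tree, enc, model)
        ll = _optimize_branches(ws, config.branch_tol, config.ll_epsilon,
                                config.full_sweeps, config.max_branch_length)
    return tree, ll


def bootstrap(enc: BinaryEncoding, model: TransitionModel,
              replicates: int, config: SearchConfig | None = None,
              point_tree: Tree | None = None) -> Tree:
    """Column-resampling bootstrap supports on the ML point-estimate tree.

    Entire columns (adjacency, telomere, and gene-family characters as one
    alignment) are resampled with replacement; each replicate is re-searched
    and every internal edge of the point tree gets the percentage of
    replicates containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    config = config or SearchConfig()
    if point_tree is None:
        point_tree, _ = ml_search(enc, model, config)
    point_tree = point_tree.copy()
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    ncols = enc.n_characters
    for _ in range(replicates):
        idx = rng.integers(0, ncols, size=ncols)
        enc_b = enc.resample_columns(idx)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_config = SearchConfig(
            max_nni_rounds=config.max_nni_rounds,
            branch_tol=config.branch_tol, ll_epsilon=config.ll_epsilon,
            seed=rep_seed, max_branch_length=config.max_branch_length,
            distance_cap=config.distance_cap,
            neighbor_sweeps=config.neighbor_sweeps,
            full_sweeps=config.full_sweeps)
        rep_tree, _ = ml_search(enc_b, model, rep_config)
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    for node in point_tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        split = point_tree.edge_bipartition(node)
        if split is None:
            continue
        node.support = 100.0 * counts.get(split, 0) / replicates
    return point_tree


def majority_consensus(trees: list[Tree], min_freq: float = 0.5) -> Tree:
    """Majority-rule consensus of a tree list (dendropy backend)."""
    import dendropy

    tl = dendropy.TreeList()
    tns = dendropy.TaxonNamespace()
    for t in trees:
        tl.append(dendropy.Tree.get(data=t.newick(), schema="newick",
                                    taxon_namespace=tns,
                                    preserve_underscores=True))
    cons = tl.consensus(min_freq=min_freq)
    from .io_formats import read_newick

    return read_newick(cons.as_string(schema="newick",
                                      suppress_rooting=True))
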