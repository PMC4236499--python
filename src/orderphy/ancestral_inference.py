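"""Ancestral genome reconstruction: posteriors, gene content, TSP assembly.

On a fixed tree the small-phylogeny stage proceeds in three steps:

1. marginal posterior of presence for every character at every internal
   node (one downward and one outward pruning pass, Yang-style marginal
   reconstruction);
2. thresholding: a gene family belongs to an ancestor iff its posterior
   is strictly greater than 50% (candidate adjacencies touching an absent
   gene are dropped);
3. adjacency assembly: gene extremities become vertices of a weighted
   graph (edge weight -ln p for a candidate adjacency with posterior p,
   -ln epsilon otherwise), each gene's head-tail pair is a mandatory edge,
   and 2L chromosome-cap vertices allow L linear chromosomes; the minimum
   tour of the resulting Travelling Salesperson instance decodes into the
   ancestral gene order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field


import numpy as np

from .evolution_model import LikelihoodWorkspace, TransitionModel
from .genome_core import (ADJACENCY, GENE_FAMILY, TELOMERE, Adjacency,
                          BinaryEncoding, Chromosome, Genome)
from .io_formats import GenomeDocument
from .tree import Tree

logger = logging.getLogger(__name__)


class AncestralError(ValueError):
    pass


@dataclass
class PosteriorTable:
    """Per internal node x character: posterior probability of presence."""

    nodes: list[str]
    columns: list  # CharacterMeta, shared with the encoding
    matrix: np.ndarray  # (len(nodes), n_characters), P(state 1)

    def row(self, node: str) -> np.ndarray:
        return self.matrix[self.nodes.index(node)]

    def to_tsv(self) -> str:
        import pandas as pd

        df = pd.DataFrame(self.matrix, index=self.nodes,
                          columns=[m.describe() for m in self.columns])
        return df.to_csv(sep="\t", index_label="node", float_format="%.6g")


@dataclass
class AncestralContent:
    """Thresholded content of one ancestral node."""

    node: str
    genes: set[int]
    # candidate adjacencies/telomeres (touching present genes only) with
    # their posterior probability of presence
    adjacencies: list[tuple[Adjacency, float]] = field(default_factory=list)

    def telomere_posterior_sum(self) -> float:
        return sum(p for a, p in self.adjacencies if a.is_telomere)


@dataclass
class TSPInstance:
    """Symmetric TSP over gene extremities plus chromosome caps."""

    vertices: list  # ("t"|"h", family) or ("cap", k)
    weights: np.ndarray  # (V, V) symmetric
    mandatory: list[tuple[int, int]]  # per-gene head-tail vertex pairs
    cap_indices: list[int]

    @property
    def size(self) -> int:
        return len(self.vertices)


def marginal_posteriors(tree: Tree, enc: BinaryEncoding,
                        model: TransitionModel) -> PosteriorTable:
    """Marginal posterior of presence at every internal node.

    The tree must carry branch lengths; unnamed internal nodes are labeled
    A1, A2, ... in preorder.  Posteriors are proportional to the product of
    the downward conditional likelihood and the outward partial likelihood,
    normalized over the two states.
    """
    tree.name_ancestors()
    ws = LikelihoodWorkspace(tree, enc, model)
    out, _ = ws.outward()
    names, rows = [], []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        names.append(node.name)
        rows.append(ws.marginal_posteriors_node(out, node))
    return PosteriorTable(nodes=names, columns=list(enc.columns),
                          matrix=np.vstack(rows))


def infer_gene_content(post: PosteriorTable,
                       threshold: float = 0.5) -> dict[str, AncestralContent]:
    """Threshold posteriors into per-node gene content and candidates.

    A family is present iff its posterior is strictly greater than
    ``threshold`` (the >50% rule); candidate adjacencies or telomeres that
    touch an absent family are dropped.
    """
    if not (0.0 < threshold < 1.0):
        raise AncestralError("threshold must lie strictly between 0 and 1")
    result: dict[str, AncestralContent] = {}
    for i, node in enumerate(post.nodes):
        probs = post.matrix[i]
        genes = {meta.payload for j, meta in enumerate(post.columns)
                 if meta.kind == GENE_FAMILY and probs[j] > threshold}
        content = AncestralContent(node=node, genes=genes)
        dropped = 0
        for j, meta in enumerate(post.columns):
            if meta.kind not in (ADJACENCY, TELOMERE):
                continue
            adj: Adjacency = meta.payload
            if all(g in genes for g in adj.genes()):
                content.adjacencies.append((adj, float(probs[j])))
            elif probs[j] > threshold:
                dropped += 1
        if dropped:
            logger.info("node %s: dropped %d supported adjacencies touching "
                        "absent genes", node, dropped)
        result[node] = content
    return result


def _ext_end(x: int) -> tuple[str, int]:
    """Extremity at the downstream end of signed gene x."""
    return ("h" if x > 0 else "t", abs(x))


def _ext_start(x: int) -> tuple[str, int]:
    """Extremity at the upstream end of signed gene x."""
    return ("t" if x > 0 else "h", abs(x))


def build_tsp(content: AncestralContent,
              epsilon: float = 1e-6) -> TSPInstance:
    """Reduce adjacency assembly at one node to a TSP instance.

    L = max(1, round(sum of telomere posteriors / 2)) linear chromosomes
    are allowed via 2L cap vertices; cap-cap edges are free, candidate
    edges cost -ln(max(p, epsilon)), everything else costs -ln(epsilon),
    and each gene's head-tail edge gets a reward large enough that every
    optimal tour keeps all genes intact.
    """
    genes = sorted(content.genes)
    if not genes:
        raise AncestralError(f"node {content.node}: no genes deemed present")
    L = max(1, round(content.telomere_posterior_sum() / 2.0))
    vertices: list = []
    index: dict = {}
    for g in genes:
        for side in ("t", "h"):
            index[(side, g)] = len(vertices)
            vertices.append((side, g))
    cap_indices = []
    for k in range(2 * L):
        cap_indices.append(len(vertices))
        index[("cap", k)] = len(vertices)
        vertices.append(("cap", k))

    V = len(vertices)
    base = -math.log(epsilon)
    weights = np.full((V, V), base)
    np.fill_diagonal(weights, 0.0)
    for a in cap_indices:
        for b in cap_indices:
            if a != b:
                weights[a, b] = 0.0

    for adj, p in content.adjacencies:
        w = -math.log(max(p, epsilon))
        if adj.is_telomere:
            u = index[_ext_start(adj.right)]
            for c in cap_indices:
                weights[u, c] = weights[c, u] = min(weights[u, c], w)
        else:
            u = index[_ext_end(adj.left)]
            v = index[_ext_start(adj.right)]
            if u == v:
                continue  # foldback pseudo-adjacency; not realizable
            weights[u, v] = weights[v, u] = min(weights[u, v], w)

    mandatory = []
    B = float(np.abs(weights).sum()) + 1.0
    for g in genes:
        u, v = index[("t", g)], index[("h", g)]
        weights[u, v] = weights[v, u] = -B
        mandatory.append((u, v))
    return TSPInstance(vertices=vertices, weights=weights,
                       mandatory=mandatory, cap_indices=cap_indices)


# ---------------------------------------------------------------------------
# TSP solvers


EXACT_LIMIT = 18


def solve_tsp(instance: TSPInstance, mode: str = "auto",
              seed: int = 0) -> list[int]:
    """Minimal (or heuristically short) tour as a cyclic vertex-index list.

    ``exact`` runs Held-Karp dynamic programming (instances up to
    18 vertices); ``heuristic`` runs seeded nearest-neighbor construction
    followed by 2-opt; ``auto`` picks exact when the instance is small.
    """
    if mode not in ("auto", "exact", "heuristic"):
        raise AncestralError(f"unknown TSP mode {mode!r}")
    if mode == "auto":
        mode = "exact" if instance.size <= EXACT_LIMIT else "heuristic"
    if mode == "exact":
        if instance.size > EXACT_LIMIT:
            raise AncestralError(
                f"exact mode limited to {EXACT_LIMIT} vertices "
                f"(instance has {instance.size}); use heuristic mode")
        return _held_karp(instance.weights)
    return _heuristic_tour(instance, seed)


def _held_karp(w: np.ndarray) -> list[int]:
    """Exact minimum Hamiltonian cycle by dynamic programming."""
    n = w.shape[0]
    if n == 1:
        return [0]
    if n == 2:
        return [0, 1]
    INF = np.inf
    # dp[S][j]: cheapest path visiting set S (bitmask over 1..n-1, always
    # containing j), starting at 0 and ending at j
    full = 1 << (n - 1)
    dp = np.full((full, n - 1), INF)
    parent = np.full((full, n - 1), -1, dtype=np.int32)
    for j in range(n - 1):
        dp[1 << j, j] = w[0, j + 1]
    wsub = w[1:, 1:]
    for S in range(1, full):
        members = np.flatnonzero([(S >> j) & 1 for j in range(n - 1)])
        if len(members) < 2:
            continue
        for j in members:
            prev = S ^ (1 << int(j))
            # dp[prev, j] is INF (j not in prev), so no self-predecessor
            vals = dp[prev, members] + wsub[members, j]
            arg = int(np.argmin(vals))
            dp[S, j] = vals[arg]
            parent[S, j] = members[arg]
    S = full - 1
    best, arg = INF, -1
    for j in range(n - 1):
        val = dp[S, j] + w[j + 1, 0]
        if val < best:
            best, arg = val, j
    tour = [0]
    j = arg
    while j >= 0:
        tour.append(j + 1)
        nj = parent[S, j]
        S ^= 1 << j
        j = nj
    tour.reverse()
    return tour


def tour_weight(instance: TSPInstance, tour: list[int]) -> float:
    w = instance.weights
    return float(sum(w[tour[i], tour[(i + 1) % len(tour)]]
                     for i in range(len(tour))))


def _heuristic_tour(instance: TSPInstance, seed: int) -> list[int]:
    """Nearest-neighbor from a seeded start, then mandatory-edge-safe 2-opt."""
    w = instance.weights
    n = instance.size
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n))
    unvisited = set(range(n))
    tour = [start]
    unvisited.remove(start)
    while unvisited:
        cur = tour[-1]
        cand = min(unvisited, key=lambda j: (w[cur, j], j))
        tour.append(cand)
        unvisited.remove(cand)
    mandatory = {frozenset(e) for e in instance.mandatory}

    def is_mand(a: int, b: int) -> bool:
        return frozenset((a, b)) in mandatory

    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            a, b = tour[i], tour[i + 1]
            if is_mand(a, b):
                continue
            for j in range(i + 2, n):
                c, d = tour[j], tour[(j + 1) % n]
                if (j + 1) % n == i or is_mand(c, d):
                    continue
                delta = (w[a, c] + w[b, d]) - (w[a, b] + w[c, d])
                if delta < -1e-12:
                    tour[i + 1:j + 1] = reversed(tour[i + 1:j + 1])
                    improved = True
                    a, b = tour[i], tour[i + 1]
    return tour


def assemble_genome(tour: list[int], instance: TSPInstance,
                    name: str) -> Genome:
    """Decode a tour into linear chromosomes, cutting at cap vertices.

    Consecutive extremity pairs alternate between mandatory gene edges
    (emitting a signed gene: entered at the tail means forward strand) and
    adjacency edges; cap-to-cap stretches are empty chromosomes and are
    dropped.
    """
    caps = set(instance.cap_indices)
    if not caps & set(tour):
        raise AncestralError("tour contains no cap vertices")
    n = len(tour)
    # rotate so the tour starts at a cap
    start = next(i for i, v in enumerate(tour) if v in caps)
    rot = tour[start:] + tour[:start]
    chromosomes: list[Chromosome] = []
    segment: list[int] = []

    def flush(seg: list[int]) -> None:
        if not seg:
            return
        if len(seg) % 2 != 0:
            raise AncestralError("tour violates gene-edge alternation")
        genes: list[int] = []
        for a, b in zip(seg[0::2], seg[1::2]):
            sa, ga = instance.vertices[a]
            sb, gb = instance.vertices[b]
            if ga != gb or {sa, sb} != {"t", "h"}:
                raise AncestralError("tour violates gene-edge alternation")
            genes.append(ga if sa == "t" else -ga)
        chromosomes.append(Chromosome(genes, circular=False))

    for v in rot[1:]:
        if v in caps:
            flush(segment)
            segment = []
        else:
            segment.append(v)
    flush(segment)
    if not chromosomes:
        raise AncestralError("tour decodes to an empty genome")
    return Genome(name, chromosomes)


def reconstruct_ancestors(tree: Tree, enc: BinaryEncoding,
                          model: TransitionModel, threshold: float = 0.5,
                          epsilon: float = 1e-6, mode: str = "auto",
                          seed: int = 0
                          ) -> tuple[GenomeDocument, PosteriorTable]:
    """Full small-phylogeny stage for every internal node of ``tree``."""
    post = marginal_posteriors(tree, enc, model)
    contents = infer_gene_content(post, threshold=threshold)
    genomes = []
    for node in post.nodes:
        instance = build_tsp(contents[node], epsilon=epsilon)
        tour = solve_tsp(instance, mode=mode, seed=seed)
        genomes.append(assemble_genome(tour, instance, name=node))
    return GenomeDocument(genomes), post
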