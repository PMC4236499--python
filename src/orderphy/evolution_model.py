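"""The asymmetric two-state substitution model and tree likelihoods.

Characters are presence/absence (1/0) of adjacencies, telomeres, and gene
families.  Under a uniform double-cut-and-join (DCJ) process a genome with
n genes and O(1) chromosomes has n+O(1) adjacencies, so one DCJ destroys a
fixed present adjacency with probability 2/(n+O(1)); with on the order of
2n^2 possible adjacencies, a fixed absent adjacency is created with
probability 2/(2n^2+O(n)).  Loss is therefore roughly 2n times more likely
than gain, and that ratio — not the individual per-event probabilities —
is what the continuous-time model embeds: branch lengths absorb the event
count.

Rates are normalized so that one unit of branch length equals one expected
state change per character at stationarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .genome_core import BinaryEncoding
from .tree import Node, Tree, TreeError


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionModel:
    """Two-state continuous-time chain with loss/gain rate ratio ``ratio``.

    ``gain_rate`` is the 0->1 rate, ``loss_rate`` the 1->0 rate; the
    stationary distribution is pi1 = 1/(1+ratio).
    """

    n: int
    ratio: float
    gain_rate: float
    loss_rate: float

    @property
    def stationary(self) -> np.ndarray:
        r = self.ratio
        return np.array([r / (1.0 + r), 1.0 / (1.0 + r)])

    @property
    def total_rate(self) -> float:
        return self.gain_rate + self.loss_rate


def make_model(n: int, ratio: Optional[float] = None) -> TransitionModel:
    """Model for a collection with ``n`` distinct gene families.

    The loss/gain rate ratio defaults to 2n (loss is ~2n times more likely
    than gain per DCJ event); rates are scaled so the expected number of
    changes per unit time at stationarity is 1.
    """
    if n < 1:
        raise ModelError("need at least one gene family")
    r = float(ratio) if ratio is not None else 2.0 * n
    if r <= 0:
        raise ModelError("rate ratio must be positive")
    # flux normalization: pi0*q01 + pi1*q10 = 2*pi0*q01 = 1
    gain = (1.0 + r) / (2.0 * r)
    loss = r * gain
    return TransitionModel(n=n, ratio=r, gain_rate=gain, loss_rate=loss)


def transition_matrix(model: TransitionModel, t: float) -> np.ndarray:
    """Closed-form P(t) of the two-state chain; rows are origin states."""
    if t < 0:
        raise ModelError("branch length must be non-negative")
    pi0, pi1 = model.stationary
    decay = math.exp(-model.total_rate * t)
    p01 = pi1 * (1.0 - decay)
    p10 = pi0 * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# pruning machinery


class LikelihoodWorkspace:
    """Conditional-likelihood tables for one (tree, encoding, model) triple.

    Holds the downward (Felsenstein) partials per node and, on demand, the
    outward partials needed for per-branch optimization and marginal
    ancestral posteriors.  Partials are scaled per node per character to
    avoid underflow; scale logs are accumulated separately.
    """

    def __init__(self, tree: Tree, enc: BinaryEncoding,
                 model: TransitionModel,
                 weights: Optional[np.ndarray] = None) -> None:
        leaf_names = sorted(tree.leaf_names())
        taxa = sorted(enc.taxa)
        if leaf_names != taxa:
            extra = sorted(set(leaf_names) ^ set(taxa))
            raise TreeError(f"tree leaves and encoding taxa differ: {extra}")
        for node in tree.postorder():
            if node.parent is not None and node.length is None:
                raise TreeError("tree has missing branch lengths")
        self.tree = tree
        self.enc = enc
        self.model = model
        self.n_chars = enc.n_characters
        self.weights = (np.ones(self.n_chars) if weights is None
                        else np.asarray(weights, dtype=float))
        self._leaf_row = {t: enc.matrix[i].astype(int)
                          for i, t in enumerate(enc.taxa)}
        self.nodes = list(tree.postorder())  # root last
        self.refresh()

    def refresh(self) -> None:
        """Recompute downward partials after any branch-length change."""
        model = self.model
        self.P = {}  # id(node) -> transition matrix of the edge above it
        self.down: dict[int, np.ndarray] = {}
        self.down_scale: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.parent is not None:
                self.P[id(node)] = transition_matrix(model, node.length)
            if node.is_leaf:
                states = self._leaf_row[node.name]
                part = np.zeros((self.n_chars, 2))
                part[np.arange(self.n_chars), states] = 1.0
                self.down[id(node)] = part
                self.down_scale[id(node)] = np.zeros(self.n_chars)
            else:
                part = np.ones((self.n_chars, 2))
                scale = np.zeros(self.n_chars)
                for c in node.children:
                    part = part * (self.down[id(c)] @ self.P[id(c)].T)
                    scale = scale + self.down_scale[id(c)]
                m = part.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                part = part / safe[:, None]
                with np.errstate(divide="ignore"):
                    scale = scale + np.where(m > 0, np.log(safe), -np.inf)
                self.down[id(node)] = part
                self.down_scale[id(node)] = scale

    def log_likelihood(self) -> float:
        pi = self.model.stationary
        root = self.nodes[-1]
        site = self.down[id(root)] @ pi
        with np.errstate(divide="ignore"):
            ll = np.log(site) + self.down_scale[id(root)]
        return float(np.dot(self.weights, ll))

    def outward(self) -> tuple[dict, dict]:
        """Outward partials: for each non-root node v with parent p,
        ``out[v][c, s]`` is the (scaled) likelihood of all data outside the
        subtree of v, as a function of the state s *at p*, including the
        root prior.  Returns (out, out_scale)."""
        pi = self.model.stationary
        out: dict[int, np.ndarray] = {}
        out_scale: dict[int, np.ndarray] = {}
        root = self.nodes[-1]
        # lifted down-partials: M_w[c, s_parent] = sum_s P[s_parent, s] D_w[c, s]
        lifted = {id(n): self.down[id(n)] @ self.P[id(n)].T
                  for n in self.nodes if n.parent is not None}
        for node in reversed(self.nodes):  # preorder-ish: root first
            if node.is_leaf:
                continue
            if node is root:
                base = np.broadcast_to(pi, (self.n_chars, 2)).copy()
                base_scale = np.zeros(self.n_chars)
            else:
                # lift this node's own outward through its edge
                base = out[id(node)] @ self.P[id(node)]
                base_scale = out_scale[id(node)]
            for child in node.children:
                prod = base.copy()
                scale = base_scale + 0.0
                for sib in node.children:
                    if sib is child:
                        continue
                    prod = prod * lifted[id(sib)]
                    scale = scale + self.down_scale[id(sib)]
                m = prod.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                prod = prod / safe[:, None]
                with np.errstate(divide="ignore"):
                    scale = scale + np.where(m > 0, np.log(safe), -np.inf)
                out[id(child)] = prod
                out_scale[id(child)] = scale
        return out, out_scale

    def marginal_posteriors_node(self, out, node: Node) -> np.ndarray:
        """Posterior P(state 1 | data) per character at ``node``."""
        if node is self.nodes[-1]:
            joint = self.down[id(node)] * self.model.stationary
        else:
            lifted_out = out[id(node)] @ self.P[id(node)]
            joint = self.down[id(node)] * lifted_out
        denom = joint.sum(axis=1)
        safe = np.where(denom > 0, denom, 1.0)
        post1 = np.where(denom > 0, joint[:, 1] / safe, 0.5)
        return post1


def log_likelihood(tree: Tree, enc: BinaryEncoding,
                   model: TransitionModel) -> float:
    """Felsenstein-pruning log-likelihood over independent characters.

    The root prior is the stationary distribution; reversibility of the
    two-state chain makes the result invariant to root placement.
    """
    return LikelihoodWorkspace(tree, enc, model).log_likelihood()


# ---------------------------------------------------------------------------
# pairwise distances


def pairwise_ml_distance(row_i: np.ndarray, row_j: np.ndarray,
                         model: TransitionModel, cap: float = 5.0,
                         tol: float = 1e-8) -> float:
    """ML branch length separating two encoded rows under the model.

    Maximizes the reversible two-sequence likelihood
    ``prod_c pi_{x_c} P(x_c -> y_c; t)`` over ``t in [0, cap]``; saturated
    pairs return the cap.
    """
    x = np.asarray(row_i, dtype=int)
    y = np.asarray(row_j, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ModelError("rows must be equal-length vectors")
    if x.size == 0:
        raise ModelError("rows must be non-empty")
    counts = np.bincount(2 * x + y, minlength=4).astype(float)  # 00,01,10,11
    if counts[1] == 0 and counts[2] == 0:
        return 0.0
    pi = model.stationary

    def neg_ll(t: float) -> float:
        P = transition_matrix(model, t)
        joint = (pi[:, None] * P).ravel()  # order 00,01,10,11
        with np.errstate(divide="ignore"):
            lj = np.log(joint)
        val = np.where(counts > 0, counts * lj, 0.0).sum()
        return -val

    t_hat = _bracketed_minimize(neg_ll, lo=1e-9, hi=cap, xatol=tol)
    # saturation: the likelihood plateaus to machine precision long before
    # the cap; report the cap when the cap is as good as the located optimum
    if neg_ll(cap) <= neg_ll(t_hat) + 1e-10:
        return cap
    return t_hat


def _bracketed_minimize(fun, lo: float, hi: float, xatol: float) -> float:
    """Minimize a 1-D branch-length objective over [lo, hi].

    Branch-length likelihoods have a narrow basin near zero and a long
    flat saturation plateau, so a first pass runs on a log scale before a
    linear refinement around the located basin.
    """
    llo, lhi = math.log(lo), math.log(hi)
    res = minimize_scalar(lambda u: fun(math.exp(u)), bounds=(llo, lhi),
                          method="bounded", options={"xatol": 1e-6})
    t0 = math.exp(float(res.x))
    res = minimize_scalar(fun, bounds=(max(lo, t0 / 4.0), min(hi, t0 * 4.0)),
                          method="bounded", options={"xatol": xatol})
    return float(res.x) if res.fun <= fun(t0) else t0


def distance_matrix(enc: BinaryEncoding, model: TransitionModel,
                    cap: float = 5.0) -> np.ndarray:
    """Symmetric matrix of pairwise ML distances between encoded taxa."""
    k = len(enc.taxa)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = pairwise_ml_distance(
                enc.matrix[i], enc.matrix[j], model, cap=cap)
    return d
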