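"""Ground-truthed genome evolution along a tree.

Evolves a root genome down a phylogeny under double-cut-and-join (DCJ)
rearrangements plus segmental deletions, insertions (of brand-new gene
families), and duplications, logging every event so any node's genome can
be replayed exactly.  A DCJ cuts two of the genome's current adjacencies
or telomeres, chosen uniformly at random, and rejoins the four loose ends
one of the two alternative ways — inversions, translocations, fusions,
fissions, excisions and (re)integrations all emerge as special cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome_core import Chromosome, Genome, GenomeError
from .io_formats import GenomeDocument
from .tree import Node, Tree


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions of the generator.

    Defaults emulate a moderate-divergence dataset: 12 taxa, a single
    linear chromosome of 100 genes, 10/3 expected events per branch of
    which 90% are DCJs and the rest split evenly among deletions,
    insertions and duplications (segment lengths geometric with p=0.5).
    """

    taxa: int = 12
    n_genes: int = 100
    n_chromosomes: int = 1
    circular: bool = False
    #: fixed number of events on every branch (fractional part applied as a
    #: Bernoulli extra); set to None to draw Poisson counts with mean
    #: branch length x rate_scale instead
    events_per_branch: Optional[float] = 10.0 / 3.0
    rate_scale: float = 1.0
    p_dcj: float = 0.9
    p_deletion: float = 1.0 / 30.0
    p_insertion: float = 1.0 / 30.0
    p_duplication: float = 1.0 / 30.0
    geometric_p: float = 0.5
    mean_branch_length: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_dcj + self.p_deletion + self.p_insertion + self.p_duplication
        if abs(total - 1.0) > 1e-12:
            raise SimulationError("event-type probabilities must sum to 1")
        if self.n_genes < 1:
            raise SimulationError("need at least one gene")

    def event_probs(self) -> list[float]:
        return [self.p_dcj, self.p_deletion, self.p_insertion,
                self.p_duplication]


@dataclass
class Event:
    """One replayable evolutionary event on a branch."""

    branch: str  # name of the child node of the branch
    kind: str  # dcj | deletion | insertion | duplication
    params: dict


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["branch\tkind\tparams"]
        for e in self.events:
            lines.append(f"{e.branch}\t{e.kind}\t{json.dumps(e.params, sort_keys=True)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# elementary operations


def _gap_count(chrom: Chromosome) -> int:
    """Number of adjacencies+telomeres (cut sites) of a chromosome."""
    return len(chrom) if chrom.circular else len(chrom) + 1


class _Piece:
    """A linear run of signed genes with two joinable (or sealed) ports."""

    __slots__ = ("genes", "left", "right")

    def __init__(self, genes: list[int], left: Optional[str],
                 right: Optional[str]) -> None:
        self.genes = genes
        self.left = left  # cut-end label, or None for a sealed telomere
        self.right = right

    def reverse(self) -> None:
        self.genes = [-g for g in reversed(self.genes)]
        self.left, self.right = self.right, self.left


def apply_dcj(genome: Genome, cut1: tuple[int, int], cut2: tuple[int, int],
              rejoin: int) -> Genome:
    """Apply one DCJ specified by two cut sites and a rejoin choice.

    A cut site is (chromosome index, gap index); for a linear chromosome
    with k genes the gaps run 0..k (0 and k being the telomeres), for a
    circular one 0..k-1 (gap g sits before the gene at position g).  With
    cut ends labeled a|b and c|d, ``rejoin=0`` joins {a,c} and {b,d},
    ``rejoin=1`` joins {a,d} and {b,c} (the original pairing is {a,b},
    {c,d}).  The gene multiset is always conserved.
    """
    if rejoin not in (0, 1):
        raise SimulationError("rejoin choice must be 0 or 1")
    if cut1 == cut2:
        raise SimulationError("the two cut sites must be distinct")
    for ci, gap in (cut1, cut2):
        if not (0 <= ci < len(genome.chromosomes)):
            raise SimulationError(f"no chromosome {ci}")
        if not (0 <= gap < _gap_count(genome.chromosomes[ci])):
            raise SimulationError(f"no gap {gap} on chromosome {ci}")

    pieces: list[_Piece] = []
    untouched: list[Chromosome] = []
    cuts_by_chrom: dict[int, list[tuple[int, str]]] = {}
    # label convention per cut: 'x' = end of the left part, 'y' = start of
    # the right part; cut1 -> (a, b), cut2 -> (c, d)
    cut_labels = {0: ("a", "b"), 1: ("c", "d")}
    for k, (ci, gap) in enumerate((cut1, cut2)):
        cuts_by_chrom.setdefault(ci, []).append((gap, k))

    for ci, chrom in enumerate(genome.chromosomes):
        if ci not in cuts_by_chrom:
            untouched.append(chrom)
            continue
        cuts = sorted(cuts_by_chrom[ci])
        g = list(chrom.genes)
        if not chrom.circular:
            if len(cuts) == 1:
                gap, k = cuts[0]
                x, y = cut_labels[k]
                pieces.append(_Piece(g[:gap], None, x))
                pieces.append(_Piece(g[gap:], y, None))
            else:
                (g1, k1), (g2, k2) = cuts
                x1, y1 = cut_labels[k1]
                x2, y2 = cut_labels[k2]
                pieces.append(_Piece(g[:g1], None, x1))
                pieces.append(_Piece(g[g1:g2], y1, x2))
                pieces.append(_Piece(g[g2:], y2, None))
        else:
            if len(cuts) == 1:
                gap, k = cuts[0]
                x, y = cut_labels[k]
                pieces.append(_Piece(g[gap:] + g[:gap], y, x))
            else:
                (g1, k1), (g2, k2) = cuts
                x1, y1 = cut_labels[k1]
                x2, y2 = cut_labels[k2]
                pieces.append(_Piece(g[g1:g2], y1, x2))
                pieces.append(_Piece(g[g2:] + g[:g1], y2, x1))

    joins = ([("a", "c"), ("b", "d")] if rejoin == 0
             else [("a", "d"), ("b", "c")])

    circulars: list[Chromosome] = []

    def find(label: str) -> Optional[_Piece]:
        for p in pieces:
            if p.left == label or p.right == label:
                return p
        return None

    for x, y in joins:
        px, py = find(x), find(y)
        if px is None or py is None:
            # a label may be missing only if its piece got circularized,
            # which cannot happen before its join is processed
            raise SimulationError("internal error: dangling cut end")
        if px is py:
            # both ends of the same piece: circularize
            if px.genes:
                circulars.append(Chromosome(px.genes, circular=True))
            pieces.remove(px)
            continue
        if px.right != x:
            px.reverse()
        if py.left != y:
            py.reverse()
        merged = _Piece(px.genes + py.genes, px.left, py.right)
        pieces.remove(px)
        pieces.remove(py)
        pieces.append(merged)

    chroms = untouched + [Chromosome(p.genes, circular=False)
                          for p in pieces if p.genes] + circulars
    if not chroms:
        raise SimulationError("DCJ produced an empty genome")
    return Genome(genome.name, chroms)


def apply_deletion(genome: Genome, chrom: int, start: int,
                   length: int) -> Genome:
    """Delete ``length`` contiguous genes starting at position ``start``."""
    c = genome.chromosomes[chrom]
    if not (0 <= start and start + length <= len(c) and length >= 1):
        raise SimulationError("invalid deletion coordinates")
    remaining = list(c.genes[:start]) + list(c.genes[start + length:])
    chroms = list(genome.chromosomes)
    if remaining:
        chroms[chrom] = Chromosome(remaining, c.circular)
    else:
        del chroms[chrom]  # full-chromosome deletion drops the chromosome
    if not chroms:
        raise SimulationError(
            "deletion annihilated the genome; lower the deletion rate")
    return Genome(genome.name, chroms)


def apply_insertion(genome: Genome, chrom: int, position: int,
                    length: int, first_id: int) -> Genome:
    """Insert ``length`` brand-new families ``first_id..`` at a gap."""
    c = genome.chromosomes[chrom]
    if not (0 <= position <= len(c)) or length < 1:
        raise SimulationError("invalid insertion coordinates")
    seg = list(range(first_id, first_id + length))
    genes = list(c.genes[:position]) + seg + list(c.genes[position:])
    chroms = list(genome.chromosomes)
    chroms[chrom] = Chromosome(genes, c.circular)
    return Genome(genome.name, chroms)


def apply_duplication(genome: Genome, src_chrom: int, start: int,
                      length: int, dest_chrom: int, dest_pos: int,
                      inverted: bool = False) -> Genome:
    """Copy a contiguous segment and insert it (possibly inverted)."""
    c = genome.chromosomes[src_chrom]
    if not (0 <= start and start + length <= len(c) and length >= 1):
        raise SimulationError("invalid duplication source coordinates")
    seg = list(c.genes[start:start + length])
    if inverted:
        seg = [-g for g in reversed(seg)]
    d = genome.chromosomes[dest_chrom]
    if not (0 <= dest_pos <= len(d)):
        raise SimulationError("invalid duplication destination")
    genes = list(d.genes[:dest_pos]) + seg + list(d.genes[dest_pos:])
    chroms = list(genome.chromosomes)
    chroms[dest_chrom] = Chromosome(genes, d.circular)
    return Genome(genome.name, chroms)


def replay(root: Genome, log: EventLog, branch: list[str]) -> Genome:
    """Re-apply the logged events of the given branch sequence to root."""
    g = Genome(root.name, root.chromosomes)
    for name in branch:
        for e in log.events:
            if e.branch != name:
                continue
            g = _apply_event(g, e)
    return g


def _apply_event(g: Genome, e: Event) -> Genome:
    p = e.params
    if e.kind == "dcj":
        return apply_dcj(g, tuple(p["cut1"]), tuple(p["cut2"]), p["rejoin"])
    if e.kind == "deletion":
        return apply_deletion(g, p["chrom"], p["start"], p["length"])
    if e.kind == "insertion":
        return apply_insertion(g, p["chrom"], p["position"], p["length"],
                               p["first_id"])
    if e.kind == "duplication":
        return apply_duplication(g, p["src_chrom"], p["start"], p["length"],
                                 p["dest_chrom"], p["dest_pos"],
                                 p["inverted"])
    raise SimulationError(f"unknown event kind {e.kind!r}")


# ---------------------------------------------------------------------------
# random generation


def random_tree(taxa: int, seed: int,
                mean_branch_length: float = 0.1) -> Tree:
    """Random binary unrooted topology by successive leaf attachment.

    Leaves are named T1..Tn; branch lengths are exponential with the given
    mean; deterministic for a given seed.
    """
    if taxa < 3:
        raise SimulationError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = Node()
    for i in range(3):
        root.add(Node(f"T{i + 1}"))
    tree = Tree(root)
    for i in range(3, taxa):
        # pick a uniformly random edge and attach the new leaf on it
        edges = [n for n in tree.postorder() if n.parent is not None]
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent
        mid = Node()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(f"T{i + 1}"))
    for n in tree.postorder():
        if n.parent is not None:
            n.length = float(rng.exponential(mean_branch_length))
    return tree


def root_genome(config: SimulationConfig, name: str = "root") -> Genome:
    """Identity gene order 1..n split across the configured chromosomes."""
    n, k = config.n_genes, max(1, config.n_chromosomes)
    per = [n // k + (1 if i < n % k else 0) for i in range(k)]
    chroms, next_id = [], 1
    for size in per:
        if size == 0:
            continue
        chroms.append(Chromosome(range(next_id, next_id + size),
                                 circular=config.circular))
        next_id += size
    return Genome(name, chroms)


def _random_cut_pair(genome: Genome, rng) -> tuple[tuple[int, int], tuple[int, int]]:
    sites = [(ci, gap) for ci, c in enumerate(genome.chromosomes)
             for gap in range(_gap_count(c))]
    if len(sites) < 2:
        raise SimulationError("genome too small for a DCJ")
    i, j = rng.choice(len(sites), size=2, replace=False)
    return sites[int(i)], sites[int(j)]


def _geometric(rng, p: float, cap: int) -> int:
    return min(int(rng.geometric(p)), cap)


def _random_event(genome: Genome, config: SimulationConfig, rng,
                  next_id: int) -> tuple[Event, Genome, int]:
    kind = ["dcj", "deletion", "insertion", "duplication"][
        int(rng.choice(4, p=config.event_probs()))]
    sizes = [len(c) for c in genome.chromosomes]
    total = sum(sizes)
    if kind == "deletion" and total <= 1:
        kind = "dcj"  # cannot delete the last gene
    if kind == "dcj":
        cut1, cut2 = _random_cut_pair(genome, rng)
        params = {"cut1": list(cut1), "cut2": list(cut2),
                  "rejoin": int(rng.integers(0, 2))}
        ev = Event("", "dcj", params)
        return ev, apply_dcj(genome, cut1, cut2, params["rejoin"]), next_id
    if kind == "deletion":
        ci = int(rng.choice(len(sizes), p=np.array(sizes) / total))
        k = sizes[ci]
        max_len = min(k, total - 1)  # never annihilate the genome
        length = _geometric(rng, config.geometric_p, max_len)
        start = int(rng.integers(0, k - length + 1))
        params = {"chrom": ci, "start": start, "length": length}
        ev = Event("", "deletion", params)
        return ev, apply_deletion(genome, ci, start, length), next_id
    if kind == "insertion":
        ci = int(rng.choice(len(sizes), p=np.array(sizes) / total))
        position = int(rng.integers(0, sizes[ci] + 1))
        length = _geometric(rng, config.geometric_p, config.n_genes)
        params = {"chrom": ci, "position": position, "length": length,
                  "first_id": next_id}
        ev = Event("", "insertion", params)
        return (ev, apply_insertion(genome, ci, position, length, next_id),
                next_id + length)
    # duplication
    ci = int(rng.choice(len(sizes), p=np.array(sizes) / total))
    k = sizes[ci]
    length = _geometric(rng, config.geometric_p, k)
    start = int(rng.integers(0, k - length + 1))
    dj = int(rng.choice(len(sizes), p=np.array(sizes) / total))
    dest_pos = int(rng.integers(0, sizes[dj] + 1))
    inverted = bool(rng.integers(0, 2))
    params = {"src_chrom": ci, "start": start, "length": length,
              "dest_chrom": dj, "dest_pos": dest_pos, "inverted": inverted}
    ev = Event("", "duplication", params)
    return (ev, apply_duplication(genome, ci, start, length, dj, dest_pos,
                                  inverted), next_id)


def evolve(tree: Tree, config: SimulationConfig
           ) -> tuple[GenomeDocument, GenomeDocument, EventLog]:
    """Evolve the root genome along ``tree``.

    Per branch the event count is the configured fixed ``events_per_branch``
    (or Poisson with mean branch length x ``rate_scale`` when that is
    None); event kinds are
    drawn from the configured distribution and DCJ cut sites uniformly
    over the genome's current adjacencies and telomeres.  Returns the leaf
    document, the ancestor document (internal nodes, named A1.. in
    preorder), and the replayable event log.
    """
    rng = np.random.default_rng(config.seed)
    tree.name_ancestors()
    root = root_genome(config, name=tree.root.name or "A1")
    genomes: dict[str, Genome] = {root.name: root}
    log = EventLog()
    next_id = config.n_genes + 1
    order = [n for n in tree.preorder() if n.parent is not None]
    for node in order:
        g = genomes[node.parent.name]
        g = Genome(node.name, g.chromosomes)
        if config.events_per_branch is not None:
            # fixed per-branch count; a fractional part becomes a Bernoulli
            # extra so non-integer settings keep their mean
            base, frac = divmod(config.events_per_branch, 1.0)
            count = int(base) + (1 if rng.random() < frac else 0)
        else:
            count = int(rng.poisson((node.length or 0.0) * config.rate_scale))
        for _ in range(count):
            ev, g, next_id = _random_event(g, config, rng, next_id)
            ev.branch = node.name
            log.events.append(ev)
        genomes[node.name] = g
    leaves = GenomeDocument([genomes[n.name] for n in tree.postorder()
                             if n.is_leaf])
    ancestors = GenomeDocument([genomes[n.name] for n in tree.preorder()
                                if not n.is_leaf])
    return leaves, ancestors, log
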