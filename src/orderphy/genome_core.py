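"""Genomes, adjacencies, and the presence/absence binary encoding.

A genome is one or more chromosomes, each an ordered list of signed gene
(or synteny-block) identifiers; the sign records the strand.  Two genes
``i`` and ``j`` form an adjacency ``(i, j)`` when ``i`` is immediately
followed by ``j`` — equivalently, when ``-j`` is immediately followed by
``-i``, so an adjacency is invariant under reading the reverse strand.
On a linear chromosome the outermost genes are adjacent to the extremity
marker ``o`` (telomeres).

The binary encoding turns a genome collection into a taxa x characters 0/1
matrix: one column per distinct adjacency or telomere observed anywhere in
the collection, plus one column per gene family.  This matrix is the
pseudo-alignment on which likelihood-based tree inference operates.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Chromosome-extremity marker ("o").  Gene identifiers are non-zero signed
#: integers, so 0 is free to stand for the extremity.
O = 0


class GenomeError(ValueError):
    """Invalid genome, chromosome or adjacency construction."""


def _ordkey(x: int) -> float:
    """Total order o < ... < -2 < -1 < 1 < 2 < ... used for canonical picks."""
    return float("-inf") if x == O else float(x)


@dataclass(frozen=True)
class Adjacency:
    """A canonicalized adjacency or telomere.

    ``Adjacency(i, j)`` and ``Adjacency(-j, -i)`` construct the same object;
    a telomere ``(k, o)`` is stored as ``(o, -k)``.  Equality and hashing
    respect this canonical form.
    """

    left: int
    right: int

    def __post_init__(self) -> None:
        left, right = self.left, self.right
        if left == O and right == O:
            raise GenomeError("adjacency cannot join two extremity markers")
        # the two ordered readings of the same adjacency
        alt = (-right, -left)
        if (_ordkey(alt[0]), _ordkey(alt[1])) < (_ordkey(left), _ordkey(right)):
            left, right = alt
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def is_telomere(self) -> bool:
        return self.left == O or self.right == O

    def genes(self) -> tuple[int, ...]:
        """Unsigned gene families touched by this adjacency."""
        return tuple(abs(x) for x in (self.left, self.right) if x != O)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        def show(x: int) -> str:
            return "o" if x == O else str(x)

        return f"({show(self.left)},{show(self.right)})"


def canonical_adjacency(left: int, right: int) -> Adjacency:
    """Return the canonical representative of the adjacency ``(left, right)``."""
    return Adjacency(left, right)


@dataclass(frozen=True)
class Chromosome:
    """An ordered, signed gene list with a linear/circular flag."""

    genes: tuple[int, ...]
    circular: bool = False

    def __init__(self, genes: Iterable[int], circular: bool = False) -> None:
        genes = tuple(int(g) for g in genes)
        if not genes:
            raise GenomeError("chromosome must contain at least one gene")
        if any(g == 0 for g in genes):
            raise GenomeError("gene id 0 is not allowed (0 has no sign)")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "circular", bool(circular))

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "Chromosome":
        """The same chromosome read on the reverse strand."""
        return Chromosome(tuple(-g for g in reversed(self.genes)), self.circular)

    def canonical(self) -> tuple:
        """Representation invariant under flips (and rotations if circular).

        The leading element flags circularity so linear and circular
        chromosomes never compare equal.
        """
        if not self.circular:
            return (0,) + min(self.genes, self.reversed().genes)
        best = None
        for cand in (self.genes, self.reversed().genes):
            for i in range(len(cand)):
                rot = cand[i:] + cand[:i]
                if best is None or rot < best:
                    best = rot
        return (1,) + best


@dataclass(frozen=True)
class Genome:
    """A named collection of chromosomes."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __init__(self, name: str, chromosomes: Iterable[Chromosome]) -> None:
        chromosomes = tuple(chromosomes)
        if not name:
            raise GenomeError("genome name must be non-empty")
        if not chromosomes:
            raise GenomeError(f"genome {name!r} has zero chromosomes")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "chromosomes", chromosomes)

    def gene_count(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def gene_families(self) -> set[int]:
        return {abs(g) for c in self.chromosomes for g in c.genes}

    def canonical(self) -> tuple:
        """Genome identity up to chromosome order and whole-chromosome flips."""
        return tuple(sorted(c.canonical() for c in self.chromosomes))


def extract_adjacencies(genome: Genome) -> Counter:
    """Multiset of canonical adjacencies and telomeres of ``genome``.

    A linear chromosome with k genes contributes k-1 adjacencies and two
    telomeres; a circular chromosome with k genes contributes k adjacencies
    and no telomeres.
    """
    out: Counter = Counter()
    for chrom in genome.chromosomes:
        g = chrom.genes
        for a, b in zip(g, g[1:]):
            out[Adjacency(a, b)] += 1
        if chrom.circular:
            out[Adjacency(g[-1], g[0])] += 1
        else:
            out[Adjacency(O, g[0])] += 1
            out[Adjacency(g[-1], O)] += 1
    return out


# ---------------------------------------------------------------------------
# binary encoding


ADJACENCY = "adjacency"
TELOMERE = "telomere"
GENE_FAMILY = "gene_family"


@dataclass(frozen=True)
class CharacterMeta:
    """Metadata for one encoding column."""

    kind: str  # ADJACENCY | TELOMERE | GENE_FAMILY
    payload: object  # Adjacency for adjacency/telomere columns, int family id

    def __post_init__(self) -> None:
        if self.kind in (ADJACENCY, TELOMERE):
            if not isinstance(self.payload, Adjacency):
                raise GenomeError(f"{self.kind} column needs an Adjacency payload")
            if (self.payload.is_telomere) != (self.kind == TELOMERE):
                raise GenomeError("payload kind does not match column kind")
        elif self.kind == GENE_FAMILY:
            if not isinstance(self.payload, int) or self.payload <= 0:
                raise GenomeError("gene_family column needs a positive family id")
        else:
            raise GenomeError(f"unknown column kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == GENE_FAMILY:
            return f"gene:{self.payload}"
        return f"{'tel' if self.kind == TELOMERE else 'adj'}:{self.payload!r}"


@dataclass
class BinaryEncoding:
    """Taxa x characters presence/absence matrix with per-column metadata."""

    taxa: list[str]
    columns: list[CharacterMeta]
    matrix: np.ndarray  # shape (len(taxa), len(columns)), dtype uint8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (len(self.taxa), len(self.columns)):
            raise GenomeError("encoding matrix shape does not match taxa/columns")

    @property
    def n_characters(self) -> int:
        return len(self.columns)

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def column_index(self) -> dict:
        return {meta.payload: j for j, meta in enumerate(self.columns)
                if meta.kind != GENE_FAMILY}

    def adjacency_column_indices(self) -> np.ndarray:
        return np.array([j for j, m in enumerate(self.columns)
                         if m.kind in (ADJACENCY, TELOMERE)], dtype=int)

    def gene_column_indices(self) -> np.ndarray:
        return np.array([j for j, m in enumerate(self.columns)
                         if m.kind == GENE_FAMILY], dtype=int)

    def resample_columns(self, indices: Sequence[int]) -> "BinaryEncoding":
        """Column-resampled copy (bootstrap replicate); invariants relaxed."""
        idx = np.asarray(indices, dtype=int)
        return BinaryEncoding(
            taxa=list(self.taxa),
            columns=[self.columns[j] for j in idx],
            matrix=self.matrix[:, idx].copy(),
        )

    def to_tsv(self) -> str:
        """Debug export: taxa rows, one descriptor-headed 0/1 column each."""
        import pandas as pd

        df = pd.DataFrame(self.matrix, index=self.taxa,
                          columns=[m.describe() for m in self.columns])
        return df.to_csv(sep="\t", index_label="taxon")


def build_encoding(genomes: Sequence[Genome]) -> BinaryEncoding:
    """Encode a genome collection as a presence/absence matrix.

    Columns are all distinct canonical adjacencies/telomeres observed in at
    least one genome, in first-observation order, followed by one column per
    distinct gene family in ascending family-id order.  Multiplicities are
    collapsed to presence (a deliberate information loss: with duplicated
    genes the encoding is not one-to-one on genomes).
    """
    genomes = list(genomes)
    if len(genomes) < 3:
        raise GenomeError("need at least 3 genomes to build an encoding")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        raise GenomeError("genome names must be unique")

    adj_sets = [set(extract_adjacencies(g)) for g in genomes]
    adj_order: list[Adjacency] = []
    seen: set[Adjacency] = set()
    for g in genomes:
        for adj in _iter_adjacencies_in_order(g):
            if adj not in seen:
                seen.add(adj)
                adj_order.append(adj)
    families = sorted(set().union(*(g.gene_families() for g in genomes)))

    columns = [CharacterMeta(TELOMERE if a.is_telomere else ADJACENCY, a)
               for a in adj_order]
    columns += [CharacterMeta(GENE_FAMILY, int(f)) for f in families]

    matrix = np.zeros((len(genomes), len(columns)), dtype=np.uint8)
    fam_pos = {f: len(adj_order) + i for i, f in enumerate(families)}
    adj_pos = {a: j for j, a in enumerate(adj_order)}
    for i, g in enumerate(genomes):
        for a in adj_sets[i]:
            matrix[i, adj_pos[a]] = 1
        for f in g.gene_families():
            matrix[i, fam_pos[f]] = 1
    return BinaryEncoding(taxa=names, columns=columns, matrix=matrix)


def _iter_adjacencies_in_order(genome: Genome) -> Iterator[Adjacency]:
    """Adjacencies of a genome in along-the-chromosome traversal order."""
    for chrom in genome.chromosomes:
        g = chrom.genes
        if not chrom.circular:
            yield Adjacency(O, g[0])
        for a, b in zip(g, g[1:]):
            yield Adjacency(a, b)
        if chrom.circular:
            yield Adjacency(g[-1], g[0])
        else:
            yield Adjacency(g[-1], O)


def adjacency_state_space_size(n: int) -> int:
    """Number of extremity pairs available to a genome on n gene families.

    Each gene contributes two extremities (head and tail) and a linear
    chromosome end contributes one of two end markers; counting unordered
    pairs over these 2n+2 symbols by explicit enumeration gives
    binom(2n+2, 2), the denominator scale of the gain (0 -> 1) transition.
    """
    symbols = [("h", i) for i in range(1, n + 1)]
    symbols += [("t", i) for i in range(1, n + 1)]
    symbols += [("cap", 1), ("cap", 2)]
    return sum(1 for _ in itertools.combinations(symbols, 2))


def distinct_adjacency_count(n: int) -> int:
    """Count of distinct canonical adjacencies+telomeres over families 1..n.

    Computed by enumeration of all signed ordered pairs plus telomeres,
    quotiented by the reverse-strand identity; equals 2n^2 + n.
    """
    objs = set()
    ids = [i for i in range(-n, n + 1) if i != 0]
    for a in ids:
        for b in ids:
            try:
                objs.add(Adjacency(a, b))
            except GenomeError:  # pragma: no cover
                pass
    # drop self-extremity "foldback" pairs (a, -a): not a pair of two
    # distinct extremities, hence not a realizable adjacency
    objs = {o for o in objs if not (o.right == -o.left)}
    for a in ids:
        objs.add(Adjacency(O, a))
    return len(objs)


def decode_genome(adjacencies: Iterable[Adjacency], name: str = "decoded") -> Genome:
    """Rebuild a duplication-free genome from its adjacency/telomere set.

    Walks the adjacency graph over gene extremities: each gene is an edge
    from its tail to its head, each adjacency joins two extremities, and
    telomeres terminate linear chromosomes.  Only valid for genomes without
    duplicated gene families (each extremity used at most once).
    """
    # extremity -> (partner extremity) through an adjacency
    def ext_end(x: int):  # extremity at the end of signed gene x
        return (abs(x), "h" if x > 0 else "t")

    def ext_start(x: int):
        return (abs(x), "t" if x > 0 else "h")

    link: dict = {}
    telo: set = set()
    genes: set[int] = set()
    for adj in adjacencies:
        for g in adj.genes():
            genes.add(g)
        if adj.is_telomere:
            # canonical telomere is (o, g): chromosome starts with g
            telo.add(ext_start(adj.right))
        else:
            a, b = ext_end(adj.left), ext_start(adj.right)
            for e in (a, b):
                if e in link:
                    raise GenomeError(f"extremity {e} used twice; duplicated genes?")
            link[a] = b
            link[b] = a

    visited: set[int] = set()
    chromosomes: list[Chromosome] = []

    def walk(start_gene: int, enter: str) -> tuple[list[int], bool]:
        """Follow gene->adjacency links; returns genes and circular flag."""
        order: list[int] = []
        g, side = start_gene, enter
        while True:
            signed = g if side == "t" else -g
            order.append(signed)
            visited.add(g)
            out = (g, "h" if side == "t" else "t")  # other extremity of g
            if out in telo or out not in link:
                return order, False
            nxt = link[out]
            g, side = nxt
            if g in visited:
                return order, True

    # linear chromosomes first (start from telomeres)
    for (g, side) in sorted(telo):
        if g in visited:
            continue
        order, _ = walk(g, side)
        chromosomes.append(Chromosome(order, circular=False))
    # remaining genes form circular chromosomes
    for g in sorted(genes):
        if g not in visited:
            order, _ = walk(g, "t")
            chromosomes.append(Chromosome(order, circular=True))
    return Genome(name, chromosomes)
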