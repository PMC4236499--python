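"""Reading and writing the GRAPPA/MGR gene-order format and Newick trees.

The gene-order dialect: a FASTA-like header line (``>`` followed by the
genome name) starts each record; the following lines hold whitespace-
separated signed integers, with ``$`` terminating a linear chromosome and
``@`` (a common extension) terminating a circular one.  Example::

    >genomeA
    1 -2 3 $
    4 5 $

All text I/O is UTF-8 with ``\\n`` newlines.
"""

from __future__ import annotations

import io
from typing import Optional

import dendropy

from .genome_core import Chromosome, Genome, GenomeError
from .tree import Node, Tree


class ParseError(ValueError):
    """Malformed input; carries the offending 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None) -> None:
        self.line = line
        if line is not None:
            message = f"{message} at line {line}"
        super().__init__(message)


class GenomeDocument:
    """An ordered collection of uniquely named genomes."""

    def __init__(self, genomes) -> None:
        self.genomes: list[Genome] = list(genomes)
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GenomeError(f"duplicate genome names: {dup}")

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, key):
        if isinstance(key, str):
            for g in self.genomes:
                if g.name == key:
                    return g
            raise KeyError(key)
        return self.genomes[key]

    def names(self) -> list[str]:
        return [g.name for g in self.genomes]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeDocument) and self.genomes == other.genomes


def read_genomes(text: str) -> GenomeDocument:
    """Parse a GRAPPA/MGR document.

    Raises :class:`ParseError` (with a line number) on malformed headers,
    duplicate names, non-integer gene tokens, gene id 0, unterminated
    chromosomes, or records with zero chromosomes.
    """
    genomes: list[Genome] = []
    name: Optional[str] = None
    header_line = 0
    chroms: list[Chromosome] = []
    pending: list[int] = []
    pending_line = 0

    def close_record(line: int) -> None:
        nonlocal name, chroms, pending
        if name is None:
            return
        if pending:
            raise ParseError(
                f"chromosome of genome {name!r} lacks a '$' terminator",
                pending_line)
        if not chroms:
            raise ParseError(f"genome {name!r} has zero chromosomes", header_line)
        genomes.append(Genome(name, chroms))
        name, chroms = None, []

    seen_names: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            close_record(lineno)
            header = line[1:].strip()
            if not header:
                raise ParseError("empty genome name in header", lineno)
            name = header.split()[0]
            if name in seen_names:
                raise ParseError(f"duplicate genome name {name!r}", lineno)
            seen_names.add(name)
            header_line = lineno
            continue
        if name is None:
            raise ParseError("gene data before any '>' header", lineno)
        for tok in line.split():
            if tok in ("$", "@"):
                if not pending:
                    raise ParseError("empty chromosome (terminator with no genes)",
                                     lineno)
                chroms.append(Chromosome(pending, circular=(tok == "@")))
                pending = []
            else:
                try:
                    gene = int(tok)
                except ValueError:
                    raise ParseError(f"gene token {tok!r} is not an integer",
                                     lineno) from None
                if gene == 0:
                    raise ParseError("gene id 0", lineno)
                if not pending:
                    pending_line = lineno
                pending.append(gene)
    close_record(0)
    if not genomes:
        raise ParseError("document contains no genome records", 1)
    return GenomeDocument(genomes)


def write_genomes(doc: GenomeDocument) -> str:
    """Serialize in the exact dialect accepted by :func:`read_genomes`."""
    out = io.StringIO()
    for g in doc:
        out.write(f">{g.name}\n")
        for chrom in g.chromosomes:
            term = "@" if chrom.circular else "$"
            out.write(" ".join(str(x) for x in chrom.genes) + f" {term}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str) -> Tree:
    """Parse a Newick tree (optional branch lengths and internal labels).

    Internal-node labels that are plain integers in [0, 100] are read as
    bootstrap supports as well as names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from None

    def convert(dn) -> Node:
        if dn.is_leaf():
            label = dn.taxon.label if dn.taxon is not None else dn.label
            if not label:
                raise ParseError("empty leaf label in Newick input")
            node = Node(name=label, length=dn.edge.length)
        else:
            node = Node(name=dn.label, length=dn.edge.length)
            if dn.label is not None:
                try:
                    val = float(dn.label)
                    if 0 <= val <= 100:
                        node.support = val
                except ValueError:
                    pass
            for c in dn.child_nodes():
                node.add(convert(c))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return Tree(root)


def write_newick(tree: Tree, with_supports: bool = False) -> str:
    """Serialize to Newick; branch lengths keep 10 significant digits.

    With ``with_supports``, internal nodes annotated with a bootstrap
    support carry it as an integer-percent label, otherwise their name.
    """
    return tree.newick(with_supports=with_supports)
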