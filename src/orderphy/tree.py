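"""A small rooted-representation phylogenetic tree with unrooted semantics.

Trees are stored as rooted node structures; an unrooted binary tree is
represented with a trifurcating root.  Branch lengths live on child nodes
(the edge to the parent); bootstrap supports likewise annotate the edge
above a node.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None,
                 length: Optional[float] = None,
                 support: Optional[float] = None) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Node {self.name or '*'}>"


class Tree:
    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise TreeError(f"no node named {name!r}")

    # -- copying -----------------------------------------------------------

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length, n.support)
            for c in n.children:
                m.add(rec(c))
            return m

        return Tree(rec(self.root))

    # -- serialization -----------------------------------------------------

    def newick(self, with_supports: bool = False) -> str:
        def fmt_len(x: Optional[float]) -> str:
            return "" if x is None else f":{x:.10g}"

        def rec(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}{fmt_len(n.length)}"
            inner = ",".join(rec(c) for c in n.children)
            if with_supports and n.support is not None:
                label = str(int(round(n.support)))
            else:
                label = n.name or ""
            return f"({inner}){label}{fmt_len(n.length)}"

        return rec(self.root) + ";"

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as its canonical side.

        The canonical side of a split is the one *not* containing the
        lexicographically smallest leaf name.
        """
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) != len(self.leaf_names()):
            raise TreeError("duplicate leaf names")
        ref = min(all_leaves)
        out: set[frozenset] = set()
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
                side = below[id(n)]
                if ref in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(side)
        return out

    def edge_bipartition(self, child: Node) -> Optional[frozenset]:
        """Canonical split of the edge above ``child`` (None if trivial)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        side = frozenset(n.name for n in Tree(child).leaves())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            return side
        return None

    # -- rerooting ---------------------------------------------------------

    def reroot_at(self, node: Node) -> None:
        """Make ``node`` the root by reversing parent links along its path."""
        if node is self.root:
            return
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        # edge attributes are stored on the child; capture before rewiring
        orig_len = {id(n): n.length for n in path}
        orig_sup = {id(n): n.support for n in path}
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
        for child, parent in zip(path, path[1:]):
            child.add(parent)
            parent.length = orig_len[id(child)]
            parent.support = orig_sup[id(child)]
        node.parent = None
        node.length = None
        node.support = None
        self.root = node
        self._suppress_unary()

    def _suppress_unary(self) -> None:
        """Splice out internal nodes left with a single child (not the root
        unless it is unary too)."""
        changed = True
        while changed:
            changed = False
            for n in list(self.preorder()):
                if n.is_leaf or len(n.children) != 1:
                    continue
                child = n.children[0]
                if n.parent is None:
                    # unary root: drop it
                    child.parent = None
                    if child.length is not None and n.length is not None:
                        child.length += n.length
                    child.length = None
                    self.root = child
                else:
                    idx = n.parent.children.index(n)
                    if child.length is None or n.length is None:
                        child.length = child.length if child.length is not None else n.length
                    else:
                        child.length += n.length
                    child.parent = n.parent
                    n.parent.children[idx] = child
                changed = True
                break

    def unroot(self) -> None:
        """Collapse a bifurcating root into a trifurcation."""
        r = self.root
        if len(r.children) != 2:
            return
        a, b = r.children
        keep, merge = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            return  # two-leaf tree cannot be unrooted further
        total = (a.length or 0.0) + (b.length or 0.0)
        r.children = []
        for c in list(keep.children):
            r.add(c)
        merge.length = total
        r.add(merge)
        r.name = r.name or keep.name
        keep.children = []

    def reroot_on_edge(self, child: Node, dist_below_parent: float) -> None:
        """Insert a new root on the edge above ``child``.

        ``dist_below_parent`` is measured from the parent end of the edge.
        """
        parent = child.parent
        if parent is None:
            raise TreeError("cannot root above the root")
        length = child.length if child.length is not None else 0.0
        dist = min(max(dist_below_parent, 0.0), length)
        new = Node()
        idx = parent.children.index(child)
        parent.children.pop(idx)
        new.add(child)
        child.length = length - dist
        new.length = dist
        new.parent = parent
        parent.children.insert(idx, new)
        self.reroot_at(new)

    def midpoint_root(self) -> None:
        """Root at the midpoint of the longest leaf-to-leaf path."""
        path, total = self.leaf_to_leaf_path()
        half = total / 2.0
        acc = 0.0
        for a, b in zip(path, path[1:]):
            # edge between a and b: one is the parent of the other
            child = b if b.parent is a else a
            length = child.length or 0.0
            last = b is path[-1]
            if acc + length >= half - 1e-12 or last:
                d_from_a = min(max(half - acc, 0.0), length)
                if child is b:  # a is the parent end of the edge
                    self.reroot_on_edge(child, d_from_a)
                else:  # b is the parent end
                    self.reroot_on_edge(child, length - d_from_a)
                return
            acc += length
        raise TreeError("midpoint not found")  # pragma: no cover

    def leaf_to_leaf_path(self) -> tuple[list[Node], float]:
        """Longest leaf-to-leaf path (node sequence, total length)."""
        leaves = self.leaves()
        if len(leaves) < 2:
            raise TreeError("need two leaves for a path")

        def path_to_root(n: Node) -> list[Node]:
            out = [n]
            while out[-1].parent is not None:
                out.append(out[-1].parent)
            return out

        best: tuple[float, list[Node]] = (-1.0, [])
        for i, a in enumerate(leaves):
            pa = path_to_root(a)
            seen = {id(x): k for k, x in enumerate(pa)}
            for b in leaves[i + 1:]:
                pb = [b]
                while id(pb[-1]) not in seen:
                    pb.append(pb[-1].parent)
                anc_idx = seen[id(pb[-1])]
                path = pa[:anc_idx + 1] + list(reversed(pb[:-1]))
                total = 0.0
                for x, y in zip(path, path[1:]):
                    child = y if y.parent is x else x
                    total += child.length or 0.0
                if total > best[0]:
                    best = (total, path)
        return best[1], best[0]

    # -- utilities ---------------------------------------------------------

    def name_ancestors(self, prefix: str = "A") -> None:
        """Label unnamed internal nodes ``A1``, ``A2``, ... in preorder."""
        i = 0
        for n in self.preorder():
            if not n.is_leaf and not n.name:
                i += 1
                n.name = f"{prefix}{i}"

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise TreeError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(t1.bipartitions() ^ t2.bipartitions())
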