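"""Node-based phylogenetic trees with branch lengths.

This is the in-memory tree container shared by every stage of the
pipeline: likelihood computation, reconciliation, rooting and the
trajectory tallies.  Newick parsing is delegated to dendropy (see
:mod:`pou_trajectory.io`); this module owns the structural operations —
traversals, rerooting on an arbitrary edge, LCA queries, leaf-to-leaf
distances and midpoint rooting.

Branch lengths are in expected substitutions per site and must be
non-negative and finite wherever present.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Iterator, Optional

from .errors import IdentifierError


class Node:
    """One tree vertex; leaves carry names, edges carry the length *above* the node."""

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.parent: Optional[Node] = None
        self.children: list[Node] = []

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf() else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind} len={self.length}>"


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """A rooted or unrooted tree.

    Unrooted trees are stored with a basal polytomy (root of degree >= 3)
    and ``rooted=False``; rooted trees have a root of degree 2 (or are a
    single edge / single leaf in degenerate cases).
    """

    def __init__(self, root: Node, rooted: bool = True, validate: bool = True):
        self.root = root
        self.rooted = rooted
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.leaves():
            if leaf.name is None:
                raise IdentifierError("unnamed leaf in tree")
            if leaf.name in seen:
                raise IdentifierError(f"duplicate leaf label: {leaf.name!r}")
            seen.add(leaf.name)
        for node in self.postorder():
            if node.length is not None:
                if not math.isfinite(node.length) or node.length < 0:
                    raise ValueError(
                        f"branch length above {node.name!r} must be finite and >= 0, "
                        f"got {node.length}"
                    )

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.postorder() if n.is_leaf())

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[tuple[Node, Node]]:
        """All (parent, child) pairs, in preorder of the child."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def is_binary(self) -> bool:
        for node in self.postorder():
            if node.children and node is not self.root and len(node.children) != 2:
                return False
        nroot = len(self.root.children)
        if self.rooted:
            return nroot in (0, 1, 2)
        return nroot == 3 or self.n_leaves() <= 3

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted, validate=False)

    def label_internal(self, prefix: str = "N") -> None:
        """Assign stable preorder names to unnamed internal nodes (in place)."""
        existing = {n.name for n in self.postorder() if n.name}
        counter = 0
        for node in self.preorder():
            if not node.is_leaf() and not node.name:
                counter += 1
                name = f"{prefix}{counter}"
                while name in existing:
                    counter += 1
                    name = f"{prefix}{counter}"
                node.name = name
                existing.add(name)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def depths(self) -> dict[Node, float]:
        """Path length from the root to every node (branch-length weighted)."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def lca(self, names: Iterable[str]) -> Node:
        """Last common ancestor of the named leaves (or named nodes)."""
        wanted = list(names)
        if not wanted:
            raise ValueError("lca of an empty set is undefined")
        nodes = [self.find(n) for n in wanted]
        paths = []
        for node in nodes:
            path = []
            cur: Optional[Node] = node
            while cur is not None:
                path.append(cur)
                cur = cur.parent
            paths.append(list(reversed(path)))
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        assert anc is not None
        return anc

    def path_between(self, a: Node, b: Node) -> list[Node]:
        """Nodes on the path from ``a`` to ``b`` inclusive."""
        up_a, cur = [], a
        while cur is not None:
            up_a.append(cur)
            cur = cur.parent
        seen = {id(n): i for i, n in enumerate(up_a)}
        down_b, cur = [], b
        while id(cur) not in seen:
            down_b.append(cur)
            cur = cur.parent
        return up_a[: seen[id(cur)] + 1] + list(reversed(down_b))

    def leaf_distances(self) -> tuple[list[str], "list[list[float]]"]:
        """All pairwise leaf-to-leaf path lengths (order = leaf_names)."""
        depths = self.depths()
        leaves = list(self.leaves())
        names = [l.name for l in leaves]
        mat = [[0.0] * len(leaves) for _ in leaves]
        for i, a in enumerate(leaves):
            for j in range(i + 1, len(leaves)):
                b = leaves[j]
                anc = self._lca_nodes(a, b)
                d = depths[a] + depths[b] - 2.0 * depths[anc]
                mat[i][j] = mat[j][i] = d
        return names, mat

    def _lca_nodes(self, a: Node, b: Node) -> Node:
        ancestors = set()
        cur: Optional[Node] = a
        while cur is not None:
            ancestors.add(id(cur))
            cur = cur.parent
        cur = b
        while id(cur) not in ancestors:
            cur = cur.parent
        return cur

    # ------------------------------------------------------------------
    # rerooting
    # ------------------------------------------------------------------
    def unrooted_copy(self) -> "PhyloTree":
        """Copy with a degree-2 root collapsed into a basal polytomy."""
        tree = self.copy()
        root = tree.root
        while len(root.children) == 2 and not root.is_leaf():
            left, right = root.children
            if left.is_leaf() and right.is_leaf():
                break  # two-leaf tree cannot be unrooted further
            keep, fold = (left, right) if not left.is_leaf() else (right, left)
            # merge the two root edges into one and splice the root out
            root.remove_child(keep)
            for grand in list(keep.children):
                keep.remove_child(grand)
                root.add_child(grand)
            fold.length = (fold.length or 0.0) + (keep.length or 0.0)
            if keep.name and not root.name:
                root.name = keep.name
            break
        tree.rooted = False
        return tree

    def reroot_on_edge(self, child: Node, dist_from_child: float) -> "PhyloTree":
        """Return a new rooted tree whose root sits on the edge above ``child``.

        ``dist_from_child`` is measured from the child end; it must not
        exceed the edge length.  The input tree is left untouched.
        """
        if child.parent is None:
            raise ValueError("cannot reroot on the edge above the root")
        edge_len = child.length if child.length is not None else 0.0
        if dist_from_child < -1e-12 or dist_from_child - edge_len > 1e-9:
            raise ValueError(
                f"root position {dist_from_child} outside edge of length {edge_len}"
            )
        dist_from_child = min(max(dist_from_child, 0.0), edge_len)

        # clone and find the corresponding child in the clone
        tree = self.copy()
        pairs = list(zip(self.preorder(), tree.preorder()))
        mapping = {id(a): b for a, b in pairs}
        child_c = mapping[id(child)]

        new_root = Node()
        parent = child_c.parent
        parent.remove_child(child_c)
        child_c.length = dist_from_child
        new_root.add_child(child_c)

        carry = edge_len - dist_from_child
        prev, cur = new_root, parent
        while cur is not None:
            nxt = cur.parent
            if nxt is not None:
                nxt.remove_child(cur)
            old_len = cur.length
            prev.add_child(cur)
            cur.length = carry
            carry = old_len if old_len is not None else 0.0
            prev, cur = cur, nxt

        # the old root may now be a degree-1 pass-through node: splice it
        for node in list(PhyloTree(new_root, rooted=True, validate=False).postorder()):
            if node is not new_root and not node.is_leaf() and len(node.children) == 1:
                only = node.children[0]
                node.remove_child(only)
                only.length = (only.length or 0.0) + (node.length or 0.0)
                par = node.parent
                par.remove_child(node)
                par.add_child(only)
        return PhyloTree(new_root, rooted=True, validate=False)

    def midpoint_root(self) -> "PhyloTree":
        """Root at the midpoint of the longest leaf-to-leaf path."""
        names, mat = self.leaf_distances()
        if len(names) < 2:
            raise ValueError("midpoint rooting needs at least two leaves")
        best, bi, bj = -1.0, 0, 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if mat[i][j] > best:
                    best, bi, bj = mat[i][j], i, j
        if best <= 0.0:
            raise ValueError("zero-diameter tree cannot be midpoint rooted")
        a = self.find(names[bi])
        b = self.find(names[bj])
        path = self.path_between(a, b)
        half = best / 2.0
        cum = 0.0
        for u, v in zip(path, path[1:]):
            # edge between u and v; one of them is the other's parent
            if v.parent is u:
                child, step = v, (v.length or 0.0)
            else:
                child, step = u, (u.length or 0.0)
            if cum + step >= half - 1e-12:
                if v.parent is u:
                    dist_from_child = cum + step - half
                else:
                    dist_from_child = half - cum
                return self.reroot_on_edge(child, dist_from_child)
            cum += step
        raise AssertionError("midpoint not found on diameter path")

    # ------------------------------------------------------------------
    # serialization (writing only; parsing lives in io via dendropy)
    # ------------------------------------------------------------------
    def to_newick(self, *, lengths: bool = True, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                body = _quote_label(node.name or "")
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner})" + (_quote_label(node.name) if node.name else "")
            if lengths and node.length is not None and node.parent is not None:
                body += f":{node.length:.{precision}g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {'rooted' if self.rooted else 'unrooted'} " \
               f"n_leaves={self.n_leaves()}>"
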