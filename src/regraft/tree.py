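"""Unrooted binary phylogenetic trees with the trifurcating-root convention.

Trees are stored rooted at a trifurcation purely as a data-structure
convention: with a time-reversible substitution model the likelihood does
not depend on where the trifurcation sits.  All internal nodes other than
the root have exactly two children.  Newick parsing goes through dendropy;
the bipartition machinery (Robinson–Foulds, topology identity, support
mapping) is implemented directly on the structure.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Callable, Iterator, Optional

import dendropy

BRANCH_FLOOR = 1e-8


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class Node:
    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length  # branch length to parent; None at the root
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """An unrooted tree held with a trifurcating root."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every edge, identified by its child node (all non-root nodes)."""
        return [n for n in self.postorder() if n.parent is not None]

    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    # ------------------------------------------------------------ invariants
    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(dup)}")
        n = len(labels)
        if n >= 3:
            if len(self.root.children) != 3:
                raise TreeError(
                    f"root must trifurcate, has {len(self.root.children)} children"
                )
            for node in self.postorder():
                if node is not self.root and node.children and len(node.children) != 2:
                    raise TreeError("internal node is not binary")
            n_edges = len(self.edges())
            n_internal = sum(1 for x in self.postorder() if x.children)
            assert n_edges == 2 * n - 3, (n_edges, n)
            assert n_internal == n - 2, (n_internal, n)
        for node in self.postorder():
            if node.parent is not None:
                if node.length is None or not (node.length >= 0) or node.length != node.length:
                    raise TreeError(f"bad branch length {node.length!r}")

    def floor_lengths(self, floor: float = BRANCH_FLOOR) -> None:
        for node in self.postorder():
            if node.parent is not None and node.length < floor:
                node.length = floor

    # ----------------------------------------------------------------- copy
    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            c = Node(n.label, n.length)
            c.support = n.support
            for ch in n.children:
                c.add(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    # ----------------------------------------------------------- bipartitions
    def leafset_below(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> frozenset of leaf labels in its subtree."""
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                s = frozenset()
                for c in n.children:
                    s |= below[id(c)]
                below[id(n)] = s
        return below

    def bipartitions(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """Splits as canonical frozensets: the side not containing the
        alphabetically first taxon."""
        all_taxa = frozenset(self.leaf_labels())
        anchor = min(all_taxa)
        below = self.leafset_below()
        out = set()
        for n in self.edges():
            side = below[id(n)]
            if anchor in side:
                side = all_taxa - side
            if nontrivial_only and (len(side) < 2 or len(side) > len(all_taxa) - 2):
                continue
            out.add(side)
        return out

    # -------------------------------------------------------------- rerooting
    def reroot(self, new_root: Node) -> None:
        """Make an internal node the trifurcating root (in place)."""
        if new_root.is_leaf:
            raise TreeError("cannot root at a leaf")
        if new_root is self.root:
            return
        path = []
        n = new_root
        while n is not None:
            path.append(n)
            n = n.parent
        # reverse parent->child links along path; path[-1] is the old root.
        # Each edge keeps its length/support, re-stored on its new child node.
        lengths = [n.length for n in path]
        supports = [n.support for n in path]
        for i in range(len(path) - 1):
            child, parent = path[i], path[i + 1]
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
            parent.length = lengths[i]
            parent.support = supports[i]
        new_root.parent = None
        new_root.length = None
        new_root.support = None
        self.root = new_root

    # ------------------------------------------------------------- utilities
    def find_leaf(self, label: str) -> Node:
        for n in self.postorder():
            if n.is_leaf and n.label == label:
                return n
        raise TreeError(f"no leaf named {label!r}")

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """All pairwise leaf-to-leaf path lengths (brute force)."""
        out = {}
        leaves = self.leaves()
        parents: dict[int, tuple[Node, float]] = {}
        for n in self.postorder():
            for c in n.children:
                parents[id(c)] = (n, c.length)

        def path_to_root(n: Node):
            d = {id(n): 0.0}
            acc = 0.0
            while id(n) in parents:
                p, t = parents[id(n)]
                acc += t
                d[id(p)] = acc
                n = p
            return d

        for a, b in itertools.combinations(leaves, 2):
            da, db = path_to_root(a), path_to_root(b)
            best = min(da[k] + db[k] for k in da.keys() & db.keys())
            key = tuple(sorted((a.label, b.label)))
            out[key] = best
        return out


# ------------------------------------------------------------------ Newick IO


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def conv(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            n = Node(label, dnode.edge.length)
        else:
            n = Node(None, dnode.edge.length)
            if dnode.label is not None:
                try:
                    n.support = float(dnode.label)
                except ValueError:
                    n.label = dnode.label
            for c in dnode.child_nodes():
                n.add(conv(c))
        return n

    root = conv(dtree.seed_node)
    root.length = None
    tree = PhyloTree(root)
    _unroot(tree)
    return tree


def _unroot(tree: PhyloTree) -> None:
    """Collapse a bifurcating root into the trifurcating convention."""
    root = tree.root
    if tree.n_leaves() < 3 or len(root.children) != 2:
        return
    a, b = root.children
    keep, other = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        raise TreeError("tree with 3+ leaves has no internal node to root at")
    # merge the two root edges into one, hanging `other` off `keep`
    merged = (a.length or 0.0) + (b.length or 0.0)
    root.children.remove(keep)
    for c in list(root.children):
        root.children.remove(c)
        keep.add(c)
        c.length = merged if c is other else c.length
    keep.parent = None
    keep.length = None
    tree.root = keep


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick string (or file path) into a PhyloTree.

    Rooted (bifurcating) inputs are converted to the trifurcating
    convention; support values on internal-node labels are preserved.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(") and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:
        raise TreeError(f"newick parse error: {e}") from None
    tree = _from_dendropy(dtree)
    tree.validate()
    return tree


def write_newick(tree: PhyloTree, path: str | Path | None = None, support: bool = False) -> str:
    """Serialise to Newick; branch lengths at 10 significant digits."""

    def fmt(n: Node) -> str:
        if n.is_leaf:
            body = n.label
        else:
            inner = ",".join(fmt(c) for c in n.children)
            lab = ""
            if support and n.support is not None:
                lab = f"{n.support:g}"
            elif n.label:
                lab = n.label
            body = f"({inner}){lab}"
        if n.parent is not None and n.length is not None:
            body += f":{n.length:.10g}"
        return body

    text = fmt(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# --------------------------------------------------------------- comparisons


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ: only in first={sorted(l1 - l2)}, "
            f"only in second={sorted(l2 - l1)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def same_topology(t1: PhyloTree, t2: PhyloTree) -> bool:
    return robinson_foulds(t1, t2) == 0


# ------------------------------------------------------------- random trees


def random_tree(
    labels: list[str],
    rng,
    branch_length: Callable[[], float] | None = None,
) -> PhyloTree:
    """Uniform random topology by sequential leaf insertion at a random edge."""
    if len(labels) < 3:
        raise TreeError("need at least 3 leaves")
    bl = branch_length or (lambda: float(rng.exponential(0.1)) + 0.01)
    labels = list(labels)
    root = Node()
    for lab in labels[:3]:
        root.add(Node(lab, bl()))
    tree = PhyloTree(root)
    for lab in labels[3:]:
        edges = tree.edges()
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node(None, target.length / 2.0)
        target.length = target.length / 2.0
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(lab, bl()))
    tree.validate()
    return tree
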