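"""Newick tree I/O and the bipartition algebra used across the package.

Trees are stored rooted (a root node with >= 2 children; polytomies are
first-class), but every comparison between trees happens on unrooted
bipartitions, so the stored rooting is a convenience, not a commitment.
Branch support values live on the child node of each internal edge, on the
0-100 percent scale; supports supplied on [0, 1] are rescaled with a warning.

Parsing and the round-trip dialect checks are delegated to dendropy; the
split algebra (canonical bipartitions, restriction, compatibility), the
outgroup-rooting rule and low-support collapsing are implemented here.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Iterator, Optional

import dendropy


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate tips, bad supports, ...)."""


_WS_RUN = re.compile(r"[\s_]+")


def normalize_taxon(label: str) -> str:
    """Trim whitespace and collapse internal space/underscore runs to '_'.

    Case is preserved: tip labels must join reliably against label tables.
    """
    return _WS_RUN.sub("_", label.strip())


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

class Bipartition:
    """A two-way split of a taxon set, orientation-free.

    The canonical side_a is the side containing the lexicographically
    smallest taxon of the universe, so a split always equals its mirror.
    """

    __slots__ = ("side_a", "side_b")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeValidationError("both sides of a bipartition must be nonempty")
        if a & b:
            raise TreeValidationError(f"bipartition sides overlap: {sorted(a & b)}")
        if min(a) > min(b):
            a, b = b, a
        self.side_a = a
        self.side_b = b

    @property
    def universe(self) -> frozenset:
        return self.side_a | self.side_b

    def is_nontrivial(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def smaller_side(self) -> frozenset:
        if len(self.side_a) < len(self.side_b):
            return self.side_a
        if len(self.side_b) < len(self.side_a):
            return self.side_b
        return self.side_a  # tie: canonical side

    def restrict(self, taxa: Iterable[str]) -> Optional["Bipartition"]:
        """Intersect both sides with ``taxa``; None when degenerate (<2 a side)."""
        t = frozenset(taxa)
        a, b = self.side_a & t, self.side_b & t
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True iff the two splits could not co-occur in one tree.

        Operationally: all four pairwise side intersections are nonempty.
        """
        return bool(
            self.side_a & other.side_a
            and self.side_a & other.side_b
            and self.side_b & other.side_a
            and self.side_b & other.side_b
        )

    def sort_key(self):
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def notation(self) -> str:
        fmt = lambda s: "{" + ",".join(sorted(s)) + "}"
        return f"{fmt(self.side_a)} | {fmt(self.side_b)}"

    @classmethod
    def from_notation(cls, text: str) -> "Bipartition":
        m = re.match(r"\s*\{(.*)\}\s*\|\s*\{(.*)\}\s*$", text)
        if not m:
            raise ValueError(f"cannot parse bipartition notation: {text!r}")
        return cls(m.group(1).split(","), m.group(2).split(","))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side_a == other.side_a
            and self.side_b == other.side_b
        )

    def __hash__(self) -> int:
        return hash((self.side_a, self.side_b))

    def __repr__(self) -> str:
        return f"Bipartition({self.notation()})"


def restrict(bipartition: Bipartition, taxa: Iterable[str]) -> Optional[Bipartition]:
    """Module-level alias for :meth:`Bipartition.restrict`."""
    return bipartition.restrict(taxa)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("children", "parent", "taxon", "support", "length")

    def __init__(self, taxon: Optional[str] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.taxon = taxon
        self.support: Optional[float] = None
        self.length: Optional[float] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_taxa(self) -> frozenset:
        if self.is_leaf:
            return frozenset((self.taxon,))
        out: set[str] = set()
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.taxon)
            else:
                stack.extend(n.children)
        return frozenset(out)


class Tree:
    """Rooted storage of a (possibly unrooted) labeled tree with supports."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.leaves():
            if leaf.taxon in seen:
                raise TreeValidationError(f"duplicate tip name: {leaf.taxon!r}")
            seen.add(leaf.taxon)
        for node in self.preorder():
            if node.support is not None and not (0.0 <= node.support <= 100.0):
                raise TreeValidationError(
                    f"branch support {node.support} outside [0, 100]"
                )
            if not node.is_leaf and len(node.children) == 1 and node is not self.root:
                raise TreeValidationError("internal node with a single child")

    @property
    def tips(self) -> frozenset:
        return self.root.leaf_taxa()

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_leaf)

    def clone(self) -> "Tree":
        def copy(n: Node) -> Node:
            m = Node(n.taxon)
            m.support, m.length = n.support, n.length
            for c in n.children:
                m.add(copy(c))
            return m

        return Tree(copy(self.root), rooted=self.rooted)

    # -- split algebra -----------------------------------------------------

    def bipartitions(self) -> set[Bipartition]:
        """All nontrivial unrooted splits induced by internal branches."""
        universe = self.tips
        out: set[Bipartition] = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            clade = node.leaf_taxa()
            rest = universe - clade
            if len(clade) >= 2 and len(rest) >= 2:
                out.add(Bipartition(clade, rest))
        return out

    def clades(self) -> set[frozenset]:
        """Leaf sets of every internal node under the stored rooting."""
        return {
            n.leaf_taxa() for n in self.preorder() if not n.is_leaf
        }

    def find_clade(self, taxa: Iterable[str]) -> Optional[Node]:
        """Node whose leaf set equals ``taxa`` under the stored rooting."""
        target = frozenset(taxa)
        for node in self.preorder():
            if not node.is_leaf and node.leaf_taxa() == target:
                return node
            if node.is_leaf and target == frozenset((node.taxon,)):
                return node
        return None

    def mrca(self, taxa: Iterable[str]) -> Node:
        target = frozenset(taxa)
        if not target <= self.tips:
            raise TreeValidationError("mrca: taxa not all present in tree")
        node = self.root
        while True:
            nxt = [c for c in node.children if target <= c.leaf_taxa()]
            if len(nxt) == 1:
                node = nxt[0]
            else:
                return node

    # -- rooting -----------------------------------------------------------

    def root_on_outgroup(self, outgroup: Iterable[str]) -> "Tree":
        """Reroot on the branch best separating the outgroup from the ingroup.

        A monophyletic outgroup roots on its stem; otherwise the edge side
        maximizing (outgroup coverage, -ingroup contamination, canonical
        order) is chosen. The unrooted bipartition set is unchanged.
        """
        present = frozenset(outgroup) & self.tips
        if not present:
            raise TreeValidationError(
                "no outgroup tip present in tree; supply an alternative outgroup"
            )
        universe = self.tips
        best = None
        for node in self.preorder():
            if node is self.root:
                continue
            clade = node.leaf_taxa()
            for side in (clade, universe - clade):
                if not side:
                    continue
                key = (
                    len(side & present),
                    -len(side - present),
                    tuple(sorted(side)),
                )
                if best is None or key > best[0]:
                    best = (key, node, side == clade)
        _, edge_child, outgroup_is_clade = best
        return self._reroot_on_edge(edge_child, outgroup_is_clade)

    def _reroot_on_edge(self, edge_child: Node, outgroup_below: bool) -> "Tree":
        """Build a new tree rooted on the edge above ``edge_child``.

        Works on an undirected view so supports (edge attributes carried by
        the child node) stay attached to the correct edge.
        """
        # Undirected adjacency with per-edge (length, support).
        nodes = list(self.preorder())
        adj: dict[int, list[tuple[int, Optional[float], Optional[float]]]] = {
            id(n): [] for n in nodes
        }
        by_id = {id(n): n for n in nodes}
        for n in nodes:
            for c in n.children:
                adj[id(n)].append((id(c), c.length, c.support))
                adj[id(c)].append((id(n), c.length, c.support))

        parent = edge_child.parent
        half = None if edge_child.length is None else edge_child.length / 2.0

        new_root = Node()

        def build(src_id: int, avoid_id: int, length, support) -> Node:
            src = by_id[src_id]
            m = Node(src.taxon if src.is_leaf else None)
            m.length, m.support = length, support
            for nb_id, nb_len, nb_sup in adj[src_id]:
                if nb_id == avoid_id:
                    continue
                m.add(build(nb_id, src_id, nb_len, nb_sup))
            return m

        down = build(id(edge_child), id(parent), half, edge_child.support)
        up = build(id(parent), id(edge_child), half, edge_child.support)
        # Suppress a degree-2 node created when the old root had 2 children
        # and lies on the "up" path (it is not a real unrooted vertex).
        for side in (down, up):
            _suppress_unary(side)
        if outgroup_below:
            new_root.add(up)
            new_root.add(down)
        else:
            new_root.add(down)
            new_root.add(up)
        return Tree(new_root, rooted=True)

    # -- support handling --------------------------------------------------

    def collapse_low_support(self, threshold: float) -> "Tree":
        """Contract internal branches with support < threshold into polytomies.

        Branches lacking a support value are retained. threshold 0 is the
        identity; 10 and 30 are the conventional gene-tree-error settings.
        """
        if not (0.0 <= threshold <= 100.0):
            raise TreeValidationError(f"threshold {threshold} outside [0, 100]")
        out = self.clone()
        changed = True
        while changed:
            changed = False
            for node in list(out.preorder()):
                if (
                    node is not out.root
                    and not node.is_leaf
                    and node.support is not None
                    and node.support < threshold
                ):
                    p = node.parent
                    idx = p.children.index(node)
                    for c in node.children:
                        c.parent = p
                    p.children[idx:idx + 1] = node.children
                    changed = True
                    break
        return out


def _suppress_unary(node: Node) -> None:
    """Merge chains of single-child internal nodes below ``node`` (in place)."""
    stack = [node]
    while stack:
        n = stack.pop()
        while len(n.children) == 1:
            only = n.children[0]
            if n.length is not None or only.length is not None:
                n.length = (n.length or 0.0) + (only.length or 0.0)
            if n.support is None:
                n.support = only.support
            if only.is_leaf:
                n.taxon = only.taxon
                n.children = []
            else:
                n.children = only.children
                for c in n.children:
                    c.parent = n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed parsing)
# ---------------------------------------------------------------------------

_NUMERIC = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree; supports may sit in internal node labels or
    in bracketed comments. Polytomies are preserved."""
    trees = read_trees(text)
    if len(trees) != 1:
        raise NewickParseError(f"expected exactly one tree, found {len(trees)}")
    return trees[0]


def read_trees(source: str) -> list[Tree]:
    """Read all trees from a Newick string or file path (one per line or
    semicolon-separated)."""
    import os

    if os.path.exists(source) and not source.lstrip().startswith("("):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    try:
        dlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if not dlist:
        raise NewickParseError("no trees found in input")
    return [_from_dendropy(dt) for dt in dlist]


def _from_dendropy(dtree: "dendropy.Tree") -> Tree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            n = Node(normalize_taxon(label))
        else:
            n = Node()
            raw = dnode.label
            if raw is None and dnode.comments:
                for comment in dnode.comments:
                    c = comment.strip().lstrip("&")
                    if _NUMERIC.match(c):
                        raw = c
                        break
            if raw is not None and _NUMERIC.match(str(raw).strip()):
                n.support = float(raw)
            for c in dnode.child_nodes():
                n.add(convert(c))
        if dnode.edge.length is not None:
            n.length = float(dnode.edge.length)
        return n

    root = convert(dtree.seed_node)
    root.support = None  # a root "support" is not an edge attribute
    _rescale_supports(root)
    rooted = bool(dtree.is_rooted)
    return Tree(root, rooted=rooted)


def _rescale_supports(root: Node) -> None:
    supports = []
    stack = [root]
    while stack:
        n = stack.pop()
        if n.support is not None:
            supports.append(n.support)
        stack.extend(n.children)
    if supports and max(supports) <= 1.0:
        warnings.warn(
            "branch supports look like proportions in [0, 1]; rescaling to percent",
            stacklevel=3,
        )
        stack = [root]
        while stack:
            n = stack.pop()
            if n.support is not None:
                n.support *= 100.0
            stack.extend(n.children)


def _fmt_num(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return f"{x:.12g}"


def write_newick(tree: Tree, include_supports: bool = True) -> str:
    """Serialize with supports as internal node labels."""

    def emit(n: Node) -> str:
        if n.is_leaf:
            s = n.taxon
        else:
            s = "(" + ",".join(emit(c) for c in n.children) + ")"
            if include_supports and n.support is not None:
                s += _fmt_num(n.support)
        if n.length is not None:
            s += f":{_fmt_num(n.length)}"
        return s

    prefix = "[&R] " if tree.rooted else ""
    return prefix + emit(tree.root) + ";"


def write_trees(trees: Iterable[Tree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")
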