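"""Rooted time-tree structures shared by the simulators and the sampler.

Ages are in Myr before present: the present is 0 and ages increase into the
past.  Every branch runs from the parent's age (older) down to the node's age
(younger).  A tree also records an *origin age*: the stem lineage starts at
``origin_age`` and runs down to the root node, because the fossilized
birth-death process conditions on the origin of the clade rather than on its
first split.

Two kinds of trees share the same node type:

* the *complete* tree produced by forward birth-death simulation, whose tips
  are extinction events, sampled extant taxa or unsampled extant taxa;
* the *sampled* (reconstructed) tree spanning the sampled extant tips and the
  fossil occurrences, in which a fossil lying on a lineage ancestral to other
  samples appears as a *sampled ancestor*: a zero-length fossil tip attached
  at its own age.
"""

from __future__ import annotations

from typing import Iterator, Optional

__all__ = [
    "Node",
    "Tree",
    "EXTANT_SAMPLED",
    "EXTANT_UNSAMPLED",
    "EXTINCT",
    "FOSSIL",
    "SPECIATION",
    "newick_string",
    "parse_newick",
]

EXTANT_SAMPLED = "extant_sampled"
EXTANT_UNSAMPLED = "extant_unsampled"
EXTINCT = "extinct"
FOSSIL = "fossil"
SPECIATION = "speciation"

_TIP_KINDS = frozenset({EXTANT_SAMPLED, EXTANT_UNSAMPLED, EXTINCT, FOSSIL})


class Node:
    """A node of a rooted time tree.

    Parameters
    ----------
    age:
        Node age in Myr before present (tip age or split age).
    label:
        Taxon label for tips; optional for internal nodes.
    kind:
        One of ``speciation``, ``extant_sampled``, ``extant_unsampled``,
        ``extinct`` or ``fossil``.
    sampled_ancestor:
        Only meaningful for fossil tips: True when the fossil lies on a
        lineage ancestral to other samples.  Such a tip has a zero-length
        branch (its age equals its parent's age).
    """

    __slots__ = ("age", "label", "kind", "parent", "children", "sampled_ancestor")

    def __init__(
        self,
        age: float,
        label: Optional[str] = None,
        kind: str = SPECIATION,
        sampled_ancestor: bool = False,
    ):
        self.age = float(age)
        self.label = label
        self.kind = kind
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.sampled_ancestor = sampled_ancestor

    # -- structure ---------------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = self.label or self.kind
        return f"<Node {tag} age={self.age:.4g}>"


class Tree:
    """A rooted time tree with an origin (stem) age."""

    def __init__(self, root: Node, origin_age: float):
        if origin_age < root.age:
            raise ValueError("origin_age must be at least the root age")
        self.root = root
        self.origin_age = float(origin_age)

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if n.children]

    def tips_of_kind(self, kind: str) -> list[Node]:
        return [n for n in self.leaves() if n.kind == kind]

    def find(self, label: str) -> Node:
        for n in self.preorder():
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def branch_parent_age(self, node: Node) -> float:
        """Age of the older end of the branch subtending ``node``."""
        return self.origin_age if node.parent is None else node.parent.age

    # -- bookkeeping -------------------------------------------------------

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def total_branch_time(self) -> float:
        """Sum of branch durations (lineage-Myr), including the stem."""
        return sum(self.branch_parent_age(n) - n.age for n in self.preorder())

    def copy(self) -> "Tree":
        """Deep, structure-only copy (fast; no ``copy.deepcopy``)."""
        mapping: dict[int, Node] = {}

        def clone(node: Node) -> Node:
            new = Node(node.age, node.label, node.kind, node.sampled_ancestor)
            mapping[id(node)] = new
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), self.origin_age)

    def validate(self) -> None:
        """Raise ``ValueError`` on an inconsistent tree."""
        for node in self.preorder():
            top = self.branch_parent_age(node)
            if node.age < 0:
                raise ValueError(f"negative age at {node!r}")
            if node.age > top + 1e-9:
                raise ValueError(f"child older than parent at {node!r}")
            if node.is_leaf and node.kind not in _TIP_KINDS:
                raise ValueError(f"leaf with internal kind at {node!r}")
            if node.kind in (EXTANT_SAMPLED, EXTANT_UNSAMPLED) and node.age != 0.0:
                raise ValueError(f"extant tip with non-zero age at {node!r}")
            if node.sampled_ancestor:
                if node.parent is None or abs(node.parent.age - node.age) > 1e-9:
                    raise ValueError(f"sampled ancestor not at its parent age: {node!r}")

    def clades(self, exclude_root: bool = True) -> set[frozenset[str]]:
        """Sets of tip labels under each internal node (non-trivial clades)."""
        below: dict[int, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                out.add(s)
        if exclude_root:
            out.discard(below[id(self.root)])
        return {c for c in out if len(c) >= 2}


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------


def newick_string(tree: Tree, include_stem: bool = False, precision: int = 17) -> str:
    """Serialize a tree to Newick with branch lengths in Myr.

    Sampled ancestors appear as zero-length terminal branches.  When
    ``include_stem`` is true the root branch length (origin to root) is
    written on the root.
    """

    fmt = f"%.{precision}g"

    def rec(node: Node, top_age: float) -> str:
        bl = fmt % max(top_age - node.age, 0.0)
        if node.is_leaf:
            return f"{node.label}:{bl}"
        inner = ",".join(rec(c, node.age) for c in node.children)
        label = node.label or ""
        return f"({inner}){label}:{bl}"

    top = tree.origin_age if include_stem else tree.root.age
    return rec(tree.root, top) + ";"


def parse_newick(text: str, origin_age: Optional[float] = None) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Node ages are reconstructed from branch lengths assuming the youngest tip
    sits at age 0.  Tips with age > 0 are marked fossils; zero-length fossil
    tips are flagged as sampled ancestors.  ``origin_age`` defaults to the
    root age (zero-length stem).
    """

    import dendropy

    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=False
    )
    # depth = distance from dendropy root; convert to ages afterwards
    depth: dict = {}
    root = dtree.seed_node
    depth[root] = 0.0
    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is not None:
            depth[edge.head_node] = depth[edge.tail_node] + (edge.length or 0.0)
    max_depth = max(depth[lf] for lf in dtree.leaf_node_iter())

    def conv(dnode) -> Node:
        age = max_depth - depth[dnode]
        if abs(age) < 1e-6:
            age = 0.0
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if not dnode.child_nodes():
            kind = EXTANT_SAMPLED if age == 0.0 else FOSSIL
            node = Node(age, label, kind)
        else:
            node = Node(age, label, SPECIATION)
            for c in dnode.child_nodes():
                node.add_child(conv(c))
        return node

    root_node = conv(root)
    # flag sampled ancestors: fossil tips at exactly their parent's age
    tree = Tree(root_node, origin_age if origin_age is not None else root_node.age)
    for n in tree.preorder():
        if n.kind == FOSSIL and n.parent is not None and abs(n.parent.age - n.age) < 1e-6:
            n.sampled_ancestor = True
            n.age = n.parent.age
    return tree


def extant_subtree(tree: Tree) -> Tree:
    """Restriction of a sampled tree to its extant tips.

    Degree-one pass-through nodes left by removing fossil subtrees are
    collapsed, which preserves path durations and therefore all likelihoods
    of Markov substitution processes along the tree.
    """

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.kind == EXTANT_SAMPLED:
                return Node(node.age, node.label, node.kind)
            return None
        kept = [r for r in (rec(c) for c in node.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(node.age, node.label, SPECIATION)
        for k in kept:
            new.add_child(k)
        return new

    root = rec(tree.root)
    if root is None:
        raise ValueError("tree has no extant sampled tips")
    return Tree(root, tree.origin_age)


def mrca_age(tree: Tree, labels: set[str]) -> float:
    """Age of the most recent common ancestor of the given tip labels."""
    below: dict[int, set[str]] = {}
    best: Optional[Node] = None
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label} if node.label in labels else set()
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
        if below[id(node)] >= labels and best is None:
            best = node
    if best is None:
        raise ValueError("labels not all present in tree")
    return best.age
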