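"""Light-weight rooted trees with Newick I/O.

Gene and species trees are held in a minimal :class:`Node` structure that the
reconciliation and ortholog-group code can traverse and re-root cheaply.
Parsing is delegated to :mod:`dendropy`; numeric internal-node labels are
interpreted as branch supports (aLRT/SH-like style), following the common
convention of support values stored as internal node labels.

Leaf labels follow the ``SPECI_geneNNN`` convention: the species code is the
substring before the first underscore (:func:`species_code`).
"""

from __future__ import annotations

from collections import deque
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "parse_newick",
    "read_newick",
    "write_newick",
    "species_code",
]


class Node:
    """One node of a rooted tree.

    Attributes
    ----------
    name:
        Leaf label, or an optional internal-node name.
    children:
        Child nodes, in order.
    parent:
        Parent node, or ``None`` at the root.
    length:
        Length of the edge above this node (``None`` if absent).
    support:
        Branch support of the edge above this node, in [0, 1], or ``None``.
    event:
        Reconciliation/simulation event label for internal nodes
        (``"speciation"`` or ``"duplication"``), or ``None``.
    """

    __slots__ = ("name", "children", "parent", "length", "support", "event")

    def __init__(
        self,
        name: Optional[str] = None,
        children: Optional[list["Node"]] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.name = name
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        self.support = support
        self.event: Optional[str] = None
        for child in children or []:
            self.add_child(child)

    # -- construction -----------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    # -- predicates and traversal -----------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: deque[Node] = deque()
        stack = [self]
        while stack:
            node = stack.pop()
            out.appendleft(node)
            stack.extend(node.children)
        return iter(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list["Node"]:
        return [n for n in self.preorder() if not n.is_leaf]

    def copy(self) -> "Node":
        """Deep copy of the subtree rooted here."""
        clone = Node(self.name, length=self.length, support=self.support)
        clone.event = self.event
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({write_newick(self)})"


def species_code(leaf_label: str) -> str:
    """Species code of a gene-tree leaf: text before the first underscore."""
    return leaf_label.split("_", 1)[0]


# -- Newick I/O ------------------------------------------------------------


def _from_dendropy(dnode: dendropy.Node) -> Node:
    node = Node()
    if dnode.taxon is not None:
        node.name = dnode.taxon.label
    elif dnode.label is not None:
        # internal label: numeric -> support, otherwise a name
        try:
            node.support = float(dnode.label)
        except ValueError:
            node.name = dnode.label
    node.length = dnode.edge.length
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


def parse_newick(newick: str) -> Node:
    """Parse one Newick string into a :class:`Node` tree.

    Internal node labels that parse as floats are stored as supports.
    """
    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return _from_dendropy(dtree.seed_node)


def read_newick(path) -> Node:
    with open(path) as handle:
        return parse_newick(handle.read())


def _fmt_length(length: Optional[float]) -> str:
    return "" if length is None else f":{length:g}"


def _node_newick(node: Node, support_fmt: Callable[[float], str]) -> str:
    if node.is_leaf:
        return f"{node.name or ''}{_fmt_length(node.length)}"
    inner = ",".join(_node_newick(c, support_fmt) for c in node.children)
    label = node.name or ""
    if node.support is not None:
        label = support_fmt(node.support)
    return f"({inner}){label}{_fmt_length(node.length)}"


def write_newick(root: Node, support_digits: int = 3) -> str:
    """Serialize a tree; internal supports are written as node labels."""

    def fmt(s: float) -> str:
        return f"{s:.{support_digits}g}"

    return _node_newick(root, fmt) + ";"
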