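"""Gene-tree / species-tree reconciliation and duplication-loss rooting.

The classic parsimony (LCA) reconciliation maps every gene-tree node onto the
species tree: a leaf maps to its species, an internal node to the lowest
common ancestor of its children's images. An internal node is a duplication
when its image coincides with a child's image, otherwise a speciation; losses
are the species-tree branches skipped along each gene-tree edge. Unrooted
gene trees are rooted by evaluating every edge as a candidate root and
keeping the rooting that minimises duplications + losses (equal weights),
which avoids any dependence on outgroup sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .species import SpeciesTree
from .trees import Node, species_code

__all__ = [
    "Reconciliation",
    "lca_map",
    "count_events",
    "root_by_dl",
    "reconciliation_table",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class Reconciliation:
    """Result of mapping a rooted gene tree onto a species tree.

    ``mapping`` sends each gene-tree node to its species-tree image;
    ``events`` labels every internal gene node; ``losses`` lists, per
    gene-tree child edge (keyed by the child node), the species-tree nodes
    whose lineage was lost along that edge.
    """

    gene_root: Node
    species_tree: SpeciesTree
    mapping: dict[Node, Node] = field(default_factory=dict)
    events: dict[Node, str] = field(default_factory=dict)
    losses: dict[Node, list[Node]] = field(default_factory=dict)

    @property
    def duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == DUPLICATION)

    @property
    def loss_count(self) -> int:
        return sum(len(v) for v in self.losses.values())

    def cost(self) -> int:
        return self.duplications + self.loss_count


def lca_map(gene_root: Node, species_tree: SpeciesTree) -> Reconciliation:
    """LCA reconciliation of a rooted binary gene tree.

    Raises
    ------
    ValueError
        If the gene tree has a multifurcation (named in the message) or a
        leaf whose species code is absent from the species tree.
    """
    rec = Reconciliation(gene_root, species_tree)
    st = species_tree
    for node in gene_root.postorder():
        if node.is_leaf:
            code = species_code(node.name)
            if code not in st.leaf_by_code:
                raise ValueError(
                    f"leaf {node.name!r}: species code {code!r} not in species tree"
                )
            rec.mapping[node] = st.leaf_by_code[code]
            continue
        if len(node.children) != 2:
            names = ",".join(sorted(node.leaf_names())[:3])
            raise ValueError(
                f"non-binary gene-tree node (clade around {names}...) rejected"
            )
        left, right = node.children
        image = st.lca(rec.mapping[left], rec.mapping[right])
        rec.mapping[node] = image
        is_dup = image is rec.mapping[left] or image is rec.mapping[right]
        rec.events[node] = DUPLICATION if is_dup else SPECIATION
        for child in node.children:
            rec.losses[child] = _edge_losses(
                st, image, rec.mapping[child], duplication=is_dup
            )
    return rec


def _edge_losses(
    st: SpeciesTree, top: Node, bottom: Node, duplication: bool
) -> list[Node]:
    """Species nodes lost along a gene-tree edge mapped from ``top`` to ``bottom``.

    Walking up from ``bottom`` to ``top``, every species node passed implies
    the sibling branch off the path lost this gene lineage; under a
    duplication the branch off ``top`` itself is lost too.
    """
    path: list[Node] = []
    x = bottom
    while x is not top:
        path.append(x)
        x = st.parent_of[id(x)]
    if not path:
        return []
    # siblings of path nodes, excluding (for speciation) the one directly
    # under `top`, which carries the other gene-tree child
    cut = path if duplication else path[:-1]
    lost = []
    for p in cut:
        parent = st.parent_of[id(p)]
        lost.extend(c for c in parent.children if c is not p)
    return lost


def count_events(rec: Reconciliation) -> tuple[int, int]:
    """Total (duplications, losses) of a reconciliation."""
    return rec.duplications, rec.loss_count


# -- rooting ---------------------------------------------------------------


def _unrooted_adjacency(root: Node) -> dict[int, list[Node]]:
    """Undirected adjacency of the tree, suppressing a degree-2 root."""
    adj: dict[int, list[Node]] = {}
    nodes = list(root.preorder())
    for node in nodes:
        adj.setdefault(id(node), [])
        for child in node.children:
            adj[id(node)].append(child)
            adj.setdefault(id(child), []).append(node)
    if len(root.children) == 2:
        a, b = root.children
        adj[id(a)] = [x for x in adj[id(a)] if x is not root] + [b]
        adj[id(b)] = [x for x in adj[id(b)] if x is not root] + [a]
        del adj[id(root)]
    return adj


def _directed_copy(node: Node, parent: Optional[Node], adj) -> Node:
    """Copy the unrooted tree as a rooted subtree growing away from ``parent``."""
    clone = Node(node.name, length=node.length, support=node.support)
    for nb in adj[id(node)]:
        if parent is not None and nb is parent:
            continue
        clone.add_child(_directed_copy(nb, node, adj))
    return clone


def _edges(adj: dict[int, list[Node]], root: Node) -> list[tuple[Node, Node]]:
    seen: set[frozenset] = set()
    order = {id(n): i for i, n in enumerate(root.preorder())}
    edges = []
    for nid, nbs in adj.items():
        for nb in nbs:
            key = frozenset((nid, id(nb)))
            if key not in seen:
                seen.add(key)
                edges.append((nid, nb))
    # deterministic order by preorder index
    node_by_id = {id(n): n for n in root.preorder()}
    return sorted(
        ((node_by_id[a], b) for a, b in edges),
        key=lambda e: (order[id(e[0])], order[id(e[1])]),
    )


def root_by_dl(
    tree: Node, species_tree: SpeciesTree
) -> tuple[Node, Reconciliation]:
    """Root an (un)rooted gene tree by minimising duplications + losses.

    Every edge of the unrooted topology is evaluated as a candidate root.
    Ties are broken by smaller duplication count, then by the candidate
    whose child clade has the lexicographically smallest sorted leaf list,
    so the result is stable across runs and leaf orderings.
    """
    if len(tree.leaves()) < 3:
        raise ValueError("rooting requires a tree with at least 3 leaves")
    adj = _unrooted_adjacency(tree)
    best = None
    for u, v in _edges(adj, tree):
        side_u = _directed_copy(u, v, adj)
        side_v = _directed_copy(v, u, adj)
        # deterministic child order: smaller sorted leaf list first
        sides = sorted(
            (side_u, side_v), key=lambda s: tuple(sorted(s.leaf_names()))
        )
        rooted = Node(children=sides)
        rec = lca_map(rooted, species_tree)
        key = (
            rec.cost(),
            rec.duplications,
            tuple(sorted(sides[0].leaf_names())),
        )
        if best is None or key < best[0]:
            best = (key, rooted, rec)
    return best[1], best[2]


# -- reporting -------------------------------------------------------------


def _species_label(node: Node) -> str:
    if node.is_leaf:
        return node.name
    names = sorted(node.leaf_names())
    return f"mrca({names[0]},{names[-1]})"


def reconciliation_table(rec: Reconciliation) -> pd.DataFrame:
    """One row per gene-tree node: image, event, losses on the edge above."""
    ids: dict[Node, str] = {}
    n_internal = 0
    rows = []
    for node in rec.gene_root.preorder():
        if node.is_leaf:
            ids[node] = node.name
        else:
            n_internal += 1
            ids[node] = f"node{n_internal}"
        rows.append(
            {
                "node": ids[node],
                "mapped_species": _species_label(rec.mapping[node]),
                "event": rec.events.get(node, "leaf" if node.is_leaf else ""),
                "losses_on_edge": ";".join(
                    _species_label(s) for s in rec.losses.get(node, [])
                ),
            }
        )
    return pd.DataFrame(rows)
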