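"""Species trees with clade annotations.

A :class:`SpeciesTree` is a rooted, labelled tree of taxa in which every leaf
carries exactly one major clade tag (``monocot``, ``dicot`` or ``outgroup``)
and optionally a set of nested subclade tags (e.g. ``Brassicaceae`` inside
``Brassicales``). The packaged default mirrors a 33-taxon embryophyte
sampling (8 monocots, 23 dicots, moss and spikemoss outgroups) with five-letter
species codes; any tagged tree can be substituted.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .trees import Node, parse_newick, read_newick

__all__ = ["SpeciesTree", "load_default_species_tree", "CLADES"]

CLADES = ("monocot", "dicot", "outgroup")


class SpeciesTree:
    """Rooted species tree plus per-leaf clade tags.

    Parameters
    ----------
    root:
        Root of a rooted tree whose leaf names are species codes.
    clade_tags:
        Mapping species code -> clade tag in :data:`CLADES`.
    subclade_tags:
        Optional mapping species code -> iterable of subclade names.
    """

    def __init__(
        self,
        root: Node,
        clade_tags: Mapping[str, str],
        subclade_tags: Optional[Mapping[str, Iterable[str]]] = None,
    ):
        self.root = root
        leaf_names = root.leaf_names()
        if len(leaf_names) != len(set(leaf_names)):
            raise ValueError("species tree leaf labels must be unique")
        missing = [s for s in leaf_names if s not in clade_tags]
        if missing:
            raise ValueError(f"species without clade tag: {missing}")
        bad = {s: t for s, t in clade_tags.items() if t not in CLADES}
        if bad:
            raise ValueError(f"unknown clade tags: {bad}")
        self.clade_tags = dict(clade_tags)
        self.subclade_tags = {
            s: frozenset(v) for s, v in (subclade_tags or {}).items()
        }
        self._index()

    def _index(self) -> None:
        self.leaf_by_code: dict[str, Node] = {}
        self.depth: dict[int, int] = {}
        self.parent_of: dict[int, Optional[Node]] = {}
        for node in self.root.preorder():
            parent = node.parent
            self.depth[id(node)] = 0 if parent is None else self.depth[id(parent)] + 1
            self.parent_of[id(node)] = parent
            if node.is_leaf:
                self.leaf_by_code[node.name] = node

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return self.root.leaf_names()

    def clade_of(self, code: str) -> str:
        try:
            return self.clade_tags[code]
        except KeyError:
            raise KeyError(f"species code {code!r} not in species tree") from None

    def members(self, clade: str) -> list[str]:
        """Species carrying a major clade tag or a subclade tag ``clade``."""
        if clade in CLADES:
            return [s for s in self.species if self.clade_tags[s] == clade]
        return [s for s in self.species if clade in self.subclade_tags.get(s, ())]

    def lca(self, a: Node, b: Node) -> Node:
        """Lowest common ancestor of two nodes of this tree."""
        while a is not b:
            if self.depth[id(a)] >= self.depth[id(b)]:
                a = self.parent_of[id(a)]
            else:
                b = self.parent_of[id(b)]
        return a

    def is_binary(self) -> bool:
        return self.root.is_binary()

    def validate_for_simulation(self) -> None:
        if self.root.parent is not None:
            raise ValueError("species tree must be rooted (root has a parent)")
        if not self.is_binary():
            raise ValueError("species tree must be binary")


def _load_tags(path) -> tuple[dict[str, str], dict[str, frozenset]]:
    tags = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    clade = dict(zip(tags["species"], tags["clade"]))
    sub = {
        row.species: frozenset(t for t in row.subclades.split(",") if t)
        for row in tags.itertuples()
        if row.subclades
    }
    return clade, sub


def load_default_species_tree() -> SpeciesTree:
    """The packaged 33-taxon species tree with clade and subclade tags."""
    data = resources.files("corekit.data")
    root = parse_newick((data / "species_tree.nwk").read_text())
    clade, sub = _load_tags(data / "species_tags.tsv")
    return SpeciesTree(root, clade, sub)


def load_species_tree(newick_path, tags_path) -> SpeciesTree:
    """Load a species tree from a Newick file and a clade-tag TSV.

    The TSV needs columns ``species`` and ``clade`` and may carry an optional
    ``subclades`` column with comma-separated subclade names.
    """
    root = read_newick(newick_path)
    clade, sub = _load_tags(tags_path)
    return SpeciesTree(root, clade, sub)
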