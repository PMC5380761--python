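"""Monocot/dicot ortholog-group (MD OG) extraction and family summaries.

An MD OG is a clade of a rooted, support-annotated gene tree whose root
bifurcation cleanly separates a monocot-only subclade from a dicot-only
subclade, with branch support strictly above a threshold (default 0.85) and
at least 3 monocot and 4 dicot species represented — the species minima
guard against keeping clusters of misannotated sequences. Clades meeting the
support and species-count conditions in which monocot and dicot leaves are
intermingled with no clean bifurcation anywhere below are reported as
"complex" OGs: their internal duplication structure does not track the
species tree. Reported OGs are pairwise leaf-disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .reconciliation import DUPLICATION, Reconciliation
from .species import SpeciesTree
from .trees import Node, species_code

__all__ = [
    "OGParams",
    "OrthologGroup",
    "FamilyCensus",
    "find_md_ogs",
    "classify_complexity",
    "presence_absence",
    "detect_clade_absence",
    "summarize_ogs",
    "round_half_up",
]

SIMPLE = "simple"
COMPLEX = "complex"


@dataclass(frozen=True)
class OGParams:
    """Thresholds of the MD OG definition."""

    support_threshold: float = 0.85  # strict >
    min_monocot_species: int = 3
    min_dicot_species: int = 4
    complexity_threshold: int = 2  # ancestral duplications making an OG complex

    def __post_init__(self):
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support threshold must lie in [0, 1]")
        if min(self.min_monocot_species, self.min_dicot_species) < 1:
            raise ValueError("species minima must be positive")


@dataclass
class OrthologGroup:
    """One MD OG: root node, members, support, census and class label."""

    og_id: str
    root: Node
    support: float
    members: list[str]
    species_census: dict[str, int]
    classification: str = SIMPLE
    sg_label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def _subtree_profiles(root: Node, stree: SpeciesTree):
    """Per-node species sets by clade, computed bottom-up."""
    prof: dict[int, dict[str, set]] = {}
    for node in root.postorder():
        if node.is_leaf:
            code = species_code(node.name)
            try:
                clade = stree.clade_of(code)
            except KeyError:
                raise ValueError(
                    f"leaf {node.name!r}: species {code!r} has no clade tag"
                ) from None
            prof[id(node)] = {
                "monocot": set(),
                "dicot": set(),
                "outgroup": set(),
            }
            prof[id(node)][clade].add(code)
        else:
            merged = {
                c: set().union(*(prof[id(k)][c] for k in node.children))
                for c in ("monocot", "dicot", "outgroup")
            }
            prof[id(node)] = merged
    return prof


def find_md_ogs(
    rooted_tree: Node,
    species_tree: SpeciesTree,
    params: OGParams = OGParams(),
) -> list[OrthologGroup]:
    """All MD OGs of a rooted, support-annotated gene tree.

    Clean OGs are rooted at supported bifurcations with one all-monocot and
    one all-dicot child subtree (no outgroup leaves inside). Complex OGs are
    the maximal supported clades with enough species of both phyla but no
    clean qualifying bifurcation at or below them; they come pre-labelled
    ``complex``. A node inside a reported OG is never reported again.
    """
    for node in rooted_tree.internal_nodes():
        if node.support is None and node.parent is not None:
            raise ValueError(
                "missing branch support on an internal node; "
                "supports are required for OG extraction"
            )
    prof = _subtree_profiles(rooted_tree, species_tree)

    def census_ok(node: Node) -> bool:
        p = prof[id(node)]
        return (
            len(p["monocot"]) >= params.min_monocot_species
            and len(p["dicot"]) >= params.min_dicot_species
            and not p["outgroup"]
        )

    def support_ok(node: Node) -> bool:
        s = node.support if node.support is not None else 0.0
        return s > params.support_threshold

    def clean_split(node: Node) -> bool:
        if len(node.children) != 2:
            return False
        a, b = (prof[id(c)] for c in node.children)
        mono_dico = (
            a["monocot"] and not a["dicot"] and b["dicot"] and not b["monocot"]
        )
        dico_mono = (
            a["dicot"] and not a["monocot"] and b["monocot"] and not b["dicot"]
        )
        return bool(mono_dico or dico_mono)

    def is_clean_og(node: Node) -> bool:
        return (
            not node.is_leaf
            and support_ok(node)
            and census_ok(node)
            and clean_split(node)
        )

    clean_below: dict[int, bool] = {}
    for node in rooted_tree.postorder():
        clean_below[id(node)] = any(
            is_clean_og(c) or clean_below[id(c)] for c in node.children
        )

    ogs: list[OrthologGroup] = []

    def make_og(node: Node, classification: str) -> None:
        members = node.leaf_names()
        census: dict[str, int] = {}
        for name in members:
            code = species_code(name)
            census[code] = census.get(code, 0) + 1
        ogs.append(
            OrthologGroup(
                og_id=f"OG_{len(ogs) + 1}",
                root=node,
                support=node.support if node.support is not None else 1.0,
                members=members,
                species_census=census,
                classification=classification,
            )
        )

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        if is_clean_og(node):
            make_og(node, SIMPLE)
            return
        if (
            support_ok(node)
            and census_ok(node)
            and not clean_below[id(node)]
        ):
            make_og(node, COMPLEX)
            return
        for child in node.children:
            walk(child)

    walk(rooted_tree)
    return ogs


def classify_complexity(
    og: OrthologGroup,
    rec: Reconciliation,
    params: OGParams = OGParams(),
) -> str:
    """Label an OG simple or complex from its internal duplication structure.

    Counts duplication nodes inside the OG whose species-tree image is an
    internal node — duplications mapping to terminal species (paralogs
    arising after the monocot/dicot divergence within one species) are
    ignored. The OG is complex when this count reaches the configured
    threshold, or when it was already flagged complex at extraction.
    """
    if og.classification == COMPLEX:
        return COMPLEX
    ancestral_dups = sum(
        1
        for node in og.root.preorder()
        if not node.is_leaf
        and rec.events.get(node) == DUPLICATION
        and not rec.mapping[node].is_leaf
    )
    og.classification = (
        COMPLEX if ancestral_dups >= params.complexity_threshold else SIMPLE
    )
    return og.classification


def presence_absence(
    ogs: Sequence[OrthologGroup], species_list: Sequence[str]
) -> pd.DataFrame:
    """Gene-count matrix, OGs as rows and species as columns.

    A zero cell records an inferred loss: no sequence of that OG was found
    in that species.
    """
    data = {
        og.og_id: [og.species_census.get(s, 0) for s in species_list]
        for og in ogs
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(species_list)
    )


def detect_clade_absence(
    matrix: pd.DataFrame, clade: Sequence[str]
) -> list[str]:
    """OG ids with zero genes in every species of ``clade``."""
    clade = list(clade)
    if not clade:
        raise ValueError("empty clade")
    missing = [s for s in clade if s not in matrix.columns]
    if missing:
        raise ValueError(f"species not in matrix: {missing}")
    sub = matrix[clade]
    return list(matrix.index[(sub == 0).all(axis=1)])


# -- summary arithmetic ----------------------------------------------------


def round_half_up(value: float, digits: int = 1) -> float:
    """Decimal round-half-up, matching printed-table precision."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FamilyCensus:
    """Printed family-level counts feeding the summary arithmetic."""

    total_sequences: int = 0
    outgroup_counts: dict[str, int] = field(default_factory=dict)
    complex_genes: int = 0
    complex_ogs: int = 0
    noncomplex_genes: int = 0
    noncomplex_ogs: int = 0
    og_counts: Optional[pd.DataFrame] = None  # per-SG: sg, n_md_og, n_og_c

    def validate(self) -> None:
        if self.og_counts is not None:
            total = int(self.og_counts["n_md_og"].sum())
            n_c = int(self.og_counts["n_og_c"].sum())
            declared = self.complex_ogs + self.noncomplex_ogs
            if declared and total != declared:
                raise ValueError(
                    f"per-SG OG counts sum to {total}, but complex + "
                    f"non-complex OG counts give {declared}"
                )
            if self.complex_ogs and n_c != self.complex_ogs:
                raise ValueError(
                    f"per-SG complex counts sum to {n_c}, declared "
                    f"{self.complex_ogs}"
                )


def summarize_ogs(
    census: FamilyCensus, ogs: Optional[Sequence[OrthologGroup]] = None
) -> dict:
    """Family-level summary: gene totals, per-class means, OG percentages.

    Means are rounded half-up to one decimal and the percentage of
    angiosperm genes in OGs uses the family total minus the outgroup
    counts as denominator, matching how the printed summary is derived.
    """
    census.validate()
    genes_in_ogs = census.complex_genes + census.noncomplex_genes
    outgroup_total = sum(census.outgroup_counts.values())
    angiosperm_total = census.total_sequences - outgroup_total
    summary = {
        "genes_in_ogs": genes_in_ogs,
        "mean_genes_per_complex_og": (
            round_half_up(census.complex_genes / census.complex_ogs)
            if census.complex_ogs
            else 0.0
        ),
        "mean_genes_per_noncomplex_og": (
            round_half_up(census.noncomplex_genes / census.noncomplex_ogs)
            if census.noncomplex_ogs
            else 0.0
        ),
        "pct_angiosperm_genes_in_ogs": (
            round_half_up(100.0 * genes_in_ogs / angiosperm_total)
            if angiosperm_total
            else 0.0
        ),
        "total_sequences": census.total_sequences,
        "angiosperm_sequences": angiosperm_total,
    }
    if census.og_counts is not None:
        summary["total_ogs"] = int(census.og_counts["n_md_og"].sum())
        summary["total_complex_ogs"] = int(census.og_counts["n_og_c"].sum())
    elif census.complex_ogs or census.noncomplex_ogs:
        summary["total_ogs"] = census.complex_ogs + census.noncomplex_ogs
        summary["total_complex_ogs"] = census.complex_ogs
    else:
        summary["total_ogs"] = len(ogs) if ogs else 0
        summary["total_complex_ogs"] = (
            sum(1 for o in ogs if o.classification == COMPLEX) if ogs else 0
        )
    return summary
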