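import pytest

from corekit.species import SpeciesTree, load_default_species_tree
from corekit.trees import parse_newick


@pytest.fixture(scope="session")
def stree33() -> SpeciesTree:
    """The packaged 33-taxon species tree."""
    return load_default_species_tree()


@pytest.fixture()
def stree3() -> SpeciesTree:
    """Minimal ((A,B),C) species tree, A/B monocots, C dicot."""
    return SpeciesTree(
        parse_newick("((A,B),C);"),
        {"A": "monocot", "B": "monocot", "C": "dicot"},
    )


@pytest.fixture()
def stree6() -> SpeciesTree:
    """Six taxa: two monocots, two dicots, two outgroups."""
    return SpeciesTree(
        parse_newick("(((A,B),(C,D)),(E,F));"),
        {
            "A": "monocot",
            "B": "monocot",
            "C": "dicot",
            "D": "dicot",
            "E": "outgroup",
            "F": "outgroup",
        },
    )


@pytest.fixture()
def stree10() -> SpeciesTree:
    """Ten taxa: four monocots, five dicots, one outgroup.

    Large enough for ortholog groups meeting the 3-monocot/4-dicot species
    minima, small enough to reason about by hand.
    """
    return SpeciesTree(
        parse_newick("((((A,B),(C,D)),((E,F),(G,(H,I)))),O);"),
        {
            "A": "monocot",
            "B": "monocot",
            "C": "monocot",
            "D": "monocot",
            "E": "dicot",
            "F": "dicot",
            "G": "dicot",
            "H": "dicot",
            "I": "dicot",
            "O": "outgroup",
        },
    )
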